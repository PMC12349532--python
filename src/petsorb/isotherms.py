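"""Equilibrium isotherm models and nonlinear fitting.

Three classical models relate the equilibrium capacity q (mg/g) to the
equilibrium solute concentration c (mg/L):

* Langmuir   q = q_max * K_L * c / (1 + K_L * c)   (monolayer saturation)
* Freundlich q = K_F * c**(1/n)                    (heterogeneous power law)
* Temkin     q = B * ln(A_T * c)                   (adsorption-heat related)

All fits are nonlinear least squares; the linearized forms serve only as
deterministic initializers.  Goodness statistics are R-squared,
RMSD = sqrt(SSE/n) and chi-square = sum((obs-pred)**2 / pred).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

MODELS = ("Langmuir", "Freundlich", "Temkin")


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or is degenerate."""


@dataclass
class IsothermFit:
    """Fitted isotherm parameters with goodness statistics."""

    model: str
    params: dict[str, float]
    stats: dict[str, float]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "stats": self.stats,
            "n_points": self.n_points,
        }


def eval_langmuir(c, q_max: float, K_L: float):
    """Langmuir capacity; monotone in c and bounded above by q_max."""
    c = np.asarray(c, dtype=float)
    return q_max * K_L * c / (1.0 + K_L * c)


def eval_freundlich(c, K_F: float, inv_n: float):
    """Freundlich power-law capacity q = K_F * c**inv_n."""
    c = np.asarray(c, dtype=float)
    return K_F * np.power(c, inv_n)


def eval_temkin(c, A_T: float, B: float):
    """Temkin capacity q = B * ln(A_T * c); requires A_T * c > 0."""
    c = np.asarray(c, dtype=float)
    if np.any(A_T * c <= 0):
        raise ValueError("Temkin model requires A_T * c > 0")
    return B * np.log(A_T * c)


def goodness(observed, predicted, n_params: int = 0) -> tuple[float, float, float]:
    """(R-squared, RMSD, chi-square) for a fitted curve.

    chi-square sums (obs - pred)**2 / pred over strictly positive
    predictions only, the convention for adsorption fit reporting.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length with >= 2 points")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance; R-squared undefined")
    sse = float(np.sum((obs - pred) ** 2))
    r2 = 1.0 - sse / sst
    rmsd = float(np.sqrt(sse / obs.size))
    pos = pred > 0
    chi2 = float(np.sum((obs[pos] - pred[pos]) ** 2 / pred[pos]))
    return r2, rmsd, chi2


def _stats_dict(obs, pred) -> dict[str, float]:
    r2, rmsd, chi2 = goodness(obs, pred)
    return {"R2": r2, "RMSD": rmsd, "chi_square": chi2}


def _init_langmuir(c, q):
    # Lineweaver-Burk style: 1/q = (1/(qmax KL)) (1/c) + 1/qmax
    mask = (c > 0) & (q > 0)
    if mask.sum() < 2:
        return (max(q.max(), 1.0), 0.1)
    slope, intercept = np.polyfit(1.0 / c[mask], 1.0 / q[mask], 1)
    if intercept <= 0 or slope <= 0:
        return (max(q.max() * 1.2, 1.0), 0.1)
    q_max = 1.0 / intercept
    K_L = intercept / slope
    return (q_max, K_L)


def _init_freundlich(c, q):
    mask = (c > 0) & (q > 0)
    if mask.sum() < 2:
        return (1.0, 0.5)
    slope, intercept = np.polyfit(np.log(c[mask]), np.log(q[mask]), 1)
    return (float(np.exp(intercept)), float(slope))


def _init_temkin(c, q):
    mask = c > 0
    if mask.sum() < 2:
        return (1.0, 1.0)
    slope, intercept = np.polyfit(np.log(c[mask]), q[mask], 1)
    if slope <= 0:
        return (1.0, max(abs(slope), 1e-3))
    return (float(np.exp(intercept / slope)), float(slope))


_MODEL_TABLE = {
    "Langmuir": (eval_langmuir, ("q_max", "K_L"), _init_langmuir),
    "Freundlich": (eval_freundlich, ("K_F", "inv_n"), _init_freundlich),
    "Temkin": (eval_temkin, ("A_T", "B"), _init_temkin),
}


def fit_isotherm(
    c_eq,
    q,
    model: str = "Langmuir",
    init: tuple | None = None,
    bounds: tuple | None = None,
) -> IsothermFit:
    """Nonlinear least-squares fit of one isotherm model to (c_eq, q) pairs.

    Initializers come from the standard linearizations; parameter bounds
    default to positives with q_max capped at 10x the largest observed q.
    """
    c_eq = np.asarray(c_eq, dtype=float)
    q = np.asarray(q, dtype=float)
    if model not in _MODEL_TABLE:
        raise ValueError(f"unknown isotherm model {model!r}; expected one of {MODELS}")
    if c_eq.size < 4:
        raise FitError(f"need at least 4 points to fit {model}, got {c_eq.size}")
    if np.any(c_eq <= 0):
        raise FitError("equilibrium concentrations must be positive")

    func, names, initializer = _MODEL_TABLE[model]
    p0 = init if init is not None else initializer(c_eq, q)
    if bounds is None:
        if model == "Langmuir":
            bounds = ([1e-12, 1e-12], [10.0 * max(q.max(), 1e-6), np.inf])
        else:
            bounds = ([1e-12, 1e-12], [np.inf, np.inf])
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, _ = curve_fit(func, c_eq, q, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(
            f"{model} fit did not converge (init={tuple(np.round(p0, 6))}, bounds={bounds}): {exc}"
        ) from exc
    pred = func(c_eq, *popt)
    return IsothermFit(
        model=model,
        params=dict(zip(names, map(float, popt))),
        stats=_stats_dict(q, pred),
        n_points=int(c_eq.size),
    )


def fit_all_isotherms(c_eq, q) -> list[IsothermFit]:
    """Fit Langmuir, Freundlich and Temkin to the same data."""
    return [fit_isotherm(c_eq, q, model=m) for m in MODELS]


def select_best(fits: list[IsothermFit]) -> IsothermFit:
    """Pick the best fit: highest R2, ties broken by lowest RMSD then chi-square."""
    if not fits:
        raise ValueError("no fits to select from")
    return max(
        fits,
        key=lambda f: (f.stats["R2"], -f.stats["RMSD"], -f.stats["chi_square"]),
    )
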