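"""Adsorption kinetic models: pseudo-first/second order and intraparticle diffusion.

* PFO  q_t = q_e * (1 - exp(-k1*t))
* PSO  q_t = k2 * q_e**2 * t / (1 + k2*q_e*t)
* IPD  q_t = k_diff * sqrt(t) + intercept, fitted piecewise in two regions
  whose breakpoint is found by an exhaustive SSE scan over admissible splits
  (the region boundary is data-driven; a nonzero intercept indicates the
  line does not pass through the origin, i.e. film diffusion contributes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from petsorb.isotherms import FitError, goodness

KINETIC_MODELS = ("PFO", "PSO", "IPD")


@dataclass
class KineticFit:
    """Fitted kinetic parameters; IPD carries per-region parameter/stat nests."""

    model: str
    params: dict
    stats: dict
    n_points: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "stats": self.stats,
            "n_points": self.n_points,
        }


def eval_pfo(t, q_e: float, k1: float):
    """Pseudo-first-order uptake, saturating at q_e."""
    t = np.asarray(t, dtype=float)
    return q_e * (1.0 - np.exp(-k1 * t))


def eval_pso(t, q_e: float, k2: float):
    """Pseudo-second-order uptake q_t = k2*q_e^2*t / (1 + k2*q_e*t)."""
    t = np.asarray(t, dtype=float)
    x = k2 * q_e * t
    return q_e * x / (1.0 + x)


def eval_ipd(t, k_diff: float, intercept: float):
    """Intraparticle-diffusion (Weber-Morris) line in sqrt-time."""
    t = np.asarray(t, dtype=float)
    return k_diff * np.sqrt(t) + intercept


def _stats_dict(obs, pred):
    r2, rmsd, chi2 = goodness(obs, pred)
    return {"R2": r2, "RMSD": rmsd, "chi_square": chi2}


def fit_kinetic(t, q_t, model: str = "PSO") -> KineticFit:
    """Nonlinear least-squares fit of PFO or PSO to a (t, q_t) time course."""
    t = np.asarray(t, dtype=float)
    q_t = np.asarray(q_t, dtype=float)
    if model == "IPD":
        return ipd_two_region_fit(t, q_t)
    if model not in ("PFO", "PSO"):
        raise ValueError(f"unknown kinetic model {model!r}; expected one of {KINETIC_MODELS}")
    if t.size < 5:
        raise FitError(f"need at least 5 time points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise FitError("time points must be strictly increasing")
    if np.ptp(q_t) == 0:
        raise FitError("constant uptake series; kinetic fit is degenerate")

    q_e0 = float(q_t.max()) * 1.05
    # half-time heuristic: time at which q crosses q_e/2
    half_idx = int(np.searchsorted(q_t, q_t.max() / 2.0))
    t_half = float(t[min(half_idx, t.size - 1)]) or 1.0
    if model == "PFO":
        func, names, p0 = eval_pfo, ("q_e", "k1"), (q_e0, np.log(2.0) / t_half)
    else:
        func, names, p0 = eval_pso, ("q_e", "k2"), (q_e0, 1.0 / (q_e0 * t_half))
    try:
        popt, _ = curve_fit(
            func, t, q_t, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"{model} fit did not converge (init={p0}): {exc}") from exc
    pred = func(t, *popt)
    return KineticFit(
        model=model,
        params=dict(zip(names, map(float, popt))),
        stats=_stats_dict(q_t, pred),
        n_points=int(t.size),
    )


def _linfit_sqrt_t(st, q):
    slope, intercept = np.polyfit(st, q, 1)
    pred = slope * st + intercept
    sse = float(np.sum((q - pred) ** 2))
    return float(slope), float(intercept), sse, pred


def ipd_two_region_fit(t, q_t, min_points: int = 3) -> KineticFit:
    """Two-region Weber-Morris fit with an SSE-scan breakpoint.

    Scans every split leaving at least ``min_points`` per side in (sqrt(t), q)
    space and keeps the one minimizing the pooled SSE of the two lines; on
    ties (e.g. globally linear data) the first admissible split is kept.
    """
    t = np.asarray(t, dtype=float)
    q_t = np.asarray(q_t, dtype=float)
    if t.size < 2 * min_points:
        raise FitError(f"need at least {2 * min_points} points for a two-region fit, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise FitError("time points must be strictly increasing")
    st = np.sqrt(t)

    best = None
    for k in range(min_points, t.size - min_points + 1):
        s1, i1, sse1, _ = _linfit_sqrt_t(st[:k], q_t[:k])
        s2, i2, sse2, _ = _linfit_sqrt_t(st[k:], q_t[k:])
        pooled = sse1 + sse2
        if best is None or pooled < best[0] - 1e-15:
            best = (pooled, k, (s1, i1), (s2, i2))
    _, k, (s1, i1), (s2, i2) = best

    regions = []
    for (lo, hi), (slope, intercept) in (((0, k), (s1, i1)), ((k, t.size), (s2, i2))):
        seg_q = q_t[lo:hi]
        pred = slope * st[lo:hi] + intercept
        try:
            stats = _stats_dict(seg_q, pred)
        except ValueError:  # flat segment: R2 undefined, report SSE-only stats
            sse = float(np.sum((seg_q - pred) ** 2))
            stats = {"R2": float("nan"), "RMSD": float(np.sqrt(sse / seg_q.size)), "chi_square": float("nan")}
        regions.append(
            {"k_diff": slope, "intercept": intercept, "n_points": int(hi - lo), "stats": stats}
        )
    return KineticFit(
        model="IPD",
        params={"breakpoint_index": int(k), "breakpoint_time": float(t[k - 1]), "regions": regions},
        stats={"pooled_SSE": float(best[0])},
        n_points=int(t.size),
    )
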