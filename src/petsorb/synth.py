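"""Mechanistic generator for synthetic batch-adsorption campaigns.

The experimental campaign this generator emulates varied one factor at a
time around a base point (pH 2.0, dose 0.4 g/L, time 180 min, c0 21.1 mg/L,
22 degrees C) across pH 2.0-6.5, dose 0.4-20 g/L, contact time 5-1440 min,
initial concentration 4-67 mg/L and temperatures {10, 22, 50} degrees C.

Each simulated capacity is the product of four mechanistic factors:

* a depletion-coupled Langmuir equilibrium (the batch mass balance is
  solved jointly with the isotherm, so high doses deplete the solution and
  q falls with dose, as observed experimentally),
* a van't Hoff temperature correction of the Langmuir affinity,
* a pseudo-second-order kinetic approach-to-equilibrium fraction,
* an exponential pH attenuation anchored at pH 2 (the most favorable pH),

times multiplicative Gaussian noise emulating spectrophotometric
measurement error, whose magnitude scales with signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from petsorb.records import AdsorptionDataset, AdsorptionRecord, compute_removal

R_GAS = 8.314  # J/(mol K)

#: base point of the one-factor-at-a-time design
BASE_POINT = {"pH": 2.0, "dose": 0.4, "time": 180.0, "c0": 21.1, "temperature": 22.0}

#: experimental ranges of the campaign
RANGES = {
    "pH": (2.0, 6.5),
    "dose": (0.4, 20.0),
    "time": (5.0, 1440.0),
    "c0": (4.0, 67.0),
    "temperature": (10.0, 50.0),
}

TEMPERATURE_LEVELS = (10.0, 22.0, 50.0)
#: sampling times, min (endpoints fixed by the campaign; interior log-spaced)
TIME_LEVELS = (5.0, 10.0, 20.0, 30.0, 60.0, 120.0, 180.0, 320.0, 720.0, 1440.0)
PH_LEVELS = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.25, 5.5, 5.75, 6.0, 6.5)
DOSE_LEVELS = (0.4, 0.8, 1.2, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 13.0, 16.0, 20.0)
C0_LEVELS = (4.0, 8.0, 12.0, 16.0, 21.1, 25.0, 30.0, 36.0, 42.0, 50.0, 58.0, 67.0)


@dataclass(frozen=True)
class MechanisticParams:
    """Per-antibiotic generator parameters.

    q_max (mg/g) and K_L_ref (L/mg at T_ref) set the Langmuir equilibrium,
    dH (kJ/mol) its van't Hoff temperature dependence, k2 (g/(mg min)) the
    pseudo-second-order rate, pH_decay the exponential capacity loss per pH
    unit above 2, and noise_cv the relative SD of multiplicative noise.
    """

    q_max: float
    K_L_ref: float
    T_ref: float = 295.15  # K (22 degrees C)
    dH: float = 0.0
    k2: float = 1e-3
    pH_decay: float = 0.0
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.q_max <= 0 or self.K_L_ref <= 0 or self.k2 <= 0:
            raise ValueError("q_max, K_L_ref and k2 must be positive")
        if self.pH_decay < 0:
            raise ValueError("pH_decay must be non-negative")
        if not 0.0 <= self.noise_cv <= 0.2:
            raise ValueError("noise_cv must lie in [0, 0.2]")


def default_params(noise_cv: float = 0.05) -> dict[str, MechanisticParams]:
    """Default mechanistic parameters for both antibiotics.

    Equilibrium and kinetic constants are the fitted Langmuir / PSO / van't
    Hoff values for RIF and RIX on PET fibers; the pH-decay shapes are
    synthetic calibration constants chosen so that RIF loses capacity
    markedly above pH 2 while RIX is nearly pH-insensitive.
    """
    return {
        "RIF": MechanisticParams(
            q_max=44.84, K_L_ref=0.0731, dH=0.41, k2=0.0019, pH_decay=0.08, noise_cv=noise_cv
        ),
        "RIX": MechanisticParams(
            q_max=15.63, K_L_ref=0.1141, dH=0.07, k2=0.0031, pH_decay=0.01, noise_cv=noise_cv
        ),
    }


@dataclass(frozen=True)
class DesignPoint:
    """One planned experimental condition (same units as AdsorptionRecord)."""

    antibiotic: str
    pH: float
    dose: float
    time: float
    c0: float
    temperature: float

    def __post_init__(self) -> None:
        for name in ("pH", "dose", "time", "c0", "temperature"):
            lo, hi = RANGES[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside experimental range [{lo}, {hi}]")


def kl_at_temperature(K_L_ref: float, T_ref: float, T: float, dH: float) -> float:
    """Langmuir affinity at temperature T via the integrated van't Hoff relation.

    K_L(T) = K_L_ref * exp(-(dH/R) * (1/T - 1/T_ref)), dH in kJ/mol, T in K.
    Increasing in T for endothermic adsorption (dH > 0).
    """
    if T <= 0 or T_ref <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    return K_L_ref * np.exp(-(dH * 1000.0 / R_GAS) * (1.0 / T - 1.0 / T_ref))


def equilibrium_capacity(c0: float, dose: float, q_max: float, K_L: float) -> float:
    """Batch equilibrium capacity coupling the mass balance with a Langmuir isotherm.

    Solves q = q_max*K_L*(c0 - q*dose) / (1 + K_L*(c0 - q*dose)) for the
    unique physical root in (0, min(q_max, c0/dose)), in closed form via the
    smaller root of the quadratic

        K_L*dose*q**2 - (1 + K_L*c0 + q_max*K_L*dose)*q + q_max*K_L*c0 = 0.
    """
    if min(c0, dose, q_max, K_L) <= 0:
        raise ValueError("all inputs must be positive")
    a = K_L * dose
    b = 1.0 + K_L * c0 + q_max * K_L * dose
    c = q_max * K_L * c0
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise RuntimeError("no real equilibrium root; inputs are internally inconsistent")
    q = (b - np.sqrt(disc)) / (2.0 * a)
    upper = min(q_max, c0 / dose)
    if not 0.0 < q < upper * (1.0 + 1e-12):
        raise RuntimeError(
            f"equilibrium root q={q} outside the admissible interval (0, {upper})"
        )
    return float(min(q, upper))


def kinetic_fraction(time: float, k2: float, q_e: float) -> float:
    """Pseudo-second-order fractional approach to equilibrium, in [0, 1).

    fraction = k2*q_e*t / (1 + k2*q_e*t); 0 at t=0, 1/2 at t = 1/(k2*q_e).
    """
    if time < 0:
        raise ValueError("time must be non-negative")
    x = k2 * q_e * time
    return x / (1.0 + x)


def ph_factor(pH: float, pH_decay: float) -> float:
    """Capacity attenuation exp(-pH_decay*(pH - 2)); equals 1 at pH 2."""
    if pH < 2.0:
        raise ValueError("pH factor is anchored at pH 2; pH must be >= 2")
    return float(np.exp(-pH_decay * (pH - 2.0)))


def generate_design() -> list[DesignPoint]:
    """One-factor-at-a-time grid for both antibiotics around the base point.

    Each factor scan holds the others at the base point; both antibiotics
    together yield >= 97 points, matching the scale of the emulated campaign.
    """
    points: list[DesignPoint] = []
    for ab in ("RIF", "RIX"):
        base = dict(BASE_POINT)
        scans = [
            ("pH", PH_LEVELS),
            ("dose", DOSE_LEVELS),
            ("time", TIME_LEVELS),
            ("c0", C0_LEVELS),
            ("temperature", TEMPERATURE_LEVELS),
        ]
        for factor, levels in scans:
            for level in levels:
                cond = dict(base)
                cond[factor] = float(level)
                points.append(DesignPoint(antibiotic=ab, **cond))
    return points


def simulate_capacity(point: DesignPoint, params: MechanisticParams) -> float:
    """Noise-free mechanistic capacity at a design point, mg/g."""
    T = point.temperature + 273.15
    kl = kl_at_temperature(params.K_L_ref, params.T_ref, T, params.dH)
    q_eq = equilibrium_capacity(point.c0, point.dose, params.q_max, kl)
    frac = kinetic_fraction(point.time, params.k2, q_eq)
    return q_eq * frac * ph_factor(point.pH, params.pH_decay)


def generate_dataset(
    params: dict[str, MechanisticParams] | None = None,
    design: list[DesignPoint] | None = None,
    noise_cv: float | None = None,
    seed: int = 0,
) -> AdsorptionDataset:
    """Simulate the full campaign into an :class:`AdsorptionDataset`.

    Each point's capacity is the mechanistic product times (1 + eps) with
    eps ~ Normal(0, noise_cv), truncated so q >= 0 and the residual
    concentration stays within [0, c0].  Deterministic under a fixed seed.
    """
    if params is None:
        params = default_params()
    if design is None:
        design = generate_design()
    rng = np.random.default_rng(seed)
    records = []
    for point in design:
        p = params[point.antibiotic]
        cv = p.noise_cv if noise_cv is None else noise_cv
        q = simulate_capacity(point, p)
        if cv > 0:
            q *= 1.0 + rng.normal(0.0, cv)
        q = float(np.clip(q, 0.0, point.c0 / point.dose))
        c_eq = point.c0 - q * point.dose
        records.append(
            AdsorptionRecord(
                antibiotic=point.antibiotic,
                pH=point.pH,
                dose=point.dose,
                time=point.time,
                c0=point.c0,
                temperature=point.temperature,
                c_eq=c_eq,
                q=q,
                removal=compute_removal(point.c0, c_eq),
            )
        )
    return AdsorptionDataset(
        records,
        metadata={"generator": "petsorb.synth", "seed": seed, "design": "one-factor-at-a-time"},
    )


def isotherm_curve(
    params: MechanisticParams,
    c0_levels=C0_LEVELS,
    dose: float = 0.4,
    temperature: float = 22.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium (c_eq, q) pairs across initial concentrations, for isotherm fitting."""
    rng = np.random.default_rng(seed)
    kl = kl_at_temperature(params.K_L_ref, params.T_ref, temperature + 273.15, params.dH)
    c_eq, q = [], []
    for c0 in c0_levels:
        qi = equilibrium_capacity(c0, dose, params.q_max, kl)
        if noise_cv > 0:
            qi *= 1.0 + rng.normal(0.0, noise_cv)
        qi = float(np.clip(qi, 0.0, c0 / dose))
        q.append(qi)
        c_eq.append(c0 - qi * dose)
    return np.array(c_eq), np.array(q)


def kinetic_curve(
    params: MechanisticParams,
    times=TIME_LEVELS,
    c0: float = 21.1,
    dose: float = 0.4,
    temperature: float = 22.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(t, q_t) time course at the base conditions, for kinetic fitting."""
    rng = np.random.default_rng(seed)
    kl = kl_at_temperature(params.K_L_ref, params.T_ref, temperature + 273.15, params.dH)
    q_eq = equilibrium_capacity(c0, dose, params.q_max, kl)
    t = np.asarray(times, dtype=float)
    q = q_eq * np.array([kinetic_fraction(ti, params.k2, q_eq) for ti in t])
    if noise_cv > 0:
        q = np.clip(q * (1.0 + rng.normal(0.0, noise_cv, size=q.shape)), 0.0, None)
    return t, q
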