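"""Adsorption thermodynamics: Gibbs energy, van't Hoff regression, entropy.

Given equilibrium constants K(T) at several temperatures:

* dG0(T) = -R * T * ln K          [kJ/mol]
* van't Hoff: ln K = -dH0/(R*T) + dS0/R, so an OLS line of ln K on 1/T has
  slope -dH0/R and intercept dS0/R (standard sign convention; a positive
  dH0 means endothermic adsorption, K increasing with T)
* dS0(T) = (dH0 - dG0(T)) / T * 1000   [J/(mol K)]

K values are accepted as supplied, as dimensionless-by-convention numbers;
no unit conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_GAS = 8.314  # J/(mol K)


@dataclass
class ThermoResult:
    """Thermodynamic parameters derived from K(T)."""

    temperatures: np.ndarray  # K
    K_values: np.ndarray
    dG: np.ndarray  # kJ/mol, per temperature
    dH: float  # kJ/mol, van't Hoff slope
    dS_regression: float  # J/(mol K), van't Hoff intercept
    dS_per_T: np.ndarray  # J/(mol K), from (dH - dG)/T
    residuals: np.ndarray  # ln K regression residuals

    def to_dict(self) -> dict:
        return {
            "temperatures_K": self.temperatures.tolist(),
            "K_values": self.K_values.tolist(),
            "dG_kJ_per_mol": self.dG.tolist(),
            "dH_kJ_per_mol": self.dH,
            "dS_regression_J_per_molK": self.dS_regression,
            "dS_per_T_J_per_molK": self.dS_per_T.tolist(),
            "lnK_residuals": self.residuals.tolist(),
        }


def gibbs_energy(K: float, T: float) -> float:
    """Standard Gibbs energy change dG0 = -R*T*ln(K) in kJ/mol (T in K)."""
    if K <= 0:
        raise ValueError(f"equilibrium constant must be positive, got {K}")
    if T <= 0:
        raise ValueError(f"temperature must be positive kelvin, got {T}")
    return -R_GAS * T * np.log(K) / 1000.0


def vant_hoff_fit(K_values, temperatures) -> tuple[float, float]:
    """(dH0 kJ/mol, dS0 J/(mol K)) from OLS of ln K on 1/T."""
    K = np.asarray(K_values, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if np.unique(T).size < 3:
        raise ValueError("van't Hoff regression needs at least 3 distinct temperatures")
    if np.any(K <= 0) or np.any(T <= 0):
        raise ValueError("K and T must be positive")
    slope, intercept = np.polyfit(1.0 / T, np.log(K), 1)
    dH = -slope * R_GAS / 1000.0
    dS = intercept * R_GAS
    return float(dH), float(dS)


def entropy_from_gh(dG: float, dH: float, T: float) -> float:
    """Entropy change dS0 = (dH0 - dG0)/T * 1000 in J/(mol K) (inputs in kJ/mol)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive kelvin, got {T}")
    return (dH - dG) / T * 1000.0


def analyze(K_values, temperatures) -> ThermoResult:
    """Full thermodynamic report from K(T) at >= 3 temperatures."""
    K = np.asarray(K_values, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    dH, dS_reg = vant_hoff_fit(K, T)
    dG = np.array([gibbs_energy(k, t) for k, t in zip(K, T)])
    dS_per_T = np.array([entropy_from_gh(g, dH, t) for g, t in zip(dG, T)])
    slope = -dH * 1000.0 / R_GAS
    intercept = dS_reg / R_GAS
    residuals = np.log(K) - (slope / T + intercept)
    return ThermoResult(
        temperatures=T,
        K_values=K,
        dG=dG,
        dH=dH,
        dS_regression=dS_reg,
        dS_per_T=dS_per_T,
        residuals=residuals,
    )
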