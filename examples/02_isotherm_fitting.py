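"""Fit the three classical isotherms to a synthetic equilibrium curve.

Generates (c_eq, q) pairs across the campaign's concentration range with 2%
measurement noise, fits Langmuir / Freundlich / Temkin by nonlinear least
squares and prints parameters with goodness statistics.  The saturating
Langmuir model should win on this plateauing data.
"""

from petsorb import select_best
from petsorb.isotherms import fit_all_isotherms
from petsorb.synth import default_params, isotherm_curve

params = default_params()["RIF"]
c_eq, q = isotherm_curve(params, noise_cv=0.02, seed=3)

fits = fit_all_isotherms(c_eq, q)
for fit in fits:
    pars = ", ".join(f"{k}={v:.4g}" for k, v in fit.params.items())
    print(f"{fit.model:11s} {pars:38s} R2={fit.stats['R2']:.4f} "
          f"RMSD={fit.stats['RMSD']:.3f} chi2={fit.stats['chi_square']:.3f}")
best = select_best(fits)
print(f"\nbest model: {best.model} "
      f"(q_max={best.params.get('q_max', float('nan')):.2f} mg/g vs 44.84 generated)")
# q_max is the fitted monolayer capacity; K_L the affinity for the surface.
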