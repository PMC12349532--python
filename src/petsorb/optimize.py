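"""Process-condition optimization with the same DE engine used for topology search.

The DE vector here encodes the five continuous process conditions (pH,
dose, time, c0, temperature) on the normalized [0,1] box; the antibiotic
one-hot is held fixed.  Fitness is the negated surrogate prediction of
removal efficiency, so the optimizer seeks the conditions maximizing
predicted removal within the experimental bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from petsorb.evolution import de_minimize
from petsorb.network import TrainedSurrogate
from petsorb.synth import RANGES

CONDITION_NAMES = ("pH", "dose", "time", "c0", "temperature")


@dataclass
class ProcessOptimum:
    """Best process conditions (original units) and the predicted removal there."""

    antibiotic: str
    conditions: dict[str, float]
    predicted_removal: float
    history: list

    def to_dict(self) -> dict:
        return {
            "antibiotic": self.antibiotic,
            "conditions": self.conditions,
            "predicted_removal_percent": self.predicted_removal,
        }


def _default_bounds() -> dict[str, tuple[float, float]]:
    return {name: RANGES[name] for name in CONDITION_NAMES}


def optimize_process(
    model: TrainedSurrogate | Callable[[np.ndarray], np.ndarray],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    antibiotic: str = "RIF",
    pop_size: int = 20,
    generations: int = 30,
    seed: int = 0,
) -> ProcessOptimum:
    """Maximize predicted removal over the experimental condition box.

    ``model`` is either a trained surrogate (predicting from raw-unit
    conditions via its stored normalization bounds) or any callable mapping
    a raw-unit condition row to a removal prediction.  The returned
    conditions always lie inside the bounds (clip repair on the normalized
    box guarantees it).
    """
    bnds = _default_bounds() if bounds is None else dict(bounds)
    lo = np.array([bnds[n][0] for n in CONDITION_NAMES])
    hi = np.array([bnds[n][1] for n in CONDITION_NAMES])
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy high > low")

    if isinstance(model, TrainedSurrogate):
        predict = lambda cond: model.predict_raw(cond, antibiotic)  # noqa: E731
    else:
        predict = model

    def objective(genome: np.ndarray) -> float:
        cond = lo + np.clip(genome, 0.0, 1.0) * (hi - lo)
        return -float(np.asarray(predict(cond[None, :])).ravel()[0])

    genome, neg_best, history = de_minimize(
        objective, dim=len(CONDITION_NAMES), pop_size=pop_size,
        generations=generations, seed=seed,
    )
    best_cond = lo + np.clip(genome, 0.0, 1.0) * (hi - lo)
    return ProcessOptimum(
        antibiotic=antibiotic,
        conditions={n: float(v) for n, v in zip(CONDITION_NAMES, best_cond)},
        # removal is a percentage: surrogate extrapolation beyond the
        # physical range is reported at the bound
        predicted_removal=float(np.clip(-neg_best, 0.0, 100.0)),
        history=history,
    )
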