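"""Shapley-value attribution of surrogate predictions to process features.

Features are treated as players in a cooperative game whose value for a
coalition S is the model prediction with the out-of-coalition features
replaced by a single background reference (by default the training-set
feature means).  With 7 features (or fewer grouped players, e.g. the
antibiotic one-hot pair attributed as one player) exhaustive enumeration of
all coalitions is cheap and makes the efficiency axiom hold exactly:

    sum_j phi_j = f(instance) - f(background).

A permutation-sampling estimator of the same quantity is provided for
cross-checks and larger player counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Callable, Sequence

import numpy as np


@dataclass
class AttributionReport:
    """Per-feature Shapley values for one instance (units of removal %)."""

    features: tuple[str, ...]
    values: np.ndarray
    baseline: float  # model prediction at the background reference
    prediction: float  # model prediction at the instance

    def ranking(self) -> list[str]:
        return rank_features(self)

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "shapley_values": self.values.tolist(),
            "baseline": self.baseline,
            "prediction": self.prediction,
            "ranking": self.ranking(),
        }


def _as_groups(
    n_features: int, groups: Sequence[Sequence[int]] | None
) -> list[np.ndarray]:
    if groups is None:
        return [np.array([j]) for j in range(n_features)]
    return [np.asarray(g, dtype=int) for g in groups]


def _coalition_value(model, background, instance, groups, coalition) -> float:
    z = background.copy()
    for gi in coalition:
        z[groups[gi]] = instance[groups[gi]]
    return float(np.asarray(model(z[None, :])).ravel()[0])


def exact_shapley(
    model: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
    feature_names: Sequence[str] | None = None,
    groups: Sequence[Sequence[int]] | None = None,
) -> AttributionReport:
    """Exact Shapley values by exhaustive coalition enumeration (2^m evaluations).

    ``groups`` optionally merges feature indices into joint players (used to
    attribute the two one-hot antibiotic columns as a single feature).
    """
    background = np.asarray(background, dtype=float)
    instance = np.asarray(instance, dtype=float)
    grp = _as_groups(instance.size, groups)
    m = len(grp)
    names = tuple(feature_names) if feature_names else tuple(f"f{j}" for j in range(m))
    if len(names) != m:
        raise ValueError("feature_names length must match the number of players")

    values_cache: dict[frozenset, float] = {}

    def value(coalition: frozenset) -> float:
        if coalition not in values_cache:
            values_cache[coalition] = _coalition_value(
                model, background, instance, grp, coalition
            )
        return values_cache[coalition]

    phi = np.zeros(m)
    players = list(range(m))
    for j in players:
        rest = [p for p in players if p != j]
        for size in range(m):
            w = factorial(size) * factorial(m - size - 1) / factorial(m)
            for S in combinations(rest, size):
                S = frozenset(S)
                phi[j] += w * (value(S | {j}) - value(S))

    baseline = value(frozenset())
    prediction = value(frozenset(players))
    return AttributionReport(features=names, values=phi, baseline=baseline, prediction=prediction)


def sampled_shapley(
    model: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
    n_permutations: int = 2000,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    groups: Sequence[Sequence[int]] | None = None,
) -> AttributionReport:
    """Unbiased Monte-Carlo Shapley estimate by permutation sampling."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    background = np.asarray(background, dtype=float)
    instance = np.asarray(instance, dtype=float)
    grp = _as_groups(instance.size, groups)
    m = len(grp)
    names = tuple(feature_names) if feature_names else tuple(f"f{j}" for j in range(m))

    rng = np.random.default_rng(seed)
    phi = np.zeros(m)
    for _ in range(n_permutations):
        order = rng.permutation(m)
        z = background.copy()
        prev = float(np.asarray(model(z[None, :])).ravel()[0])
        for j in order:
            z[grp[j]] = instance[grp[j]]
            cur = float(np.asarray(model(z[None, :])).ravel()[0])
            phi[j] += cur - prev
            prev = cur
    phi /= n_permutations

    baseline = float(np.asarray(model(background[None, :])).ravel()[0])
    prediction = float(np.asarray(model(instance[None, :])).ravel()[0])
    return AttributionReport(features=names, values=phi, baseline=baseline, prediction=prediction)


def rank_features(report: AttributionReport) -> list[str]:
    """Features in descending mean-|attribution| order; ties broken alphabetically."""
    order = sorted(
        range(len(report.features)),
        key=lambda j: (-abs(report.values[j]), report.features[j]),
    )
    return [report.features[j] for j in order]
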