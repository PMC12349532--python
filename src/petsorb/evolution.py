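"""Self-adaptive differential evolution and neuroevolution of the surrogate.

The optimizer is DE/current-to-best/bin with jDE-style self-adaptation:
every individual carries its own mutation factor F in [0.1, 1.0] and
crossover rate Cr in [0, 1], each resampled uniformly with probability 0.1
when the individual produces offspring.  Genomes live in the [0, 1] box and
are repaired by clipping.  Selection is greedy: the trial replaces its
target when its fitness is less than or equal to the target's.

For topology search the 8-gene genome is directly decoded into a dense
network architecture (1 layer-count gene + 5 width genes; the trailing F
and Cr genes ride along as control parameters, not topology).  Fitness is
the final penalized training loss of the decoded, trained network.  The
same engine drives generic minimization (:func:`de_minimize`), which the
process optimizer reuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from petsorb.network import (
    MAX_HIDDEN_LAYERS,
    MAX_NEURONS,
    NetworkTopology,
    TrainedSurrogate,
    train_network,
)

F_BOUNDS = (0.1, 1.0)
CR_BOUNDS = (0.0, 1.0)
ADAPT_PROB = 0.1
TOPOLOGY_GENES = 1 + MAX_HIDDEN_LAYERS  # layer-count gene + one width gene per layer slot


@dataclass
class DEIndividual:
    """A candidate solution: genome in [0,1]^d plus self-adaptive F and Cr."""

    genome: np.ndarray
    F: float
    Cr: float
    fitness: float = np.inf

    def __post_init__(self) -> None:
        self.genome = np.asarray(self.genome, dtype=float)
        if not F_BOUNDS[0] <= self.F <= F_BOUNDS[1]:
            raise ValueError(f"F={self.F} outside {F_BOUNDS}")
        if not CR_BOUNDS[0] <= self.Cr <= CR_BOUNDS[1]:
            raise ValueError(f"Cr={self.Cr} outside {CR_BOUNDS}")


def decode(genome: np.ndarray) -> NetworkTopology:
    """Direct decoding of a topology genome (clip-repaired to [0,1]).

    layer count = 1 + round(g0 * 4); width_i = 1 + round(g_i * 19) for the
    first layer-count width genes; surplus width genes are ignored.
    """
    g = np.clip(np.asarray(genome, dtype=float)[:TOPOLOGY_GENES], 0.0, 1.0)
    n_layers = 1 + int(round(g[0] * (MAX_HIDDEN_LAYERS - 1)))
    widths = tuple(1 + int(round(g[1 + i] * (MAX_NEURONS - 1))) for i in range(n_layers))
    return NetworkTopology(hidden_layers=widths)


def encode(topology: NetworkTopology) -> np.ndarray:
    """Inverse of :func:`decode` (canonical genome; unused width genes set to 0)."""
    g = np.zeros(TOPOLOGY_GENES)
    g[0] = (len(topology.hidden_layers) - 1) / (MAX_HIDDEN_LAYERS - 1)
    for i, w in enumerate(topology.hidden_layers):
        g[1 + i] = (w - 1) / (MAX_NEURONS - 1)
    return g


def mutate(
    x_current: np.ndarray,
    x_best: np.ndarray,
    x_r1: np.ndarray,
    x_r2: np.ndarray,
    F: float,
) -> np.ndarray:
    """DE/current-to-best mutation: v = x + F*(best - x) + F*(r1 - r2)."""
    if F <= 0:
        raise ValueError(f"mutation factor must be positive, got F={F}")
    return x_current + F * (x_best - x_current) + F * (x_r1 - x_r2)


def crossover_binomial(
    target: np.ndarray,
    donor: np.ndarray,
    Cr: float,
    forced_index: int,
    randoms: np.ndarray,
) -> np.ndarray:
    """Binomial crossover: donor gene where random < Cr or at the forced index."""
    target = np.asarray(target, dtype=float)
    donor = np.asarray(donor, dtype=float)
    if target.shape != donor.shape:
        raise ValueError("target and donor must have equal length")
    if not 0 <= forced_index < target.size:
        raise ValueError(f"forced_index {forced_index} out of range")
    mask = np.asarray(randoms) < Cr
    mask[forced_index] = True
    return np.where(mask, donor, target)


def self_adapt(F: float, Cr: float, rng: np.random.Generator) -> tuple[float, float]:
    """jDE control-parameter update: resample each with probability 0.1."""
    if rng.random() < ADAPT_PROB:
        F = float(rng.uniform(*F_BOUNDS))
    if rng.random() < ADAPT_PROB:
        Cr = float(rng.uniform(*CR_BOUNDS))
    return F, Cr


def de_minimize(
    objective: Callable[[np.ndarray], float],
    dim: int,
    pop_size: int = 20,
    generations: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize an objective over [0,1]^dim with self-adaptive DE/current-to-best/bin.

    Returns (best genome, best fitness, per-generation best-fitness history).
    The history is non-increasing because selection is greedy.  The
    population is updated in place (asynchronous), so an accepted trial
    becomes available as the "best so far" within the same generation.
    """
    rng = np.random.default_rng(seed)
    # jDE initialization: F = 0.5, Cr = 0.9 for every individual
    pop = [
        DEIndividual(genome=rng.uniform(0.0, 1.0, dim), F=0.5, Cr=0.9)
        for _ in range(pop_size)
    ]
    for ind in pop:
        ind.fitness = float(objective(ind.genome))

    history = []
    for _ in range(generations):
        for i, ind in enumerate(pop):
            best = min(pop, key=lambda x: x.fitness)
            others = [j for j in range(pop_size) if j != i]
            r1, r2 = rng.choice(others, size=2, replace=False)
            F_new, Cr_new = self_adapt(ind.F, ind.Cr, rng)
            donor = mutate(ind.genome, best.genome, pop[r1].genome, pop[r2].genome, F_new)
            donor = np.clip(donor, 0.0, 1.0)
            trial = crossover_binomial(
                ind.genome, donor, Cr_new, int(rng.integers(dim)), rng.random(dim)
            )
            trial_fit = float(objective(trial))
            if trial_fit <= ind.fitness:
                pop[i] = DEIndividual(trial, F_new, Cr_new, trial_fit)
        history.append(min(ind.fitness for ind in pop))

    best = min(pop, key=lambda ind: ind.fitness)
    return best.genome.copy(), best.fitness, history


def fitness(
    genome: np.ndarray,
    train_features: np.ndarray,
    train_targets: np.ndarray,
    seed: int,
    cache: dict | None = None,
    train_kwargs: dict | None = None,
) -> float:
    """Fitness of a topology genome: final penalized training loss after training.

    Identical decoded topologies (under the same training seed) share a
    cached value, since the topology fully determines the trained network.
    """
    topo = decode(genome)
    key = topo.hidden_layers
    if cache is not None and key in cache:
        return cache[key]
    try:
        model = train_network(
            topo, train_features, train_targets, seed=seed, **(train_kwargs or {})
        )
        fit = model.final_loss
    except FloatingPointError:
        fit = np.inf  # diverged training is the worst possible candidate
    if cache is not None:
        cache[key] = fit
    return fit


@dataclass
class EvolutionHistory:
    """Per-run record of the topology search."""

    run_seeds: list[int] = field(default_factory=list)
    best_fitness_per_gen: list[list[float]] = field(default_factory=list)
    best_topologies: list[tuple[int, ...]] = field(default_factory=list)
    best_fitnesses: list[float] = field(default_factory=list)


def evolve(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    pop_size: int = 20,
    generations: int = 30,
    runs: int = 10,
    seed: int = 0,
    bounds: np.ndarray | None = None,
    train_kwargs: dict | None = None,
) -> tuple[TrainedSurrogate, EvolutionHistory]:
    """Neuroevolution: independent DE runs over topology space; best network wins.

    Each run draws its own child seed from the master seed, evolves a
    population of topology genomes for ``generations`` generations, and the
    overall best topology (lowest final training loss) across all runs is
    retrained and returned together with the full history.
    """
    master = np.random.default_rng(seed)
    run_seeds = [int(master.integers(2**31 - 1)) for _ in range(runs)]
    history = EvolutionHistory(run_seeds=run_seeds)

    overall_best: tuple[float, tuple[int, ...], int] | None = None
    for run_seed in run_seeds:
        cache: dict = {}
        obj = lambda g: fitness(  # noqa: E731
            g, train_features, train_targets, seed=run_seed, cache=cache,
            train_kwargs=train_kwargs,
        )
        genome, fit, gen_hist = de_minimize(
            obj, dim=TOPOLOGY_GENES + 2, pop_size=pop_size,
            generations=generations, seed=run_seed,
        )
        topo = decode(genome).hidden_layers
        history.best_fitness_per_gen.append(gen_hist)
        history.best_topologies.append(topo)
        history.best_fitnesses.append(fit)
        if overall_best is None or fit < overall_best[0]:
            overall_best = (fit, topo, run_seed)

    _, best_topo, best_seed = overall_best
    model = train_network(
        NetworkTopology(hidden_layers=best_topo),
        train_features,
        train_targets,
        seed=best_seed,
        bounds=bounds,
        **(train_kwargs or {}),
    )
    return model, history
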