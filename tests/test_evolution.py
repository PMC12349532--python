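"""Differential evolution: operators, decoding, self-adaptation, convergence."""

import numpy as np
import pytest

from petsorb.evolution import (
    TOPOLOGY_GENES,
    crossover_binomial,
    de_minimize,
    decode,
    encode,
    evolve,
    fitness,
    mutate,
    self_adapt,
)
from petsorb.network import NetworkTopology, performance


class TestDecode:
    def test_lower_corner(self):
        assert decode(np.zeros(8)).hidden_layers == (1,)

    def test_upper_corner(self):
        assert decode(np.ones(8)).hidden_layers == (20,) * 5

    def test_encode_decode_round_trip(self):
        topo = NetworkTopology((19, 5, 6, 3))
        assert decode(encode(topo)).hidden_layers == (19, 5, 6, 3)

    def test_repair_by_clipping(self, rng):
        for _ in range(50):
            g = rng.normal(0, 3, TOPOLOGY_GENES)  # wildly out of the box
            topo = decode(g)
            assert 1 <= len(topo.hidden_layers) <= 5
            assert all(1 <= w <= 20 for w in topo.hidden_layers)


class TestOperators:
    def test_mutation_stationary_point(self):
        x = np.array([0.2, 0.8])
        assert np.array_equal(mutate(x, x, np.array([0.3, 0.3]), np.array([0.3, 0.3]), 0.7), x)

    def test_mutation_hand_arithmetic(self):
        v = mutate(
            np.array([0.0, 0.0]), np.array([1.0, 0.0]),
            np.array([0.0, 1.0]), np.array([0.0, 0.0]), 0.5,
        )
        assert np.allclose(v, [0.5, 0.5])

    def test_mutation_rejects_nonpositive_f(self):
        z = np.zeros(2)
        with pytest.raises(ValueError):
            mutate(z, z, z, z, 0.0)

    def test_crossover_full_and_none(self):
        target, donor = np.zeros(6), np.ones(6)
        randoms = np.full(6, 0.5)
        assert np.array_equal(crossover_binomial(target, donor, 1.0, 2, randoms), donor)
        only_forced = crossover_binomial(target, donor, 0.0, 2, randoms)
        assert only_forced[2] == 1.0 and only_forced.sum() == 1.0

    def test_crossover_exact_mask(self):
        target, donor = np.zeros(5), np.ones(5)
        randoms = np.array([0.1, 0.9, 0.4, 0.6, 0.2])
        trial = crossover_binomial(target, donor, 0.5, 3, randoms)
        assert np.array_equal(trial, [1.0, 0.0, 1.0, 1.0, 1.0])


class TestSelfAdapt:
    def test_bounds_always_respected(self, rng):
        F, Cr = 0.5, 0.9
        for _ in range(1000):
            F, Cr = self_adapt(F, Cr, rng)
            assert 0.1 <= F <= 1.0
            assert 0.0 <= Cr <= 1.0

    def test_empirical_resample_rate(self):
        rng = np.random.default_rng(99)
        changed = 0
        n = 100_000
        for _ in range(n):
            F, _ = self_adapt(0.5, 0.9, rng)
            changed += F != 0.5
        assert changed / n == pytest.approx(0.1, abs=0.01)


class TestDEMinimize:
    def test_sphere_convergence(self):
        # classical DE benchmark: 8-d sphere, pop 20, 30 generations
        hits = sum(
            de_minimize(lambda g: float(np.sum(g**2)), dim=8, pop_size=20,
                        generations=30, seed=s)[1] <= 1e-3
            for s in range(10)
        )
        assert hits >= 6

    def test_best_fitness_monotone_non_increasing(self):
        _, _, hist = de_minimize(
            lambda g: float(np.sum((g - 0.4) ** 2)), dim=5, pop_size=12,
            generations=25, seed=3,
        )
        assert len(hist) == 25
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))

    def test_deterministic_under_seed(self):
        obj = lambda g: float(np.sum(np.abs(g - 0.2)))  # noqa: E731
        a = de_minimize(obj, dim=6, pop_size=10, generations=10, seed=5)
        b = de_minimize(obj, dim=6, pop_size=10, generations=10, seed=5)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1] and a[2] == b[2]


class TestFitness:
    def test_identical_genomes_identical_fitness(self, normalized_features):
        fm = normalized_features
        g = np.full(8, 0.3)
        kw = dict(train_kwargs={"max_epochs": 30})
        assert fitness(g, fm.X, fm.y, seed=1, **kw) == fitness(g, fm.X, fm.y, seed=1, **kw)

    def test_cache_hit(self, normalized_features):
        fm = normalized_features
        cache = {}
        g = np.full(8, 0.3)
        f1 = fitness(g, fm.X, fm.y, seed=1, cache=cache, train_kwargs={"max_epochs": 30})
        assert cache
        # perturbing only the F/Cr genes leaves the decoded topology unchanged
        g2 = g.copy()
        g2[-2:] = 0.9
        f2 = fitness(g2, fm.X, fm.y, seed=1, cache=cache, train_kwargs={"max_epochs": 30})
        assert f1 == f2

    def test_noise_target_harder_than_learnable(self, rng):
        X = rng.uniform(0, 1, size=(60, 7))
        X[:, 5], X[:, 6] = 1.0, 0.0
        learnable = X @ np.array([10.0, -5.0, 3.0, 2.0, -1.0, 0.0, 0.0]) + 50
        noise = rng.normal(50, 10, 60)
        g = encode(NetworkTopology((10, 5)))
        genome = np.concatenate([g, [0.5, 0.9]])
        kw = dict(train_kwargs={"max_epochs": 100})
        f_learn = fitness(genome, X, learnable, seed=2, **kw)
        f_noise = fitness(genome, X, noise, seed=2, **kw)
        assert f_noise > f_learn


class TestEvolve:
    def test_bit_reproducible(self, normalized_features):
        fm = normalized_features
        kw = dict(pop_size=4, generations=2, runs=1, seed=11,
                  train_kwargs={"max_epochs": 20})
        m1, h1 = evolve(fm.X, fm.y, **kw)
        m2, h2 = evolve(fm.X, fm.y, **kw)
        assert m1.topology == m2.topology
        for Wa, Wb in zip(m1.weights, m2.weights):
            assert np.array_equal(Wa, Wb)
        assert h1.best_fitnesses == h2.best_fitnesses

    def test_history_shapes(self, normalized_features):
        fm = normalized_features
        _, hist = evolve(fm.X, fm.y, pop_size=4, generations=3, runs=2, seed=0,
                         train_kwargs={"max_epochs": 20})
        assert len(hist.best_fitness_per_gen) == 2
        assert all(len(h) == 3 for h in hist.best_fitness_per_gen)
        for h in hist.best_fitness_per_gen:
            assert all(b <= a + 1e-15 for a, b in zip(h, h[1:]))

    def test_reaches_high_training_r2(self, normalized_features):
        # scaled-down neuroevolution on the noiseless campaign still finds
        # topologies that explain >= 90% of removal variance in most runs
        fm = normalized_features
        hits = 0
        for seed in range(10):
            model, _ = evolve(fm.X, fm.y, pop_size=10, generations=6, runs=1,
                              seed=seed, bounds=fm.bounds)
            hits += performance(model, fm.X, fm.y)["R2"] >= 0.9
        assert hits >= 8
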