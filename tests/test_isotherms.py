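"""Isotherm evaluation, nonlinear fitting, goodness statistics, model selection."""

import numpy as np
import pytest

from petsorb.isotherms import (
    FitError,
    IsothermFit,
    eval_freundlich,
    eval_langmuir,
    eval_temkin,
    fit_all_isotherms,
    fit_isotherm,
    goodness,
    select_best,
)
from petsorb.synth import isotherm_curve


class TestEvaluation:
    def test_langmuir(self):
        assert eval_langmuir(0.0, 44.84, 0.0731) == 0.0
        assert eval_langmuir(1 / 0.0731, 44.84, 0.0731) == pytest.approx(44.84 / 2)
        assert eval_langmuir(10.0, 44.84, 0.0731) == pytest.approx(18.94, abs=0.01)

    def test_langmuir_bounded_by_qmax(self, rng):
        c = rng.uniform(0, 1e6, 100)
        assert np.all(eval_langmuir(c, 44.84, 0.0731) <= 44.84)

    def test_freundlich(self):
        assert eval_freundlich(1.0, 6.6054, 0.43) == pytest.approx(6.6054)
        assert eval_freundlich(7.0, 3.0, 1.0) == pytest.approx(21.0)
        assert eval_freundlich(10.0, 6.6054, 0.43) == pytest.approx(17.78, abs=0.01)

    def test_temkin(self):
        assert eval_temkin(1 / 8.55, 8.55, 2.0) == pytest.approx(0.0)
        assert eval_temkin(np.e / 8.55, 8.55, 2.0) == pytest.approx(2.0)
        assert eval_temkin(10.0, 8.55, 1.0) == pytest.approx(np.log(85.5))

    def test_temkin_domain_error(self):
        with pytest.raises(ValueError):
            eval_temkin(-1.0, 8.55, 2.0)


class TestGoodness:
    def test_perfect_prediction(self):
        r2, rmsd, chi2 = goodness([1, 2, 3], [1, 2, 3])
        assert (r2, rmsd, chi2) == (1.0, 0.0, 0.0)

    def test_mean_prediction_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0])
        r2, _, _ = goodness(obs, np.full(3, obs.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        r2, rmsd, chi2 = goodness([1, 2, 3], [1, 2, 4])
        assert r2 == pytest.approx(0.5)
        assert rmsd == pytest.approx(np.sqrt(1 / 3))
        assert chi2 == pytest.approx(0.25)

    def test_matches_definition_on_random_vectors(self, rng):
        # independent recomputation from the bare formulas
        for _ in range(20):
            obs = rng.uniform(1, 50, 12)
            pred = obs + rng.normal(0, 2, 12)
            r2, rmsd, chi2 = goodness(obs, pred)
            sse = sum((o - p) ** 2 for o, p in zip(obs, pred))
            sst = sum((o - np.mean(obs)) ** 2 for o in obs)
            assert r2 == pytest.approx(1 - sse / sst)
            assert rmsd == pytest.approx(np.sqrt(sse / 12))
            assert chi2 == pytest.approx(
                sum((o - p) ** 2 / p for o, p in zip(obs, pred) if p > 0)
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            goodness([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestFitting:
    @pytest.mark.parametrize(
        "model,true_params",
        [
            ("Langmuir", {"q_max": 44.84, "K_L": 0.0731}),
            ("Freundlich", {"K_F": 6.6054, "inv_n": 0.43}),
            ("Temkin", {"A_T": 8.55, "B": 2.5}),
        ],
    )
    def test_noiseless_recovery(self, model, true_params):
        c = np.array([4.0, 8.0, 12.0, 21.1, 30.0, 42.0, 55.0, 67.0])
        func = {"Langmuir": eval_langmuir, "Freundlich": eval_freundlich, "Temkin": eval_temkin}[
            model
        ]
        q = func(c, *true_params.values())
        fit = fit_isotherm(c, q, model=model)
        for name, truth in true_params.items():
            assert fit.params[name] == pytest.approx(truth, rel=1e-4)
        assert fit.stats["R2"] == pytest.approx(1.0, abs=1e-8)

    def test_freundlich_log_linear_oracle(self, rng):
        # log-log OLS is an independent exact solver for noiseless power laws
        c = rng.uniform(2, 60, 8)
        q = eval_freundlich(c, 5.1642, 0.23)
        slope, intercept = np.polyfit(np.log(c), np.log(q), 1)
        fit = fit_isotherm(c, q, model="Freundlich")
        assert fit.params["inv_n"] == pytest.approx(slope, rel=1e-6)
        assert fit.params["K_F"] == pytest.approx(np.exp(intercept), rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(FitError, match="4 points"):
            fit_isotherm([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], model="Langmuir")

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown"):
            fit_isotherm([1, 2, 3, 4], [1, 2, 3, 4], model="BET")

    def test_depletion_curve_recovery(self, noiseless_params):
        # generator-oracle round trip at the campaign concentration levels
        p = noiseless_params["RIF"]
        c_eq, q = isotherm_curve(p)
        fit = fit_isotherm(c_eq, q, model="Langmuir")
        assert fit.params["q_max"] == pytest.approx(p.q_max, rel=1e-4)
        assert fit.params["K_L"] == pytest.approx(p.K_L_ref, rel=1e-4)


class TestSelection:
    def _fit(self, model, r2, rmsd=0.02, chi2=0.01):
        return IsothermFit(model, {}, {"R2": r2, "RMSD": rmsd, "chi_square": chi2}, 8)

    def test_highest_r2_wins(self):
        fits = [self._fit("Langmuir", 0.987), self._fit("Freundlich", 0.880),
                self._fit("Temkin", 0.946)]
        assert select_best(fits).model == "Langmuir"

    def test_tie_broken_by_rmsd(self):
        fits = [self._fit("A", 0.95, rmsd=0.02), self._fit("B", 0.95, rmsd=0.03)]
        assert select_best(fits).model == "A"

    def test_single_fit(self):
        only = self._fit("Temkin", 0.5)
        assert select_best([only]) is only

    def test_prefers_langmuir_on_saturating_data(self, noiseless_params):
        # plateaued synthetic curves: the saturating model should win a
        # majority of noisy replicates (Freundlich is unbounded)
        wins = 0
        for seed in range(20):
            c_eq, q = isotherm_curve(noiseless_params["RIF"], noise_cv=0.02, seed=seed)
            wins += select_best(fit_all_isotherms(c_eq, q)).model == "Langmuir"
        assert wins > 10
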