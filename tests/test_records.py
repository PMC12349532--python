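"""Mass-balance arithmetic, feature-matrix construction and dataset I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petsorb.records import (
    AdsorptionDataset,
    AdsorptionRecord,
    DomainError,
    FeatureMatrix,
    build_feature_matrix,
    capacity_from_removal,
    compute_capacity,
    compute_removal,
    denormalize,
    minmax_normalize,
    one_hot,
    read_dataset,
    split_dataset,
    write_dataset,
)


class TestMassBalance:
    @pytest.mark.parametrize(
        "c0,c,volume,mass,expected",
        [
            (21.1, 21.1, 0.025, 0.01, 0.0),  # no removal
            (21.1, 0.0, 0.025, 0.01, 52.75),  # complete removal
            (10.0, 5.0, 0.05, 0.02, 12.5),
        ],
    )
    def test_capacity(self, c0, c, volume, mass, expected):
        assert compute_capacity(c0, c, volume, mass) == pytest.approx(expected)

    def test_capacity_from_removal_dose_form(self):
        # q = R*c0/(100*dose) at the dose-scan endpoint conditions
        assert capacity_from_removal(58.9, 21.1, 0.4) == pytest.approx(31.07, abs=0.005)

    def test_capacity_rejects_negative_uptake(self):
        with pytest.raises(DomainError, match="c0"):
            compute_capacity(5.0, 6.0, 0.025, 0.01)

    @pytest.mark.parametrize(
        "c0,c,expected", [(21.1, 0.0, 100.0), (21.1, 21.1, 0.0), (21.1, 9.3, 55.924)]
    )
    def test_removal(self, c0, c, expected):
        assert compute_removal(c0, c) == pytest.approx(expected, abs=5e-4)

    def test_removal_rejects_nonpositive_c0(self):
        with pytest.raises(DomainError):
            compute_removal(0.0, 0.0)


class TestOneHot:
    def test_categories(self):
        assert one_hot("RIF") == (1, 0)
        assert one_hot("RIX") == (0, 1)

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="AMX"):
            one_hot("AMX")


class TestRecordInvariants:
    def test_consistent_record_accepted(self):
        AdsorptionRecord(
            antibiotic="RIF", pH=2.0, dose=0.4, time=180, c0=21.1,
            temperature=22, c_eq=9.3,
            q=capacity_from_removal(compute_removal(21.1, 9.3), 21.1, 0.4),
            removal=compute_removal(21.1, 9.3),
        )

    def test_inconsistent_capacity_removal_rejected(self):
        with pytest.raises(DomainError, match="inconsistent"):
            AdsorptionRecord(
                antibiotic="RIF", pH=2.0, dose=0.4, time=180, c0=21.1,
                temperature=22, q=30.0, removal=10.0,
            )

    @pytest.mark.parametrize(
        "field,value",
        [("pH", 15.0), ("dose", -1.0), ("c0", 0.0), ("removal", 120.0), ("c_eq", 30.0)],
    )
    def test_field_bounds(self, field, value):
        kwargs = dict(
            antibiotic="RIF", pH=2.0, dose=0.4, time=180, c0=21.1, temperature=22
        )
        kwargs[field] = value
        with pytest.raises(DomainError):
            AdsorptionRecord(**kwargs)


class TestNormalization:
    def _matrix(self, X):
        X = np.asarray(X, dtype=float)
        bounds = np.vstack([X.min(axis=0), X.max(axis=0)])
        return FeatureMatrix(X=X, y=np.zeros(X.shape[0]), bounds=bounds)

    def test_endpoints_and_midpoint(self):
        X = np.array(
            [[2.0, 1, 1, 1, 1, 1, 0], [6.5, 2, 2, 2, 2, 0, 1], [4.25, 3, 3, 3, 3, 1, 0]]
        )
        norm = minmax_normalize(self._matrix(X))
        assert norm.X[:, 0] == pytest.approx([0.0, 1.0, 0.5])
        # one-hot columns untouched
        assert np.array_equal(norm.X[:, 5:], X[:, 5:])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(1.0, 100.0, size=(8, 7))
        X[:, 5] = rng.integers(0, 2, 8)
        X[:, 6] = 1 - X[:, 5]
        fm = self._matrix(X)
        back = denormalize(minmax_normalize(fm))
        assert np.allclose(back.X, X, atol=1e-12)

    def test_constant_column_rejected(self):
        X = np.ones((4, 7))
        X[:, 6] = 0
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(self._matrix(X))

    def test_onehot_sum_enforced(self):
        X = np.ones((3, 7))
        with pytest.raises(ValueError, match="one-hot"):
            FeatureMatrix(X=X, y=np.zeros(3), bounds=np.vstack([X.min(0), X.max(0)]))


class TestSplit:
    def test_sizes_floor(self, noiseless_dataset):
        n = len(noiseless_dataset)
        train, test = split_dataset(noiseless_dataset, 0.7, seed=1)
        assert len(train) == int(np.floor(0.7 * n))
        assert len(train) + len(test) == n

    def test_partition_property(self, noiseless_dataset):
        train, test = split_dataset(noiseless_dataset, 0.5, seed=3)
        ids = lambda ds: {id(r) for r in ds.records}  # noqa: E731
        assert ids(train).isdisjoint(ids(test))
        assert ids(train) | ids(test) == ids(noiseless_dataset)

    def test_deterministic_under_seed(self, noiseless_dataset):
        a = split_dataset(noiseless_dataset, 0.7, seed=11)
        b = split_dataset(noiseless_dataset, 0.7, seed=11)
        assert [r for r in a[0]] == [r for r in b[0]]


class TestIO:
    def test_round_trip(self, noiseless_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        write_dataset(noiseless_dataset, path)
        back = read_dataset(path)
        assert len(back) == len(noiseless_dataset)
        for a, b in zip(back, noiseless_dataset):
            assert a.removal == pytest.approx(b.removal, rel=1e-12)
            assert a.q == pytest.approx(b.q, rel=1e-12)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"antibiotic": ["RIF"], "pH": [2.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="dose_g_per_L"):
            read_dataset(path)

    def test_invalid_removal_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "antibiotic": ["RIF"], "pH": [2.0], "dose_g_per_L": [0.4],
                "time_min": [180], "conc0_mg_per_L": [21.1],
                "temperature_C": [22], "removal_percent": [120.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 0"):
            read_dataset(path)


def test_feature_matrix_shape(noiseless_dataset):
    fm = build_feature_matrix(noiseless_dataset)
    assert fm.X.shape == (len(noiseless_dataset), 7)
    assert np.allclose(fm.X[:, 5] + fm.X[:, 6], 1.0)
    assert np.all((fm.y >= 0) & (fm.y <= 100))
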