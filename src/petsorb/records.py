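"""Data model for batch adsorption experiments.

A batch experiment contacts a known mass of adsorbent (here PET fibers) with
a fixed volume of antibiotic solution.  Two standard figures of merit follow
from the mass balance between the initial concentration ``c0`` and the
residual concentration ``c``:

* adsorption capacity  ``q = (c0 - c) * V / m``      [mg solute / g adsorbent]
* removal percentage   ``R = 100 * (c0 - c) / c0``   [%]

This module houses the record/dataset containers, the mass-balance
arithmetic, the seven-column feature matrix used by the surrogate models
(five continuous process conditions plus a two-column one-hot antibiotic
indicator), min-max normalization with stored invertible bounds, the
train/test split, and CSV round-trip I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANTIBIOTICS = ("RIF", "RIX")

#: column order of the surrogate feature matrix
FEATURE_COLUMNS = (
    "pH",
    "dose",
    "time",
    "c0",
    "temperature",
    "onehot_RIF",
    "onehot_RIX",
)

CSV_COLUMNS = (
    "antibiotic",
    "pH",
    "dose_g_per_L",
    "time_min",
    "conc0_mg_per_L",
    "temperature_C",
    "conc_eq_mg_per_L",
    "capacity_mg_per_g",
    "removal_percent",
)

_REQUIRED_CSV = CSV_COLUMNS[:6]

#: default batch solution volume, L (25 mL flasks)
DEFAULT_VOLUME = 0.025


class DomainError(ValueError):
    """Raised when inputs violate the physical domain of an operation."""


def compute_capacity(c0: float, c: float, volume: float, mass: float) -> float:
    """Adsorption capacity q (mg/g) from the batch mass balance.

    Parameters
    ----------
    c0, c : float
        Initial and residual solute concentration, mg/L.
    volume : float
        Solution volume, L.
    mass : float
        Adsorbent mass, g.
    """
    if mass <= 0 or volume <= 0:
        raise DomainError(f"mass and volume must be positive (mass={mass}, volume={volume})")
    if c < 0 or c > c0:
        raise DomainError(
            f"residual concentration must satisfy 0 <= c <= c0; got c={c}, c0={c0}"
        )
    return (c0 - c) * volume / mass


def capacity_from_removal(removal: float, c0: float, dose: float) -> float:
    """Capacity q (mg/g) from removal % at a given dose (g/L): q = R*c0/(100*dose)."""
    if dose <= 0:
        raise DomainError(f"dose must be positive, got {dose}")
    return removal * c0 / (100.0 * dose)


def compute_removal(c0: float, c: float) -> float:
    """Removal percentage R = 100 * (c0 - c) / c0."""
    if c0 <= 0:
        raise DomainError(f"initial concentration must be positive, got c0={c0}")
    if c < 0 or c > c0:
        raise DomainError(
            f"residual concentration must satisfy 0 <= c <= c0; got c={c}, c0={c0}"
        )
    return 100.0 * (c0 - c) / c0


def one_hot(antibiotic: str) -> tuple[int, int]:
    """One-hot indicator pair (RIF, RIX) for the antibiotic category."""
    if antibiotic == "RIF":
        return (1, 0)
    if antibiotic == "RIX":
        return (0, 1)
    raise ValueError(f"unknown antibiotic label {antibiotic!r}; expected one of {ANTIBIOTICS}")


@dataclass(frozen=True)
class AdsorptionRecord:
    """One batch adsorption experiment: conditions plus measured outcomes.

    ``c_eq`` (residual concentration, mg/L), ``q`` (capacity, mg/g) and
    ``removal`` (%) are optional; when all are present they must be mutually
    consistent with the mass balance to 1e-6 relative.
    """

    antibiotic: str
    pH: float
    dose: float  # g/L
    time: float  # min
    c0: float  # mg/L
    temperature: float  # degrees C
    c_eq: float | None = None
    q: float | None = None
    removal: float | None = None
    volume: float = DEFAULT_VOLUME  # L

    def __post_init__(self) -> None:
        one_hot(self.antibiotic)  # raises for unknown labels
        if not 0.0 <= self.pH <= 14.0:
            raise DomainError(f"pH={self.pH} outside [0, 14]")
        if self.dose <= 0:
            raise DomainError(f"dose={self.dose} must be positive")
        if self.time < 0:
            raise DomainError(f"time={self.time} must be non-negative")
        if self.c0 <= 0:
            raise DomainError(f"c0={self.c0} must be positive")
        if self.volume <= 0:
            raise DomainError(f"volume={self.volume} must be positive")
        if self.c_eq is not None and (self.c_eq < 0 or self.c_eq > self.c0):
            raise DomainError(f"c_eq={self.c_eq} outside [0, c0={self.c0}]")
        if self.q is not None and self.q < 0:
            raise DomainError(f"q={self.q} must be non-negative")
        if self.removal is not None and not 0.0 <= self.removal <= 100.0:
            raise DomainError(f"removal={self.removal} outside [0, 100]")
        self._check_consistency()

    def _check_consistency(self, rtol: float = 1e-6) -> None:
        # mass balance couples the three measured quantities: R = 100*q*dose/c0
        if self.q is not None and self.removal is not None:
            implied = 100.0 * self.q * self.dose / self.c0
            if not np.isclose(implied, self.removal, rtol=rtol, atol=1e-9):
                raise DomainError(
                    f"inconsistent record: q={self.q} and dose={self.dose} imply "
                    f"removal {implied:.6g}, but removal={self.removal}"
                )
        if self.c_eq is not None and self.removal is not None:
            implied = compute_removal(self.c0, self.c_eq)
            if not np.isclose(implied, self.removal, rtol=rtol, atol=1e-9):
                raise DomainError(
                    f"inconsistent record: c_eq={self.c_eq} implies removal "
                    f"{implied:.6g}, but removal={self.removal}"
                )

    @property
    def mass(self) -> float:
        """Adsorbent mass, g, implied by dose and volume."""
        return self.dose * self.volume


@dataclass
class AdsorptionDataset:
    """Ordered collection of :class:`AdsorptionRecord` with provenance metadata."""

    records: list[AdsorptionRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset must contain at least one record")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, antibiotic: str) -> "AdsorptionDataset":
        recs = [r for r in self.records if r.antibiotic == antibiotic]
        return AdsorptionDataset(recs, dict(self.metadata, antibiotic=antibiotic))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "antibiotic": r.antibiotic,
                "pH": r.pH,
                "dose_g_per_L": r.dose,
                "time_min": r.time,
                "conc0_mg_per_L": r.c0,
                "temperature_C": r.temperature,
                "conc_eq_mg_per_L": r.c_eq,
                "capacity_mg_per_g": r.q,
                "removal_percent": r.removal,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


@dataclass
class FeatureMatrix:
    """Seven-feature design matrix for the removal-efficiency surrogate.

    Columns: pH, dose, time, c0, temperature, onehot_RIF, onehot_RIX.
    ``bounds`` stores per-column (min, max) so min-max normalization is an
    exact bijection; one-hot columns are passed through untouched.
    """

    X: np.ndarray
    y: np.ndarray  # removal %, original scale
    bounds: np.ndarray  # shape (2, 7): row 0 mins, row 1 maxs
    normalized: bool = False
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError(f"feature matrix must have {len(self.columns)} columns")
        onehots = self.X[:, 5] + self.X[:, 6]
        if not np.allclose(onehots, 1.0):
            raise ValueError("one-hot indicator columns must sum to 1 per row")

    @property
    def n_continuous(self) -> int:
        return 5


def build_feature_matrix(dataset: AdsorptionDataset) -> FeatureMatrix:
    """Assemble the raw (unnormalized) feature matrix and removal target."""
    rows, targets = [], []
    for r in dataset:
        if r.removal is None:
            raise ValueError("every record needs a removal value to build the feature matrix")
        hot = one_hot(r.antibiotic)
        rows.append([r.pH, r.dose, r.time, r.c0, r.temperature, hot[0], hot[1]])
        targets.append(r.removal)
    X = np.array(rows, dtype=float)
    bounds = np.vstack([X.min(axis=0), X.max(axis=0)])
    return FeatureMatrix(X=X, y=np.array(targets), bounds=bounds, normalized=False)


def minmax_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Map continuous columns onto [0, 1] using the stored bounds.

    The one-hot columns are already binary and are left untouched.  Raises
    for constant continuous columns, which cannot be normalized invertibly.
    """
    if matrix.normalized:
        return matrix
    lo, hi = matrix.bounds[0], matrix.bounds[1]
    span = hi - lo
    for j in range(matrix.n_continuous):
        if span[j] <= 0:
            raise ValueError(
                f"column {matrix.columns[j]!r} is constant; remove it before normalizing"
            )
    X = matrix.X.copy()
    cont = slice(0, matrix.n_continuous)
    X[:, cont] = (X[:, cont] - lo[cont]) / span[cont]
    return FeatureMatrix(
        X=X, y=matrix.y, bounds=matrix.bounds.copy(), normalized=True, columns=matrix.columns
    )


def denormalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Inverse of :func:`minmax_normalize` using the stored bounds."""
    if not matrix.normalized:
        return matrix
    lo, hi = matrix.bounds[0], matrix.bounds[1]
    X = matrix.X.copy()
    cont = slice(0, matrix.n_continuous)
    X[:, cont] = X[:, cont] * (hi[cont] - lo[cont]) + lo[cont]
    return FeatureMatrix(
        X=X, y=matrix.y, bounds=matrix.bounds.copy(), normalized=False, columns=matrix.columns
    )


def normalize_rows(raw: np.ndarray, bounds: np.ndarray, n_continuous: int = 5) -> np.ndarray:
    """Normalize raw feature rows with previously stored bounds (surrogate input path)."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    lo, hi = bounds[0], bounds[1]
    out = raw.copy()
    cont = slice(0, n_continuous)
    out[:, cont] = (out[:, cont] - lo[cont]) / (hi[cont] - lo[cont])
    return out


def split_dataset(
    dataset: AdsorptionDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[AdsorptionDataset, AdsorptionDataset]:
    """Random disjoint train/test partition; train size = floor(n * fraction)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    train_idx, test_idx = sorted(perm[:n_train]), sorted(perm[n_train:])
    meta = dict(dataset.metadata, split_seed=seed, train_fraction=train_fraction)
    train = AdsorptionDataset([dataset.records[i] for i in train_idx], dict(meta, split="train"))
    test = AdsorptionDataset([dataset.records[i] for i in test_idx], dict(meta, split="test"))
    return train, test


def write_dataset(dataset: AdsorptionDataset, path) -> None:
    """Write the dataset as CSV (comma separated, dot decimal, header row)."""
    dataset.to_dataframe().to_csv(path, index=False)


def read_dataset(path) -> AdsorptionDataset:
    """Read a dataset CSV, validating the schema and every record's invariants."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_CSV if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} is missing required columns: {missing}")
    records = []
    for i, row in df.iterrows():
        def opt(col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        try:
            records.append(
                AdsorptionRecord(
                    antibiotic=str(row["antibiotic"]),
                    pH=float(row["pH"]),
                    dose=float(row["dose_g_per_L"]),
                    time=float(row["time_min"]),
                    c0=float(row["conc0_mg_per_L"]),
                    temperature=float(row["temperature_C"]),
                    c_eq=opt("conc_eq_mg_per_L"),
                    q=opt("capacity_mg_per_g"),
                    removal=opt("removal_percent"),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {i} of {path}: {exc}") from exc
    return AdsorptionDataset(records, metadata={"source": str(path)})
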