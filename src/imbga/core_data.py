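"""Core dataset container, imbalance quantification and normalization.

Label convention used throughout the package: ``0`` is the minority class of
interest (the rare clinical outcome — e.g. preterm birth, preeclampsia),
``1`` is the majority class.  The unbalanced ratio (UR) is the majority
count divided by the minority count, so UR > 1 for any imbalanced dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROVENANCE_ORIGINAL = "original"
PROVENANCE_SYNTHETIC = "synthetic_amom"


class DegenerateClassError(ValueError):
    """Raised when an operation needs both classes but one is empty."""


@dataclass
class Dataset:
    """A feature matrix with binary labels.

    Attributes
    ----------
    X : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix.
    y : ndarray of shape (n_samples,)
        Integer labels in {0, 1}; 0 is the minority class of interest.
    feature_names : list of str
        Column names, one per feature.
    provenance : ndarray of str or None
        Optional per-row tag, ``"original"`` or ``"synthetic_amom"``.
    groups : ndarray of int or None
        Optional per-row group id tying oversampled synthetic rows to the
        original sample they interpolate from; CV splitters keep a group in
        a single fold so interpolation copies cannot leak across folds.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    provenance: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"y length {self.y.shape} does not match {self.X.shape[0]} rows of X"
            )
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {self.X.shape[1]} columns"
            )
        extra = set(np.unique(self.y)) - {0, 1}
        if extra:
            raise ValueError(f"labels must be in {{0, 1}}; found {sorted(extra)}")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape != self.y.shape:
                raise ValueError("provenance length must match y")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=int)
            if self.groups.shape != self.y.shape:
                raise ValueError("groups length must match y")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """Return (minority count = #y==0, majority count = #y==1)."""
        return int(np.sum(self.y == 0)), int(np.sum(self.y == 1))

    def copy(self) -> "Dataset":
        return Dataset(
            self.X.copy(),
            self.y.copy(),
            list(self.feature_names),
            None if self.provenance is None else self.provenance.copy(),
            None if self.groups is None else self.groups.copy(),
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_column] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str = "label") -> "Dataset":
        if label_column not in df.columns:
            raise ValueError(
                f"label column {label_column!r} not found; columns: {list(df.columns)}"
            )
        y = df[label_column].to_numpy()
        bad = set(pd.unique(y)) - {0, 1}
        if bad:
            raise ValueError(f"non-binary labels found in {label_column!r}: {sorted(bad)}")
        feats = [c for c in df.columns if c != label_column]
        return cls(df[feats].to_numpy(dtype=float), y.astype(int), feats)


@dataclass
class NormalizationParams:
    """Per-feature min/max learned from training data, reusable on held-out data."""

    fmin: np.ndarray
    fmax: np.ndarray

    def __post_init__(self) -> None:
        self.fmin = np.asarray(self.fmin, dtype=float)
        self.fmax = np.asarray(self.fmax, dtype=float)
        if np.any(self.fmax < self.fmin):
            raise ValueError("per-feature max must be >= min")

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.fmax - self.fmin
        out = np.zeros_like(X, dtype=float)
        ok = span > 0
        out[:, ok] = (X[:, ok] - self.fmin[ok]) / span[ok]
        return out


def compute_ur(dataset: Dataset) -> float:
    """Unbalanced ratio: majority count (y==1) / minority count (y==0).

    Displayed to 3 decimals by convention; the full-precision value is
    returned.  Raises :class:`DegenerateClassError` if either class is empty.
    """
    n_min, n_maj = dataset.class_counts()
    if n_min == 0:
        raise DegenerateClassError("minority class (label 0) is empty; UR undefined")
    if n_maj == 0:
        raise DegenerateClassError("majority class (label 1) is empty; UR undefined")
    return n_maj / n_min


def minmax_normalize(
    dataset: Dataset, params: NormalizationParams | None = None
) -> tuple[Dataset, NormalizationParams]:
    """Rescale each feature to [0, 1] via (v - fmin) / (fmax - fmin).

    A constant feature (fmax == fmin) has zero range and is mapped to 0,
    with a warning.  If ``params`` is given the stored min/max are applied
    (held-out data; values may then fall outside [0, 1]).
    """
    X = dataset.X
    if not np.all(np.isfinite(X)):
        r, c = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(
            f"non-finite value at row {r}, column {dataset.feature_names[c]!r}"
        )
    if params is None:
        fmin = X.min(axis=0)
        fmax = X.max(axis=0)
        params = NormalizationParams(fmin, fmax)
        const = np.nonzero(fmax == fmin)[0]
        if const.size:
            names = [dataset.feature_names[i] for i in const]
            warnings.warn(f"constant feature(s) mapped to 0: {names}", stacklevel=2)
    out = Dataset(
        params.transform(X),
        dataset.y.copy(),
        list(dataset.feature_names),
        None if dataset.provenance is None else dataset.provenance.copy(),
    )
    return out, params


def derive_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight (kg) divided by height (m) squared."""
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if height_m <= 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


def derive_season(month: int) -> int:
    """Ordinal season code 1-4 from calendar month.

    Mar-May = 1 (spring), Jun-Aug = 2, Sep-Nov = 3, Dec-Feb = 4.
    """
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be 1..12, got {month}")
    return {3: 1, 4: 1, 5: 1, 6: 2, 7: 2, 8: 2, 9: 3, 10: 3, 11: 3, 12: 4, 1: 4, 2: 4}[
        int(month)
    ]


def drop_missing(
    df: pd.DataFrame, label_column: str = "label", max_col_missing: float = 0.2
) -> pd.DataFrame:
    """Missing-value policy: drop columns with > ``max_col_missing`` fraction
    missing, then drop any remaining rows with missing values.  Both actions
    are logged."""
    frac = df.drop(columns=[label_column], errors="ignore").isna().mean()
    bad_cols = frac.index[frac > max_col_missing].tolist()
    if bad_cols:
        logger.info("dropping columns with >%.0f%% missing: %s", 100 * max_col_missing, bad_cols)
        df = df.drop(columns=bad_cols)
    n_before = len(df)
    df = df.dropna(axis=0)
    if len(df) < n_before:
        logger.info("dropped %d rows with missing values", n_before - len(df))
    return df


def read_dataset(
    path, label_column: str = "label", dialect: str = "csv"
) -> Dataset:
    """Read a delimited text file (header row required) into a :class:`Dataset`.

    ``dialect`` is "csv" or "tsv".  Labels must be binary {0, 1}; missing
    values are handled by :func:`drop_missing` before validation.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = pd.read_csv(path, sep=sep)
    df = drop_missing(df, label_column=label_column)
    return Dataset.from_frame(df, label_column=label_column)


def write_dataset(
    dataset: Dataset, path, label_column: str = "label", dialect: str = "csv"
) -> None:
    """Write a dataset as delimited text; inverse of :func:`read_dataset`
    up to float text precision."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    dataset.to_frame(label_column).to_csv(path, sep=sep, index=False)
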