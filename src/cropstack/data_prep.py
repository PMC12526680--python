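"""Tabular input handling: CSV reading, min-max scaling, splits and folds.

All features are rescaled to [0, 1] using minima/maxima learned from the
training partition only (fitted per split and per cross-validation fold, never
on held-out rows).  The raw temperature and pH columns are carried alongside
the scaled matrix because the physics penalty is unit-bearing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

__all__ = [
    "FEATURES",
    "LABEL_COLUMN",
    "Dataset",
    "FeatureScaler",
    "FoldPlan",
    "read_samples",
    "fit_scaler",
    "apply_scaler",
    "split_train_test",
    "make_folds",
    "encode_labels",
]

FEATURES = ["N", "P", "K", "temperature", "humidity", "ph", "rainfall"]
LABEL_COLUMN = "label"

# (column, lower bound, upper bound or None) — physical sanity limits per row
_ROW_BOUNDS = [
    ("N", 0.0, None),
    ("P", 0.0, None),
    ("K", 0.0, None),
    ("humidity", 0.0, 100.0),
    ("ph", 0.0, 14.0),
    ("rainfall", 0.0, None),
]


@dataclass
class Dataset:
    """Ordered crop samples (7 features + label) with a canonical class order."""

    df: pd.DataFrame
    class_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValidationError("dataset must be non-empty")
        if not self.class_order:
            self.class_order = sorted(self.df[LABEL_COLUMN].unique())
        present = set(self.df[LABEL_COLUMN].unique())
        if not present <= set(self.class_order):
            raise ValidationError("every label in the data must appear in class_order")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df[LABEL_COLUMN].to_numpy()

    @property
    def features(self) -> pd.DataFrame:
        return self.df[FEATURES]

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """Row subset by positional index, keeping the parent class_order."""
        return Dataset(self.df.iloc[list(indices)].reset_index(drop=True),
                       class_order=list(self.class_order))

    def to_csv(self, path: str | Path) -> None:
        self.df[FEATURES + [LABEL_COLUMN]].to_csv(path, index=False)


def _validate_rows(df: pd.DataFrame, context: str) -> None:
    if df[FEATURES].isna().any().any() or df[LABEL_COLUMN].isna().any():
        bad = int(df[df[FEATURES + [LABEL_COLUMN]].isna().any(axis=1)].index[0])
        raise ParseError(f"{context}: missing value at row {bad}; rows with missing cells are rejected")
    for col, lo, hi in _ROW_BOUNDS:
        vals = df[col].to_numpy()
        mask = vals < lo if hi is None else (vals < lo) | (vals > hi)
        if mask.any():
            row = int(np.argmax(mask))
            bound = f">= {lo}" if hi is None else f"in [{lo}, {hi}]"
            raise ValidationError(
                f"{context}: column {col!r} must be {bound}; row {row} has {vals[row]}"
            )


def read_samples(path: str | Path) -> Dataset:
    """Read a crop-records CSV (columns N, P, K, temperature, humidity, ph,
    rainfall, label — case-insensitive) into a validated :class:`Dataset`."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"dataset file not found: {path}")
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    lower = {c.lower(): c for c in raw.columns}
    missing = [c for c in FEATURES + [LABEL_COLUMN] if c.lower() not in lower]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = pd.DataFrame()
    for col in FEATURES:
        src = raw[lower[col.lower()]]
        numeric = pd.to_numeric(src, errors="coerce")
        bad = numeric.isna() & src.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(f"{path}: non-numeric value {src[row]!r} in column {col!r}, row {row}")
        df[col] = numeric
    df[LABEL_COLUMN] = raw[lower[LABEL_COLUMN]].astype(str)
    _validate_rows(df, str(path))
    return Dataset(df)


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature min/max learned from a training partition.

    ``transform`` maps the training partition into [0, 1]; held-out values may
    fall outside that interval.  Constant features map to 0 by convention.
    """

    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            x = features[list(self.feature_names)].to_numpy(dtype=float)
        else:
            x = np.asarray(features, dtype=float)
        if x.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got {x.shape[1]}"
            )
        span = self.maxs - self.mins
        safe = np.where(span == 0, 1.0, span)
        out = (x - self.mins) / safe
        out[:, span == 0] = 0.0
        return out


def fit_scaler(train: Dataset | pd.DataFrame) -> FeatureScaler:
    """Learn per-feature min/max from the training partition only."""
    df = train.features if isinstance(train, Dataset) else train[FEATURES]
    if len(df) == 0:
        raise ValidationError("cannot fit a scaler on an empty dataset")
    x = df.to_numpy(dtype=float)
    return FeatureScaler(
        feature_names=tuple(FEATURES),
        mins=x.min(axis=0),
        maxs=x.max(axis=0),
    )


def apply_scaler(
    scaler: FeatureScaler, data: Dataset
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled feature matrix plus the untouched raw temperature and pH columns."""
    x = scaler.transform(data.features)
    raw_temp = data.df["temperature"].to_numpy(dtype=float)
    raw_ph = data.df["ph"].to_numpy(dtype=float)
    return x, raw_temp, raw_ph


def encode_labels(labels: Sequence[str], class_order: Sequence[str]) -> np.ndarray:
    """Map string labels to integer indices in class_order."""
    index = {lbl: i for i, lbl in enumerate(class_order)}
    try:
        return np.array([index[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"label {exc.args[0]!r} not in class_order") from None


def split_train_test(
    data: Dataset, test_fraction: float = 0.2, seed: int = 42
) -> tuple[Dataset, Dataset]:
    """Stratified train/test split, reproducible for a fixed seed.

    Classes with a single sample go to the training partition with a warning.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    labels = data.labels
    for cls in data.class_order:
        cls_idx = np.flatnonzero(labels == cls)
        if len(cls_idx) == 0:
            continue
        if len(cls_idx) == 1:
            warnings.warn(
                f"class {cls!r} has a single sample; assigned to train", stacklevel=2
            )
            train_idx.extend(cls_idx.tolist())
            continue
        perm = rng.permutation(cls_idx)
        n_test = int(round(test_fraction * len(cls_idx)))
        n_test = min(max(n_test, 1), len(cls_idx) - 1)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return data.subset(sorted(train_idx)), data.subset(sorted(test_idx))


@dataclass(frozen=True)
class FoldPlan:
    """Stratified k-fold assignment: per-fold (train, validation) index sets."""

    k: int
    seed: int
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __iter__(self):
        return iter(self.folds)


def make_folds(labels: Sequence[str], k: int = 5, seed: int = 42) -> FoldPlan:
    """Stratified k-fold plan: per-class counts across folds differ by <= 1.

    Indices are shuffled within class by a seeded generator, then dealt
    round-robin to folds, so the plan is deterministic for (labels, k, seed).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    offset = 0
    for cls in sorted(np.unique(labels).tolist()):
        cls_idx = np.flatnonzero(labels == cls)
        if len(cls_idx) < k:
            warnings.warn(
                f"class {cls!r} has {len(cls_idx)} < k={k} samples; "
                "folds will be as even as possible",
                stacklevel=2,
            )
        perm = rng.permutation(cls_idx)
        fold_of[perm] = (np.arange(len(perm)) + offset) % k
        offset += len(perm)  # stagger so small classes do not pile into fold 0
    all_idx = np.arange(n)
    folds = tuple(
        (all_idx[fold_of != f], all_idx[fold_of == f]) for f in range(k)
    )
    return FoldPlan(k=k, seed=seed, folds=folds)
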