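"""Confusion matrices, macro metrics, and stratified cross-validated reports.

Precision and recall are computed one-vs-rest per class and macro-averaged
(a ``weighted`` switch exists); accuracy is trace/total.  Cross-validation
reports per-fold metrics with mean and population standard deviation
(ddof=0) over folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .data_prep import Dataset, FoldPlan, make_folds
from .ensemble import BaseLearnerSpec, fit_base, fit_stacking
from .exceptions import ValidationError
from .knowledge_base import PhysicsKnowledgeBase
from .pinn import NetworkConfig, train as train_pinn

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "CVReport",
    "confusion",
    "metrics",
    "cross_validate",
    "PinnModel",
    "BaseModel",
    "StackingEnsembleModel",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count table; rows = true class, columns = predicted class."""

    table: np.ndarray
    class_order: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.table, index=list(self.class_order), columns=list(self.class_order)
        ).to_csv(path)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall}


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred must have equal length")
    index = {lbl: i for i, lbl in enumerate(class_order)}
    table = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValidationError(f"true label {t!r} not in class_order")
        if p not in index:
            raise ValidationError(f"predicted label {p!r} not in class_order")
        table[index[t], index[p]] += 1
    return ConfusionMatrix(table=table, class_order=tuple(class_order))


def metrics(
    cm: ConfusionMatrix, average: Literal["macro", "weighted"] = "macro"
) -> MetricSet:
    """Accuracy, precision and recall from one-vs-rest per-class counts.

    Classes with a zero denominator contribute 0 to the average, with a
    warning.
    """
    table = cm.table
    total = table.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    tp = np.diag(table).astype(float)
    fp = table.sum(axis=0) - tp
    fn = table.sum(axis=1) - tp
    support = table.sum(axis=1).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    if np.any(tp + fp == 0):
        empty = [cm.class_order[i] for i in np.flatnonzero(tp + fp == 0)]
        warnings.warn(
            f"no predicted positives for class(es) {empty}; precision set to 0",
            stacklevel=2,
        )
    if average == "macro":
        w = np.full(len(tp), 1.0 / len(tp))
    elif average == "weighted":
        w = support / total
    else:
        raise ValidationError(f"unknown average {average!r}")
    return MetricSet(
        accuracy=float(tp.sum() / total),
        precision=float((prec * w).sum()),
        recall=float((rec * w).sum()),
    )


@dataclass
class CVReport:
    """Per-fold metrics with mean and population std, plus run provenance."""

    fold_metrics: list[MetricSet]
    k: int
    seed: int
    model_spec: str
    kb_hash: str | None = None
    extra: dict = field(default_factory=dict)

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.fold_metrics])

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def std(self, name: str) -> float:
        return float(self._values(name).std(ddof=0))  # population std over folds

    def summary(self) -> dict:
        return {
            name: {"mean": self.mean(name), "std": self.std(name)}
            for name in ("accuracy", "precision", "recall")
        }

    def to_dict(self) -> dict:
        return {
            "model_spec": self.model_spec,
            "k": self.k,
            "seed": self.seed,
            "kb_hash": self.kb_hash,
            "std_convention": "population (ddof=0)",
            "folds": [m.as_dict() for m in self.fold_metrics],
            "summary": self.summary(),
            **self.extra,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# --- model adapters with a uniform fit/predict contract -------------------


class PinnModel:
    """Adapter: constraint-penalised network as a cross-validatable model."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.fitted = None

    def fit(self, train: Dataset, kb: PhysicsKnowledgeBase | None):
        cfg = self.config
        if cfg.n_classes != train.n_classes:
            cfg = NetworkConfig(**{**cfg.__dict__, "n_classes": train.n_classes})
        self.fitted = train_pinn(train, kb, cfg)
        return self

    def predict(self, data: Dataset) -> np.ndarray:
        return self.fitted.predict(data)


class BaseModel:
    """Adapter: a single base learner as a cross-validatable model."""

    def __init__(self, spec: BaseLearnerSpec, seed: int = 42):
        self.spec = spec
        self.seed = seed
        self.fitted = None

    def fit(self, train: Dataset, kb: PhysicsKnowledgeBase | None):
        self.fitted = fit_base(self.spec, train, kb, seed=self.seed)
        return self

    def predict(self, data: Dataset) -> np.ndarray:
        return self.fitted.predict(data)


class StackingEnsembleModel:
    """Adapter: full stacking ensemble (inner folds built per training set)."""

    def __init__(self, specs: Sequence[BaseLearnerSpec], inner_k: int = 5,
                 seed: int = 42):
        self.specs = list(specs)
        self.inner_k = inner_k
        self.seed = seed
        self.fitted = None

    def fit(self, train: Dataset, kb: PhysicsKnowledgeBase | None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny classes inside inner folds
            folds = make_folds(train.labels, k=self.inner_k, seed=self.seed)
        self.fitted = fit_stacking(self.specs, train, kb, folds, seed=self.seed)
        return self

    def predict(self, data: Dataset) -> np.ndarray:
        return self.fitted.predict(data)


def cross_validate(
    model_factory: Callable[[], object],
    data: Dataset,
    kb: PhysicsKnowledgeBase | None,
    folds: FoldPlan,
    model_spec: str = "model",
) -> CVReport:
    """Fit a fresh model per fold on the train part and score the validation
    part; any per-fold preprocessing (scaling) happens inside the model's own
    ``fit``, so no statistic leaks from validation rows."""
    fold_metrics: list[MetricSet] = []
    for fold_idx, (train_idx, val_idx) in enumerate(folds):
        try:
            model = model_factory()
            model.fit(data.subset(train_idx), kb)
            val = data.subset(val_idx)
            preds = model.predict(val)
            cm = confusion(val.labels, preds, data.class_order)
            fold_metrics.append(metrics(cm))
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed at fold {fold_idx}: {exc}") from exc
    return CVReport(
        fold_metrics=fold_metrics,
        k=folds.k,
        seed=folds.seed,
        model_spec=model_spec,
        kb_hash=kb.sha256() if kb is not None else None,
    )
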