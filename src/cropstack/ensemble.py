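"""Stacking ensemble: tree learners plus the constraint-penalised network as
base estimators, multinomial logistic regression as meta-learner.

Meta-features are out-of-fold class probabilities: for every training row,
each base learner contributes the probability vector predicted by a model that
never saw that row, built from a stratified fold plan.  The meta-learner is
fit on those features; the bases are then refit on the full training set for
inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .data_prep import Dataset, FoldPlan, apply_scaler, encode_labels, fit_scaler
from .exceptions import ValidationError
from .knowledge_base import PhysicsKnowledgeBase, require_coverage
from .pinn import NetworkConfig, fit_network, forward

__all__ = [
    "BASE_KINDS",
    "BaseLearnerSpec",
    "StackedFeatureMatrix",
    "StackingModel",
    "fit_base",
    "build_meta_features",
    "fit_stacking",
    "predict",
    "default_base_specs",
]

BASE_KINDS = ("random_forest", "extra_trees", "gradient_boosted_trees", "pinn")

# Tree defaults follow published tuned values where available, library
# defaults otherwise; all overridable per spec.
_TREE_DEFAULTS = {
    "random_forest": {"n_estimators": 116, "max_depth": 16, "min_samples_split": 10},
    "extra_trees": {"n_estimators": 441, "max_depth": 16, "min_samples_split": 5},
    "gradient_boosted_trees": {
        "n_estimators": 465,
        "learning_rate": 0.0640,
        "max_depth": 7,
    },
}


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One base learner: a kind plus hyperparameter overrides."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in BASE_KINDS:
            raise ValidationError(
                f"unknown base learner kind {self.kind!r}; expected one of {BASE_KINDS}"
            )


def default_base_specs(include_pinn: bool = True) -> list[BaseLearnerSpec]:
    specs = [
        BaseLearnerSpec("random_forest"),
        BaseLearnerSpec("extra_trees"),
        BaseLearnerSpec("gradient_boosted_trees"),
    ]
    if include_pinn:
        specs.append(BaseLearnerSpec("pinn"))
    return specs


class _SklearnBase:
    """Probability-emitting wrapper around a tree classifier.

    Re-indexes predict_proba columns to the full class range in case a
    training partition lacks some class.
    """

    def __init__(self, estimator, n_classes: int):
        self.estimator = estimator
        self.n_classes = n_classes

    def fit(self, x, y_idx, raw_temp=None, raw_ph=None):
        self.estimator.fit(x, y_idx)
        return self

    def predict_proba(self, x, raw_temp=None, raw_ph=None) -> np.ndarray:
        raw = self.estimator.predict_proba(x)
        classes = np.asarray(self.estimator.classes_, dtype=int)
        out = np.zeros((raw.shape[0], self.n_classes))
        out[:, classes] = raw
        return out


class _PinnBase:
    """Network base learner operating on pre-scaled features."""

    def __init__(self, config: NetworkConfig, kb: PhysicsKnowledgeBase):
        self.config = config
        self.kb = kb
        self.state = None

    def fit(self, x, y_idx, raw_temp=None, raw_ph=None):
        if self.config.lambda_physics > 0 and (raw_temp is None or raw_ph is None):
            raise ValidationError("network base with physics penalty needs raw temp/ph")
        self.state, _ = fit_network(x, y_idx, raw_temp, raw_ph, self.kb, self.config)
        return self

    def predict_proba(self, x, raw_temp=None, raw_ph=None) -> np.ndarray:
        if self.state is None:
            raise ValidationError("base learner not fitted")
        return forward(self.state, x)


@dataclass
class FittedBase:
    """One fitted base learner bundled with its scaler and class order."""

    spec: BaseLearnerSpec
    estimator: object
    scaler: object
    class_order: list[str]

    def predict_proba(self, data: Dataset) -> np.ndarray:
        x, raw_t, raw_p = apply_scaler(self.scaler, data)
        return self.estimator.predict_proba(x, raw_t, raw_p)

    def predict(self, data: Dataset) -> np.ndarray:
        probs = self.predict_proba(data)
        return np.array([self.class_order[i] for i in probs.argmax(axis=1)])


def fit_base(
    spec: BaseLearnerSpec,
    train: Dataset,
    kb: PhysicsKnowledgeBase | None,
    seed: int = 42,
) -> FittedBase:
    """Fit one base learner on a dataset (scaling handled internally here;
    inside the stacking machinery scaling is done per fold instead)."""
    scaler = fit_scaler(train)
    x, raw_t, raw_p = apply_scaler(scaler, train)
    y = encode_labels(train.labels, train.class_order)
    est = _make_estimator(spec, len(train.class_order), kb, train.class_order, seed)
    est.fit(x, y, raw_t, raw_p)
    return FittedBase(spec=spec, estimator=est, scaler=scaler,
                      class_order=list(train.class_order))


def _make_estimator(
    spec: BaseLearnerSpec,
    n_classes: int,
    kb: PhysicsKnowledgeBase | None,
    class_order: Sequence[str],
    seed: int,
):
    hp = dict(spec.hyperparameters)
    if spec.kind == "random_forest":
        params = {**_TREE_DEFAULTS[spec.kind], **hp}
        return _SklearnBase(
            RandomForestClassifier(random_state=seed, **params), n_classes
        )
    if spec.kind == "extra_trees":
        params = {**_TREE_DEFAULTS[spec.kind], **hp}
        return _SklearnBase(
            ExtraTreesClassifier(random_state=seed, **params), n_classes
        )
    if spec.kind == "gradient_boosted_trees":
        params = {**_TREE_DEFAULTS[spec.kind], **hp}
        params["max_iter"] = params.pop("n_estimators")
        return _SklearnBase(
            HistGradientBoostingClassifier(random_state=seed, **params), n_classes
        )
    if spec.kind == "pinn":
        if kb is None:
            raise ValidationError("the pinn base learner requires a knowledge base")
        require_coverage(kb, class_order)
        kb_aligned = PhysicsKnowledgeBase(
            [kb.entry(lbl) for lbl in class_order], class_order=list(class_order)
        )
        cfg_kwargs = {
            "n_classes": n_classes,
            "seed": seed,
            "epochs": 120,
            **hp,
        }
        if "hidden_sizes" in cfg_kwargs:
            cfg_kwargs["hidden_sizes"] = tuple(cfg_kwargs["hidden_sizes"])
        return _PinnBase(NetworkConfig(**cfg_kwargs), kb_aligned)
    raise ValidationError(f"unknown base learner kind {spec.kind!r}")


@dataclass
class StackedFeatureMatrix:
    """Out-of-fold class-probability features: shape n x (B*C)."""

    matrix: np.ndarray
    specs: list[BaseLearnerSpec]
    n_classes: int
    fold_plan: FoldPlan

    def block(self, b: int) -> np.ndarray:
        return self.matrix[:, b * self.n_classes : (b + 1) * self.n_classes]


def build_meta_features(
    specs: Sequence[BaseLearnerSpec],
    train: Dataset,
    kb: PhysicsKnowledgeBase | None,
    folds: FoldPlan,
    seed: int = 42,
) -> StackedFeatureMatrix:
    """Fit each base on every fold's train part and predict probabilities on
    its validation part; every row gets exactly one out-of-fold prediction per
    base, assembled in original row order."""
    if not specs:
        raise ValidationError("at least one base learner spec is required")
    n = len(train)
    c = train.n_classes
    y = encode_labels(train.labels, train.class_order)
    matrix = np.full((n, len(specs) * c), np.nan)
    for train_idx, val_idx in folds:
        if len(train_idx) == 0 or len(val_idx) == 0:
            raise ValidationError("degenerate fold with an empty partition")
        sub_train = train.subset(train_idx)
        scaler = fit_scaler(sub_train)
        x_tr, t_tr, p_tr = apply_scaler(scaler, sub_train)
        x_va, t_va, p_va = apply_scaler(scaler, train.subset(val_idx))
        for b, spec in enumerate(specs):
            est = _make_estimator(spec, c, kb, train.class_order, seed)
            est.fit(x_tr, y[train_idx], t_tr, p_tr)
            matrix[val_idx, b * c : (b + 1) * c] = est.predict_proba(x_va, t_va, p_va)
    if np.isnan(matrix).any():
        raise ValidationError("fold plan does not cover every training row")
    return StackedFeatureMatrix(matrix=matrix, specs=list(specs), n_classes=c,
                                fold_plan=folds)


@dataclass
class StackingModel:
    """Fitted stack: refit bases, meta logistic regression, shared class order."""

    specs: list[BaseLearnerSpec]
    bases: list
    meta: LogisticRegression
    scaler: object
    class_order: list[str]
    fold_plan: FoldPlan
    kb_hash: str | None

    def _meta_features(self, data: Dataset) -> np.ndarray:
        x, raw_t, raw_p = apply_scaler(self.scaler, data)
        blocks = [b.predict_proba(x, raw_t, raw_p) for b in self.bases]
        return np.hstack(blocks)

    def predict_proba(self, data: Dataset) -> np.ndarray:
        feats = self._meta_features(data)
        raw = self.meta.predict_proba(feats)
        classes = np.asarray(self.meta.classes_, dtype=int)
        out = np.zeros((feats.shape[0], len(self.class_order)))
        out[:, classes] = raw
        return out

    def predict(self, data: Dataset) -> np.ndarray:
        probs = self.predict_proba(data)
        return np.array([self.class_order[i] for i in probs.argmax(axis=1)])


def fit_stacking(
    specs: Sequence[BaseLearnerSpec],
    train: Dataset,
    kb: PhysicsKnowledgeBase | None,
    folds: FoldPlan,
    seed: int = 42,
    hard_labels: bool = False,
) -> StackingModel:
    """Meta-learner on out-of-fold probabilities; bases refit on all rows."""
    meta_feats = build_meta_features(specs, train, kb, folds, seed=seed)
    features = meta_feats.matrix
    if hard_labels:
        c = meta_feats.n_classes
        hard = np.zeros_like(features)
        for b in range(len(specs)):
            block = features[:, b * c : (b + 1) * c]
            hard[np.arange(len(block)), b * c + block.argmax(axis=1)] = 1.0
        features = hard
    y = encode_labels(train.labels, train.class_order)
    meta = LogisticRegression(max_iter=2000, C=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            meta.fit(features, y)
        except ConvergenceWarning:
            warnings.warn(
                f"meta-learner did not converge within {meta.max_iter} iterations",
                stacklevel=2,
            )
            meta = LogisticRegression(max_iter=2000, C=1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                meta.fit(features, y)
    scaler = fit_scaler(train)
    x, raw_t, raw_p = apply_scaler(scaler, train)
    bases = []
    for spec in specs:
        est = _make_estimator(spec, train.n_classes, kb, train.class_order, seed)
        est.fit(x, y, raw_t, raw_p)
        bases.append(est)
    return StackingModel(
        specs=list(specs),
        bases=bases,
        meta=meta,
        scaler=scaler,
        class_order=list(train.class_order),
        fold_plan=folds,
        kb_hash=kb.sha256() if kb is not None else None,
    )


def predict(model: StackingModel, data: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """(predicted labels, per-row probability vectors)."""
    probs = model.predict_proba(data)
    labels = np.array([model.class_order[i] for i in probs.argmax(axis=1)])
    return labels, probs
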