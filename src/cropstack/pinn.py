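"""Constraint-penalised neural classifier.

A three-layer ReLU network trained with a composite objective:

    total = data + lambda_physics * physics

where ``data`` is mean cross-entropy against the true labels and ``physics``
penalises confidence placed on crops whose temperature/pH optima are far from
the sample's raw measurements:

    penalty[i, c] = 1 - p[i, c] * temp_score_c(t_i) * ph_score_c(ph_i)

The suitability scores come from the knowledge base and are evaluated on raw
physical units; the network itself consumes min-max scaled features.

Training is plain mini-batch Adam implemented in numpy.  Everything —
initialisation, shuffling, updates — is driven by one seeded generator, so a
fixed config reproduces the run bit-for-bit, and lambda_physics = 0 follows
exactly the trajectory of a physics-free network (the penalty gradient is
skipped, not merely zero-weighted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .data_prep import Dataset, FeatureScaler, apply_scaler, encode_labels, fit_scaler
from .exceptions import ValidationError
from .knowledge_base import PhysicsKnowledgeBase, require_coverage

__all__ = [
    "NetworkConfig",
    "LossBreakdown",
    "NetworkState",
    "FittedPinn",
    "init_network",
    "forward",
    "data_loss",
    "physics_loss",
    "total_loss",
    "train",
    "fit_network",
    "predict_proba",
]

_EPS = 1e-12  # probability clip before log

PhysicsMode = Literal["all_crops", "true_class"]


@dataclass(frozen=True)
class NetworkConfig:
    n_features: int = 7
    n_classes: int = 22
    hidden_sizes: tuple[int, int] = (64, 64)
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    lambda_physics: float = 0.1
    physics_mode: PhysicsMode = "all_crops"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_classes < 2:
            raise ValidationError("n_features must be >= 1 and n_classes >= 2")
        if len(self.hidden_sizes) != 2 or any(h < 1 for h in self.hidden_sizes):
            raise ValidationError("hidden_sizes must be two positive integers")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.lambda_physics < 0:
            raise ValidationError("lambda_physics must be >= 0")
        if self.physics_mode not in ("all_crops", "true_class"):
            raise ValidationError(f"unknown physics_mode {self.physics_mode!r}")


@dataclass(frozen=True)
class LossBreakdown:
    """One training step's objective, decomposed."""

    data_loss: float
    physics_loss: float
    lambda_physics: float
    total_loss: float

    def as_dict(self) -> dict:
        return {
            "data_loss": self.data_loss,
            "physics_loss": self.physics_loss,
            "lambda_physics": self.lambda_physics,
            "total_loss": self.total_loss,
        }


@dataclass
class NetworkState:
    """Weights and biases of the three linear layers."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: NetworkConfig

    def copy(self) -> "NetworkState":
        return NetworkState(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.config,
        )


def init_network(config: NetworkConfig) -> NetworkState:
    """Glorot-uniform initialisation, deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sizes = [config.n_features, *config.hidden_sizes, config.n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkState(weights, biases, config)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cached(state: NetworkState, x: np.ndarray):
    w, b = state.weights, state.biases
    z1 = x @ w[0] + b[0]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ w[1] + b[1]
    a2 = np.maximum(z2, 0.0)
    z3 = a2 @ w[2] + b[2]
    return _softmax(z3), (x, a1, a2)


def forward(state: NetworkState, scaled_features: np.ndarray) -> np.ndarray:
    """linear -> ReLU -> linear -> ReLU -> linear -> softmax; rows sum to 1."""
    x = np.atleast_2d(np.asarray(scaled_features, dtype=float))
    if x.shape[1] != state.config.n_features:
        raise ValidationError(
            f"expected {state.config.n_features} features, got {x.shape[1]}"
        )
    probs, _ = _forward_cached(state, x)
    return probs


def data_loss(probs: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean cross-entropy, probabilities clipped to [1e-12, 1] before the log."""
    probs = np.asarray(probs, dtype=float)
    labels_onehot = np.asarray(labels_onehot, dtype=float)
    if probs.shape != labels_onehot.shape:
        raise ValidationError(
            f"probs shape {probs.shape} does not match labels shape {labels_onehot.shape}"
        )
    clipped = np.clip(probs, _EPS, 1.0)
    return float(-(labels_onehot * np.log(clipped)).sum() / probs.shape[0])


def physics_loss(
    probs: np.ndarray,
    raw_temp: np.ndarray,
    raw_ph: np.ndarray,
    kb: PhysicsKnowledgeBase,
    labels_idx: np.ndarray | None = None,
    mode: PhysicsMode = "all_crops",
) -> float:
    """Mean physical-implausibility penalty; always in [0, 1].

    ``all_crops`` averages ``1 - p[i, c] * score[i, c]`` over every sample and
    crop; ``true_class`` restricts to the sample's true crop (requires
    ``labels_idx``).
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    scores = kb.score_matrix(raw_temp, raw_ph)
    if probs.shape != scores.shape:
        raise ValidationError(
            f"probs shape {probs.shape} incompatible with kb/sample shape {scores.shape}"
        )
    if mode == "all_crops":
        return float(np.mean(1.0 - probs * scores))
    if mode == "true_class":
        if labels_idx is None:
            raise ValidationError("true_class mode requires labels_idx")
        rows = np.arange(probs.shape[0])
        return float(np.mean(1.0 - probs[rows, labels_idx] * scores[rows, labels_idx]))
    raise ValidationError(f"unknown physics mode {mode!r}")


def total_loss(data: float, physics: float, lambda_physics: float) -> LossBreakdown:
    if lambda_physics < 0:
        raise ValidationError("lambda_physics must be >= 0")
    return LossBreakdown(
        data_loss=float(data),
        physics_loss=float(physics),
        lambda_physics=float(lambda_physics),
        total_loss=float(data) + float(lambda_physics) * float(physics),
    )


def _grad_logits(
    probs: np.ndarray,
    y_idx: np.ndarray,
    scores: np.ndarray | None,
    lam: float,
    mode: PhysicsMode,
) -> np.ndarray:
    """Gradient of the composite loss with respect to the pre-softmax logits."""
    n, c = probs.shape
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y_idx] = 1.0
    g = (probs - onehot) / n  # cross-entropy through softmax
    if lam > 0 and scores is not None:
        if mode == "all_crops":
            dp = -scores / (n * c)
        else:
            dp = np.zeros_like(probs)
            rows = np.arange(n)
            dp[rows, y_idx] = -scores[rows, y_idx] / n
        # chain rule through softmax: dz = p * (dp - sum_j dp_j p_j)
        g = g + lam * probs * (dp - (dp * probs).sum(axis=1, keepdims=True))
    return g


def fit_network(
    x: np.ndarray,
    y_idx: np.ndarray,
    raw_temp: np.ndarray,
    raw_ph: np.ndarray,
    kb: PhysicsKnowledgeBase | None,
    config: NetworkConfig,
) -> tuple[NetworkState, list[LossBreakdown]]:
    """Train on pre-scaled arrays; returns the state and per-epoch losses.

    ``kb`` may be None only when ``lambda_physics == 0`` (a plain
    cross-entropy network); the recorded physics term is then 0.
    """
    x = np.asarray(x, dtype=float)
    y_idx = np.asarray(y_idx, dtype=int)
    n = x.shape[0]
    lam = config.lambda_physics
    use_physics = lam > 0
    if use_physics and kb is None:
        raise ValidationError("lambda_physics > 0 requires a knowledge base")
    scores = kb.score_matrix(raw_temp, raw_ph) if kb is not None else None

    state = init_network(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    # Adam moments
    params = state.weights + state.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    onehot_all = np.zeros((n, config.n_classes))
    onehot_all[np.arange(n), y_idx] = 1.0
    history: list[LossBreakdown] = []

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            probs, (xb, a1, a2) = _forward_cached(state, x[batch])
            sb = scores[batch] if (use_physics and scores is not None) else None
            gz3 = _grad_logits(probs, y_idx[batch], sb, lam, config.physics_mode)
            w = state.weights
            gw3 = a2.T @ gz3
            gb3 = gz3.sum(axis=0)
            ga2 = gz3 @ w[2].T
            gz2 = ga2 * (a2 > 0)
            gw2 = a1.T @ gz2
            gb2 = gz2.sum(axis=0)
            ga1 = gz2 @ w[1].T
            gz1 = ga1 * (a1 > 0)
            gw1 = xb.T @ gz1
            gb1 = gz1.sum(axis=0)
            grads = [gw1, gw2, gw3, gb1, gb2, gb3]
            t += 1
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1**t)
                vhat = vi / (1 - beta2**t)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        probs_all = forward(state, x)
        d = data_loss(probs_all, onehot_all)
        p_loss = (
            float(np.mean(1.0 - probs_all * scores)) if scores is not None else 0.0
        )
        if scores is not None and config.physics_mode == "true_class":
            rows = np.arange(n)
            p_loss = float(np.mean(1.0 - probs_all[rows, y_idx] * scores[rows, y_idx]))
        breakdown = total_loss(d, p_loss, lam)
        if not np.isfinite(breakdown.total_loss):
            raise ValidationError(
                f"training diverged at epoch {_epoch}: total loss = {breakdown.total_loss}"
            )
        history.append(breakdown)
    return state, history


@dataclass
class FittedPinn:
    """A trained network bundled with its scaler, class order and kb hash."""

    state: NetworkState
    scaler: FeatureScaler
    class_order: list[str]
    kb_hash: str | None
    history: list[LossBreakdown] = field(default_factory=list)

    def predict_proba(self, scaled_features: np.ndarray) -> np.ndarray:
        return forward(self.state, scaled_features)

    def predict_proba_dataset(self, data: Dataset) -> np.ndarray:
        x, _, _ = apply_scaler(self.scaler, data)
        return forward(self.state, x)

    def predict(self, data: Dataset) -> np.ndarray:
        probs = self.predict_proba_dataset(data)
        return np.array([self.class_order[i] for i in probs.argmax(axis=1)])

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "cropstack-pinn",
            "version": 1,
            "config": {
                **{
                    k: getattr(self.state.config, k)
                    for k in (
                        "n_features", "n_classes", "epochs", "learning_rate",
                        "batch_size", "lambda_physics", "physics_mode", "seed",
                    )
                },
                "hidden_sizes": list(self.state.config.hidden_sizes),
            },
            "class_order": self.class_order,
            "kb_hash": self.kb_hash,
            "scaler": {
                "feature_names": list(self.scaler.feature_names),
                "mins": self.scaler.mins.tolist(),
                "maxs": self.scaler.maxs.tolist(),
            },
            "weights": [w.tolist() for w in self.state.weights],
            "biases": [b.tolist() for b in self.state.biases],
        }
        Path(path).write_text(json.dumps(doc) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FittedPinn":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "cropstack-pinn":
            raise ValidationError(f"{path}: not a serialized network")
        cfg_doc = dict(doc["config"])
        cfg_doc["hidden_sizes"] = tuple(cfg_doc["hidden_sizes"])
        config = NetworkConfig(**cfg_doc)
        state = NetworkState(
            [np.array(w) for w in doc["weights"]],
            [np.array(b) for b in doc["biases"]],
            config,
        )
        scaler = FeatureScaler(
            feature_names=tuple(doc["scaler"]["feature_names"]),
            mins=np.array(doc["scaler"]["mins"]),
            maxs=np.array(doc["scaler"]["maxs"]),
        )
        return cls(
            state=state,
            scaler=scaler,
            class_order=list(doc["class_order"]),
            kb_hash=doc.get("kb_hash"),
        )


def train(
    train_data: Dataset,
    kb: PhysicsKnowledgeBase | None,
    config: NetworkConfig,
) -> FittedPinn:
    """Fit on a dataset: scales features internally (min-max on this data),
    feeds raw temperature/pH to the penalty, and records per-epoch losses."""
    class_order = list(train_data.class_order)
    if config.n_classes != len(class_order):
        raise ValidationError(
            f"config.n_classes={config.n_classes} but data has {len(class_order)} classes"
        )
    if kb is not None:
        require_coverage(kb, class_order)
        # score columns must follow the data's class order; drop unused crops
        kb_aligned = PhysicsKnowledgeBase(
            [kb.entry(lbl) for lbl in class_order], class_order=class_order
        )
    else:
        kb_aligned = None
        if config.lambda_physics > 0:
            raise ValidationError("lambda_physics > 0 requires a knowledge base")
    scaler = fit_scaler(train_data)
    x, raw_t, raw_p = apply_scaler(scaler, train_data)
    y_idx = encode_labels(train_data.labels, class_order)
    state, history = fit_network(x, y_idx, raw_t, raw_p, kb_aligned, config)
    return FittedPinn(
        state=state,
        scaler=scaler,
        class_order=class_order,
        kb_hash=kb.sha256() if kb is not None else None,
        history=history,
    )


def predict_proba(model: FittedPinn, scaled_features: np.ndarray) -> np.ndarray:
    """Deterministic forward pass on pre-scaled features."""
    return model.predict_proba(scaled_features)
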