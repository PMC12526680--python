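"""Class-conditional synthetic crop datasets.

Generates balanced tabular datasets with the structure the downstream models
assume: temperature and pH clustered at each crop's optimum (as recorded in a
knowledge base), and the remaining features drawn from class-specific
truncated normals whose centres are spread across classes.

Randomness comes from a single integer seed; per-class sub-streams are derived
from a digest of the crop label, so a class's draws do not depend on how many
other classes are generated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data_prep import FEATURES, LABEL_COLUMN, Dataset
from .exceptions import ValidationError
from .knowledge_base import CropPhysicsEntry, PhysicsKnowledgeBase, require_coverage

__all__ = [
    "DEFAULT_CROP_NAMES",
    "SyntheticConfig",
    "make_default_knowledge_base",
    "generate",
    "corrupt",
]

# Label vocabulary shared with the shipped default knowledge base.
DEFAULT_CROP_NAMES = [
    "apple", "banana", "blackgram", "chickpea", "coconut", "coffee", "cotton",
    "grapes", "jute", "kidneybeans", "lentil", "maize", "mango", "mothbeans",
    "mungbean", "muskmelon", "orange", "papaya", "pigeonpeas", "pomegranate",
    "rice", "watermelon",
]

# (low, high) generation ranges for the non-physics features
_FEATURE_RANGES = {
    "N": (0.0, 140.0),
    "P": (5.0, 145.0),
    "K": (5.0, 205.0),
    "humidity": (14.0, 100.0),
    "rainfall": (20.0, 300.0),
}
_NON_PHYSICS = list(_FEATURE_RANGES)

_TEMP_RANGE = (15.0, 35.0)
_PH_RANGE = (5.0, 7.5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator.

    ``separation`` scales the between-class distance of the non-physics
    features relative to their within-class spread; ``noise_scale`` scales the
    within-class spread itself; ``physics_fidelity`` multiplies the
    knowledge-base sigmas to set how tightly temperature/pH cluster at each
    crop's optimum.
    """

    n_classes: int = 22
    samples_per_class: int = 100
    separation: float = 3.0
    noise_scale: float = 1.0
    physics_fidelity: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.samples_per_class < 1:
            raise ValidationError("samples_per_class must be >= 1")
        if self.separation <= 0 or self.noise_scale <= 0 or self.physics_fidelity <= 0:
            raise ValidationError(
                "separation, noise_scale and physics_fidelity must be > 0"
            )


def _class_names(n_classes: int) -> list[str]:
    if n_classes <= len(DEFAULT_CROP_NAMES):
        return DEFAULT_CROP_NAMES[:n_classes]
    return [f"crop_{i:03d}" for i in range(n_classes)]


def _label_digest(label: str) -> int:
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")


def make_default_knowledge_base(
    n_classes: int = 22,
    seed: int = 42,
    sigma_temp_range: tuple[float, float] = (0.6, 1.2),
    sigma_ph_range: tuple[float, float] = (0.10, 0.22),
) -> PhysicsKnowledgeBase:
    """Seeded synthetic optimum table: mu_temp spread over 15-35 degrees C and
    mu_ph over 5.0-7.5, assigned to crops by independent permutations so the
    (temperature, pH) pair jointly separates classes.  Narrower sigma ranges
    make the optima more discriminative between neighbouring crops."""
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    names = sorted(_class_names(n_classes))
    rng = np.random.default_rng(seed)
    t_lo, t_hi = _TEMP_RANGE
    p_lo, p_hi = _PH_RANGE
    mu_temp = np.linspace(t_lo, t_hi, n_classes)[rng.permutation(n_classes)]
    mu_ph = np.linspace(p_lo, p_hi, n_classes)[rng.permutation(n_classes)]
    sigma_temp = rng.uniform(*sigma_temp_range, size=n_classes)
    sigma_ph = rng.uniform(*sigma_ph_range, size=n_classes)
    entries = [
        CropPhysicsEntry(
            crop_label=names[i],
            mu_temp=float(mu_temp[i]),
            sigma_temp=float(sigma_temp[i]),
            mu_ph=float(mu_ph[i]),
            sigma_ph=float(sigma_ph[i]),
        )
        for i in range(n_classes)
    ]
    return PhysicsKnowledgeBase(entries)


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate(config: SyntheticConfig, kb: PhysicsKnowledgeBase) -> Dataset:
    """Draw a balanced class-conditional dataset consistent with the kb.

    Per class: temperature ~ N(mu_temp, physics_fidelity * sigma_temp),
    pH ~ N(mu_ph, physics_fidelity * sigma_ph) truncated to [0, 14]; the
    remaining features come from truncated normals on per-class centres laid
    out on a permuted grid, with spread = grid spacing * noise_scale /
    separation.
    """
    names = sorted(_class_names(config.n_classes))
    require_coverage(kb, names)
    c = config.n_classes
    # per-feature class centre assignment, deterministic in the seed
    centres: dict[str, np.ndarray] = {}
    for feat in _NON_PHYSICS:
        lo, hi = _FEATURE_RANGES[feat]
        frng = np.random.default_rng([config.seed, _label_digest(feat)])
        centres[feat] = np.linspace(lo, hi, c)[frng.permutation(c)]
    frames = []
    for ci, name in enumerate(names):
        entry = kb.entry(name)
        rng = np.random.default_rng([config.seed, _label_digest(name)])
        n = config.samples_per_class
        cols: dict[str, np.ndarray] = {}
        for feat in _NON_PHYSICS:
            lo, hi = _FEATURE_RANGES[feat]
            spacing = (hi - lo) / max(c - 1, 1)
            sd = spacing * config.noise_scale / config.separation
            cols[feat] = _truncated_normal(rng, centres[feat][ci], sd, lo, hi, n)
        cols["temperature"] = rng.normal(
            entry.mu_temp, config.physics_fidelity * entry.sigma_temp, size=n
        )
        cols["ph"] = _truncated_normal(
            rng, entry.mu_ph, config.physics_fidelity * entry.sigma_ph, 0.0, 14.0, n
        )
        cols[LABEL_COLUMN] = np.repeat(name, n)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)[FEATURES + [LABEL_COLUMN]]
    return Dataset(df, class_order=names)


def corrupt(
    data: Dataset, label_noise: float = 0.0, feature_noise: float = 0.0, seed: int = 0
) -> Dataset:
    """Perturb a dataset: flip an exact fraction of labels to a uniformly
    random other class, and jitter the non-physics features with zero-mean
    Gaussian noise scaled by ``feature_noise`` times each column's spread."""
    if not 0 <= label_noise < 1:
        raise ValidationError("label_noise must be in [0, 1)")
    if feature_noise < 0:
        raise ValidationError("feature_noise must be >= 0")
    df = data.df.copy()
    rng = np.random.default_rng(seed)
    n = len(df)
    n_flip = int(round(label_noise * n))
    if n_flip:
        order = list(data.class_order)
        flip_idx = rng.choice(n, size=n_flip, replace=False)
        labels = df[LABEL_COLUMN].to_numpy().copy()
        for i in flip_idx:
            others = [c for c in order if c != labels[i]]
            labels[i] = others[rng.integers(len(others))]
        df[LABEL_COLUMN] = labels
    if feature_noise > 0:
        for feat in _NON_PHYSICS:
            lo, hi = _FEATURE_RANGES[feat]
            sd = feature_noise * float(df[feat].std(ddof=0))
            if sd > 0:
                vals = df[feat].to_numpy(dtype=float) + rng.normal(0.0, sd, size=n)
                df[feat] = np.clip(vals, lo, hi)
    return Dataset(df, class_order=list(data.class_order))
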