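import numpy as np
import pandas as pd
import pytest

from cropstack.data_prep import FEATURES, Dataset
from cropstack.knowledge_base import CropPhysicsEntry, PhysicsKnowledgeBase
from cropstack.synthetic import SyntheticConfig, generate, make_default_knowledge_base


@pytest.fixture
def two_crop_kb() -> PhysicsKnowledgeBase:
    return PhysicsKnowledgeBase(
        [
            CropPhysicsEntry("rice", mu_temp=25.0, sigma_temp=3.0, mu_ph=6.0, sigma_ph=0.5),
            CropPhysicsEntry("maize", mu_temp=22.0, sigma_temp=2.0, mu_ph=6.5, sigma_ph=0.4),
        ]
    )


@pytest.fixture
def toy_dataset() -> Dataset:
    rows = [
        [90, 42, 43, 20.8, 82.0, 6.5, 202.9, "rice"],
        [85, 58, 41, 21.7, 80.3, 7.0, 226.6, "rice"],
        [60, 55, 44, 23.0, 82.3, 7.8, 263.9, "maize"],
        [74, 35, 40, 26.4, 80.1, 6.9, 242.8, "maize"],
    ]
    df = pd.DataFrame(rows, columns=FEATURES + ["label"])
    return Dataset(df)


@pytest.fixture(scope="session")
def small_synth():
    """5 classes x 30 samples, well separated — shared across model tests."""
    kb = make_default_knowledge_base(5, seed=7)
    cfg = SyntheticConfig(n_classes=5, samples_per_class=30, separation=4.0, seed=7)
    return generate(cfg, kb), kb


@pytest.fixture
def rng():
    return np.random.default_rng(0)
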