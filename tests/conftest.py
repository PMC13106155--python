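import numpy as np
import pytest
from hypothesis import settings

import swinatt as sa

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_items():
    """Default 56x56 phantom dataset shared across training tests."""
    return sa.generate_synthetic_dataset(sa.SyntheticSpec(image_size=56, seed=7))


@pytest.fixture(scope="session")
def desk_split(desk_items):
    return sa.patient_level_split(desk_items, seed=7)


@pytest.fixture(scope="session")
def trained_desk_model(desk_split):
    """One trained desk-scale model reused by evaluation-oriented tests."""
    model = sa.SwinTransformer(sa.SwinConfig.desk(), seed=7)
    cfg = sa.desk_train_config(seed=7, epochs=10)
    model, log = sa.fit(model, desk_split, cfg)
    return model, log, cfg
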