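import numpy as np
import pytest

from mtmask.io_core import split_trials
from mtmask.model import ModelConfig
from mtmask.synthetic import SimConfig, generate_session
from mtmask.training import TrainConfig


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Two small regions, short trials: enough structure to exercise every path."""
    return SimConfig(
        n_sessions=1,
        n_trials=24,
        n_bins=12,
        regions=[("A", 6), ("B", 6)],
        cross_region_coupling=np.array([[0.5, 0.2], [0.2, 0.5]]),
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    return generate_session(tiny_config, 0)


@pytest.fixture(scope="session")
def tiny_split(tiny_session):
    return split_trials(tiny_session.n_trials, seed=0)


@pytest.fixture
def tiny_model_config() -> ModelConfig:
    return ModelConfig(d_model=16, n_layers=1, n_heads=2, ffn_dim=32, max_bins=16)


@pytest.fixture
def tiny_train_config() -> TrainConfig:
    return TrainConfig(epochs=2, batch_size=8, seed=0, eval_every=1, k_active=5)
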