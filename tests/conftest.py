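import numpy as np
import pytest
from hypothesis import settings

from attnbind.network import ModelConfig, init_params

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small architecture used across unit tests (t = 6)."""
    return ModelConfig(seq_length=30, kernel_len=5, n_kernels=6, pool_window=4,
                       lstm_hidden=5, fc_dim=7, n_tasks=3)


@pytest.fixture
def tiny_params(tiny_config):
    return init_params(tiny_config, np.random.default_rng(0), dtype=np.float64)
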