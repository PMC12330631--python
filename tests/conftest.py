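import numpy as np
import pytest

from swmphot.microcircuit import NetworkConfig
from swmphot.synth import GeneratorParams


@pytest.fixture
def short_config():
    """1-second microcircuit config for fast unit tests."""
    return NetworkConfig(duration_s=1.0, stim_window_s=(0.2, 0.4))


@pytest.fixture
def quiet_config():
    """Config with all stochastic drives silenced."""
    cfg = NetworkConfig(duration_s=0.5, stim_window_s=(0.1, 0.2),
                        stim_rate_hz=0.0, vhpc_noise_rate_hz=0.0)
    cfg.neuron_noise["rate_hz"] = 0.0
    return cfg


@pytest.fixture
def gen_params():
    return GeneratorParams()


@pytest.fixture
def null_effects():
    return {k: 0.0 for k in ("outcome", "training", "training:outcome",
                             "group", "training:group")}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
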