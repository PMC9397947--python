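import numpy as np
import pytest
from hypothesis import settings

from handrim.config import SimulationConfig
from handrim.synthetic import simulate_ergometer_block

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_cfg() -> SimulationConfig:
    """One-minute friction-balanced block, no noise, 1 Hz pushes."""
    return SimulationConfig(seed=11, block_duration=60.0, noise_sd_force=0.0,
                            noise_sd_breath=0.0, marker_noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_block(clean_cfg):
    return simulate_ergometer_block(clean_cfg)


@pytest.fixture(scope="session")
def noisy_block():
    cfg = SimulationConfig(seed=12, block_duration=60.0)
    return simulate_ergometer_block(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
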