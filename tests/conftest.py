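import numpy as np
import pytest

from enosecast import SimulationConfig


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def quiet_config(default_config) -> SimulationConfig:
    """Noise-free variant of the default study."""
    return default_config.with_noise(daily_frac=0.0, session_frac=0.0)


@pytest.fixture(scope="session")
def small_dataset(default_config):
    """A 30-sample dataset shared by classifier/IO tests (cheap to build)."""
    from enosecast import generate_dataset

    return generate_dataset(default_config, n_samples=30, seed=11)
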