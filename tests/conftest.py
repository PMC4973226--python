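import numpy as np
import pytest

from tmsalpha import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale session: few trials, short rest, default dynamics."""
    return SimulationConfig(seed=101, n_trials_target=12, rest_duration=60.0)


@pytest.fixture(scope="session")
def small_session(small_config):
    """One generated closed-loop session shared across read-only tests."""
    rec, truth = simulate_session(small_config, "MPFC")
    return rec, truth


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    """Noise-free generator: pure alpha + responses, no outlier trials."""
    return SimulationConfig(
        seed=202, n_trials_target=8, noise_sd=0.0, outlier_rate=0.0,
        rest_duration=60.0,
    )


@pytest.fixture(scope="session")
def noiseless_session(noiseless_config):
    rec, truth = simulate_session(noiseless_config, "MPFC")
    return rec, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
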