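import numpy as np
import pytest

from insolegrf import GaitConfig, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_gait_config():
    """A short trapezoidal walking protocol (fast to generate and fit)."""
    return GaitConfig(
        speed_profile=((2.5, 10.0), (3.0, 10.0), (3.5, 10.0), (3.0, 10.0), (2.5, 10.0)),
        sample_rate=50.0,
    )


@pytest.fixture(scope="session")
def short_trial(short_gait_config):
    trial, truth = generate_trial(short_gait_config, seed=7)
    return trial, truth
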