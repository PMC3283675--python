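import numpy as np
import pytest
from hypothesis import settings

from rbctweezers import Chamber, Medium, NoiseModel, standard_schedule

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def medium():
    """Blood-serum medium with the published constants."""
    return Medium()


@pytest.fixture(scope="session")
def chamber():
    """Default chamber: d = 1 cm, Z1 = Z2 = 50 um."""
    return Chamber()


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel(velocity_rel_sd=0.0, position_noise_sd=0.0, length_noise_sd=0.0)


@pytest.fixture(scope="session")
def schedule():
    return standard_schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
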