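import numpy as np
import pytest

from aquarad.spectra import DEFAULT_GRID
from aquarad.synthetic import default_instrument, generate_campaign


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def noiseless_instrument():
    return default_instrument(noise_sd_fraction=0.0)


@pytest.fixture(scope="session")
def noiseless_campaign(noiseless_instrument):
    """6 sites, 31 stations, zero instrument noise."""
    return generate_campaign(seed=123, inst=noiseless_instrument)


@pytest.fixture(scope="session")
def noisy_campaign():
    """6 sites, 31 stations, 1% multiplicative count noise."""
    return generate_campaign(seed=123, inst=default_instrument(noise_sd_fraction=0.01))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
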