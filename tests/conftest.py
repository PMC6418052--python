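import numpy as np
import pytest

from volespace.simulate import (
    SignalNoiseModel,
    make_site,
    simulate_voles,
)


@pytest.fixture(scope="session")
def site():
    return make_site(seed=2)


@pytest.fixture(scope="session")
def noiseless():
    return SignalNoiseModel(repeat_noise_sd=0.0)


@pytest.fixture(scope="session")
def voles(site):
    return simulate_voles(site, 12, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
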