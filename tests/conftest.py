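import numpy as np
import pytest

from aslbs import AcquisitionConfig, make_phantom

# short excitation TR: the 9/20-degree pair straddles the Ernst angle there,
# which is what makes the two-point fit well conditioned under noise
VFA_TR_MS = 15.0


@pytest.fixture(scope="session")
def clean_config():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def vfa_config():
    return AcquisitionConfig(tr=VFA_TR_MS, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def phantom_small():
    return make_phantom(shape=(16, 16, 12))


@pytest.fixture(scope="session")
def phantom_default():
    return make_phantom(shape=(32, 32, 16))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
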