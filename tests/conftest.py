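import numpy as np
import pytest

import randgen as rg
from randgen import abc_compare as ac


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gauss_domain():
    return rg.heights_gaussian()


@pytest.fixture(scope="session")
def uniform_domain():
    return rg.heights_uniform()


@pytest.fixture(scope="session")
def line7_domain():
    return rg.syllables("line7")


@pytest.fixture(scope="session")
def hex7_domain():
    return rg.syllables("hex7")


# Desk-scale recovery experiments (2000 train / 500 test per model, length
# 400) are expensive, so they are built once per session and shared between
# the recovery-rate checks and the forest property tests.

@pytest.fixture(scope="session")
def uniform_recovery():
    return ac.model_recovery(rg.MODELS, rg.heights_uniform(),
                             n_train=2000, n_test=500, length=400, seed=20)


@pytest.fixture(scope="session")
def gauss_recovery():
    return ac.model_recovery(rg.MODELS, rg.heights_gaussian(),
                             n_train=2000, n_test=500, length=400, seed=21)
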