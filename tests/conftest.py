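import numpy as np
import pytest

from pursuitnet import ArenaConfig, RTParams, default_ct_params


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


@pytest.fixture(scope="session")
def periodic_arena():
    return ArenaConfig(boundary="periodic")


@pytest.fixture(scope="session")
def rt_params():
    return RTParams()


@pytest.fixture(scope="session")
def ct_params(arena):
    return default_ct_params(arena)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
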