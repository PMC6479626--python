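import numpy as np
import pytest

from fsabm import EnvironmentConfig, generate_households


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_env():
    return EnvironmentConfig()


@pytest.fixture
def small_env():
    """A scaled-down population for fast simulation tests."""
    return EnvironmentConfig(n_households=600)


@pytest.fixture
def households(default_env):
    return generate_households(default_env, seed=7)
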