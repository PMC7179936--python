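import numpy as np
import pytest

from proclean.params import cleaner_params, default_config, producer_params


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def producer_wt(cfg):
    """Producer parameters without heterologous production (wild-type-like)."""
    return producer_params(cfg, Y_h=0.0)


@pytest.fixture(scope="session")
def producer(cfg):
    """Producer parameters at the default product yield Y_h = 0.2."""
    return producer_params(cfg, Y_h=0.2)


@pytest.fixture(scope="session")
def cleaner(cfg):
    return cleaner_params(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
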