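import numpy as np
import pytest

from fpcalib import SimConfig, get_fp_properties


@pytest.fixture(scope="session")
def mcherry():
    return get_fp_properties("mcherry")


@pytest.fixture(scope="session")
def gfp():
    return get_fp_properties("gfpmut3")


@pytest.fixture(scope="session")
def fluorescein():
    return get_fp_properties("fluorescein")


@pytest.fixture
def noiseless_cfg():
    return SimConfig(seed=1, od_noise_sd=0.0, rfu_cv=0.0, growth_od_noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
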