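import numpy as np
import pytest

from burstgtm import GTMParameters

# the two gamma-dwell parameter sets used throughout as worked examples:
# a bimodal regime (k_off=3, r_off=0.5, k_on=2, r_on=0.5, r_syn=20) and a
# unimodal one (k_off=5, r_off=3, k_on=1, r_on=0.8, r_syn=30), r_deg=1
BIMODAL_THETA = (3.0, 0.5, 2.0, 0.5, 20.0)
UNIMODAL_THETA = (5.0, 3.0, 1.0, 0.8, 30.0)


@pytest.fixture
def bimodal_params() -> GTMParameters:
    return GTMParameters.from_gamma(*BIMODAL_THETA)


@pytest.fixture
def unimodal_params() -> GTMParameters:
    return GTMParameters.from_gamma(*UNIMODAL_THETA)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230405)
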