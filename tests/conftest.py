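import numpy as np
import pytest

from leafhydraulics import ContinuousLeaf, UniformLeafParams, build_uniform_chain

# whole-leaf parameter set used across the canned experiments:
# psi0 = 0 MPa, psi_a = -100 MPa, R = 2, Ra = 50 MPa·m²·s·mmol⁻¹
WELL_WATERED = dict(R=2.0, Ra=50.0, psi0=0.0, psi_a=-100.0)

# (C, Rc) pairs exercised in the excised-leaf experiment
EXCISED_PAIRS = [(30.0, 1.0), (30.0, 50.0), (120.0, 1.0), (120.0, 50.0)]


@pytest.fixture
def table_params():
    return UniformLeafParams(N=100, **WELL_WATERED)


@pytest.fixture
def table_chain(table_params):
    return build_uniform_chain(table_params)


@pytest.fixture
def table_leaf():
    return ContinuousLeaf(**WELL_WATERED)


@pytest.fixture
def storage_params():
    return UniformLeafParams(N=100, Rc=1.0, C=30.0, **WELL_WATERED)


@pytest.fixture
def rng():
    return np.random.default_rng(20211014)
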