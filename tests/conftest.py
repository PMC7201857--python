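import numpy as np
import pytest

from virorad import ModelParameters, RadialGrid


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def grid(params):
    return RadialGrid(params.r_b, params.r_outer, 41)


@pytest.fixture
def rng():
    return np.random.default_rng(20200412)
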