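import numpy as np
import pytest

from rheoref.geometry import DWRGeometry, ProbeDynamics, WATER


@pytest.fixture(scope="session")
def geom():
    return DWRGeometry()


@pytest.fixture(scope="session")
def dyn(geom):
    return ProbeDynamics.from_geometry(1.0e-5, geom)


@pytest.fixture(scope="session")
def water():
    return WATER


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
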