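import numpy as np
import pytest

from lungfate.params import FieldGeometry
from lungfate.synthetic import make_vessels


@pytest.fixture(scope="session")
def geometry() -> FieldGeometry:
    return FieldGeometry(field_size_um=256.0)


@pytest.fixture(scope="session")
def vessels(geometry):
    return make_vessels(geometry, np.random.default_rng(7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
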