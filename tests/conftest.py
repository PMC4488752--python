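import numpy as np
import pytest

from nucleomc import Spherocylinder
from nucleomc.pipeline import make_fixture


@pytest.fixture(scope="session")
def cell():
    """The reference cell: 350 nm radius, 3.0 um pole-to-pole."""
    return Spherocylinder(350.0, 3000.0)


@pytest.fixture(scope="session")
def half_cell():
    return Spherocylinder(350.0, 1500.0)


@pytest.fixture(scope="session")
def tiny_model():
    """Deterministic ~220-particle DNA + polysome system."""
    return make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def small_model():
    """~1300-particle DNA + polysome system in a short cell."""
    return make_fixture("small", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
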