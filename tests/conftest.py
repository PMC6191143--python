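import numpy as np
import pytest

from electrodiff import PhysicalConstants, PorousMedium, default_ion_set
from electrodiff.applications import binary_ion_set


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def porous():
    return PorousMedium()


@pytest.fixture(scope="session")
def ecs_ions():
    """Packaged four-species ECS composition (Na+, K+, X-, Ca2+)."""
    return default_ion_set()


@pytest.fixture(scope="session")
def nax_ions():
    """Binary Na+/X- salt used by the 1-D step runs."""
    return binary_ion_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
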