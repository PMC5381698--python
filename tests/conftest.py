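import numpy as np
import pytest

from quatlock import make_assembly, make_subunit
from quatlock.structure_io import RegionDefinition


@pytest.fixture(scope="session")
def subunit():
    return make_subunit(seed=1, n_residues=30)


@pytest.fixture(scope="session")
def c4_assembly(subunit):
    return make_assembly(subunit, "Cn", 4)


@pytest.fixture(scope="session")
def d4_assembly(subunit):
    return make_assembly(subunit, "Dn", 4)


@pytest.fixture
def mobile_region():
    return RegionDefinition("mobile", ((20, 25),))


@pytest.fixture
def stable_region():
    return RegionDefinition("stable", ((1, 19), (26, 30)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
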