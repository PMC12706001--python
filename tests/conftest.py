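import numpy as np
import pytest

from dyn2lattice import ForceField, LatticeSpec
from dyn2lattice.lattice import build_lattice, make_site_grid
from dyn2lattice.synthetic import assemble_toy_system


@pytest.fixture(scope="session")
def lattice_spec():
    return LatticeSpec()


@pytest.fixture(scope="session")
def y_lattice(lattice_spec):
    return build_lattice(lattice_spec)


@pytest.fixture(scope="session")
def site_grid(lattice_spec):
    return make_site_grid(lattice_spec)


@pytest.fixture(scope="session")
def ff():
    return ForceField()


@pytest.fixture(scope="session")
def toy_system_y(ff):
    return assemble_toy_system("Y", 2, ff=ff)


@pytest.fixture(scope="session")
def toy_system_dy(ff):
    return assemble_toy_system("dY", 2, ff=ff)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
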