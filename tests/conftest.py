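import numpy as np
import pytest

from icnma import elastic_network as enm
from icnma import fixtures as fx
from icnma import internal_coords as ic
from icnma import nma_core as nc


@pytest.fixture(scope="session")
def helix10():
    return fx.make_helix(10)


@pytest.fixture(scope="session")
def helix10_nma(helix10):
    """(structure, network, dofs, torsional system, 10 lowest modes)."""
    net = enm.build_network(helix10)
    dofs = ic.define_dofs(helix10)
    system = ic.assemble(helix10, net, dofs)
    modes = nc.solve_modes(system, m=10)
    return helix10, net, dofs, system, modes


@pytest.fixture(scope="session")
def hinge12():
    return fx.make_hinge_pair(12, 40.0)


@pytest.fixture(scope="session")
def hinge12_nma(hinge12):
    src, _ = hinge12
    net = enm.build_network(src)
    dofs = ic.define_dofs(src)
    system = ic.assemble(src, net, dofs)
    modes = nc.solve_modes(system, m=15)
    return src, net, dofs, system, modes


@pytest.fixture(scope="session")
def rigid_field():
    return fx.make_two_rigid_field(12, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
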