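import numpy as np
import pytest

from genff.analysis import FIXTURE_NAMES, generate_fixture
from genff.engine import ForceField
from genff.params import default_table
from genff.topology import perceive_topology


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def molecules():
    return {name: generate_fixture(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def topologies(molecules, table):
    return {name: perceive_topology(mol, table) for name, mol in molecules.items()}


@pytest.fixture(scope="session")
def forcefields(molecules, table, topologies):
    return {
        name: ForceField(mol, table, topologies[name])
        for name, mol in molecules.items()
    }


def fd_gradient(fun, xyz, step=1e-5):
    """Central finite-difference gradient of a scalar function of (N,3)."""
    xyz = np.asarray(xyz, float)
    g = np.zeros_like(xyz)
    for a in range(xyz.shape[0]):
        for d in range(3):
            xp = xyz.copy()
            xp[a, d] += step
            xm = xyz.copy()
            xm[a, d] -= step
            g[a, d] = (fun(xp) - fun(xm)) / (2.0 * step)
    return g
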