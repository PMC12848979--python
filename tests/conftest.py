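import numpy as np
import pytest

from aipmap import (
    MoleculeGraph,
    SolventModel,
    make_toy_fragment_library,
)
from aipmap.aip_core import AIP, AipClass, AtomSite, Hybridization


@pytest.fixture(scope="session")
def library():
    return make_toy_fragment_library(seed=0)


@pytest.fixture(scope="session")
def water_model():
    from aipmap.energetics import water

    return water()


@pytest.fixture
def symmetric_solvent():
    return SolventModel(theta=1.0, solvent_aips=[(2.0, 0.5), (-2.0, 0.5)])


def make_atom(aid, element, coords, hyb=Hybridization.SP3, sybyl=""):
    return AtomSite(atom_id=aid, element=element, coords=np.asarray(coords, float),
                    hybridization=hyb, sybyl_type=sybyl)


def make_aip(pos, eps, parent, aip_class=AipClass.CH_DONOR, fraction=1.0):
    return AIP(position=np.asarray(pos, float), epsilon=eps, fraction=fraction,
               aip_class=aip_class, parent_atom_id=parent)


@pytest.fixture
def two_atom_molecule():
    atoms = [make_atom("a1", "C", (0, 0, 0)), make_atom("a2", "O", (1.4, 0, 0))]
    return MoleculeGraph(atoms=atoms, bonds=[("a1", "a2", 1.0)])


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random rotation matrix from a QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
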