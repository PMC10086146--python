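import numpy as np
import pytest
import biotite.structure as struc

import hintmaps as hm
from hintmaps.config import PipelineConfig


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def ala_helix():
    """Protonated 18-residue ideal polyalanine α-helix."""
    model = hm.build_peptide(hm.FixtureSpec(kind="helix", n_residues=18,
                                            sequence="ALA", seed=0))
    return hm.protonate(model)


@pytest.fixture(scope="session")
def ala_strand():
    model = hm.build_peptide(hm.FixtureSpec(kind="strand", n_residues=10,
                                            sequence="ALA", seed=0))
    return hm.protonate(model)


@pytest.fixture(scope="session")
def membrane_system():
    """(model, distortions, by_resid) for the 4-helix membrane fixture."""
    spec = hm.FixtureSpec(seed=2, bilayer_half_width=15.0, bead_sd=0.0)
    return hm.build_membrane_system(spec)


@pytest.fixture(scope="session")
def membrane_prepared(membrane_system, config):
    model, distortions, by_resid = membrane_system
    return hm.prepare_model(model, config), distortions, by_resid


def make_model(atoms: list[struc.Atom], **kwargs) -> hm.StructureModel:
    """Assemble a StructureModel from a list of biotite Atoms."""
    return hm.StructureModel(struc.array(atoms), **kwargs)


def atom(xyz, name, res_name="ALA", res_id=1, chain="A", element=None,
         hetero=False):
    return struc.Atom(np.asarray(xyz, dtype=float), chain_id=chain,
                      res_id=res_id, res_name=res_name, hetero=hetero,
                      atom_name=name, element=element or name[0])


@pytest.fixture
def identity_frame():
    return hm.CanonicalFrame(rotation=np.eye(3), translation=np.zeros(3))
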