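import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from pharmdiff import make_toy_complex
from pharmdiff.molio import Molecule3D, ProteinContext, from_rdkit
from pharmdiff.toysystem import hbond_probe_context


def mol_from_smiles(smiles: str, seed: int = 7, add_hs: bool = True) -> Molecule3D:
    """Embed a SMILES into 3D and convert to the package's molecule type."""
    rdmol = Chem.MolFromSmiles(smiles)
    assert rdmol is not None, smiles
    rdmol = Chem.AddHs(rdmol)
    assert AllChem.EmbedMolecule(rdmol, randomSeed=seed) == 0, smiles
    if not add_hs:
        rdmol = Chem.RemoveHs(rdmol)
    return from_rdkit(rdmol)


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation plus a translation."""
    from scipy.stats import special_ortho_group
    q = special_ortho_group.rvs(3, random_state=rng)
    b = rng.uniform(-5, 5, size=3)
    return q, b


@pytest.fixture(scope="session")
def toy_system():
    return make_toy_complex(seed=1)


@pytest.fixture(scope="session")
def probe_context(toy_system):
    return hbond_probe_context(toy_system)


@pytest.fixture()
def small_pocket():
    """A tiny hand-placed protein context with donor/acceptor atoms."""
    rng = np.random.default_rng(0)
    pos = rng.uniform(-6, 6, size=(8, 3)) + np.array([0, 0, 12.0])
    elements = ["C", "O", "N", "C", "O", "N", "C", "C"]
    labels = [f"A:RES:{i+1}" for i in range(8)]
    return ProteinContext(pos, labels, elements, sigma=1.0, clash_threshold=2.0)
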