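import numpy as np
import pytest
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from fragstitch import Config, FragmentHit, PositionedMol
from fragstitch import fixtures as fx

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def overlap_pair():
    return fx.overlap_pair()


@pytest.fixture(scope="session")
def toy_pocket():
    return fx.toy_pocket()


@pytest.fixture(scope="session")
def covalent_case():
    return fx.covalent_toy()


@pytest.fixture(scope="session")
def druglike():
    mols = fx.drug_like_set(100, seed=7)
    assert len(mols) >= 100
    return mols


@pytest.fixture
def cfg():
    return Config()


def mol_from_smiles_3d(smiles: str, seed: int = 0, name: str = "") -> PositionedMol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    mol = Chem.RemoveHs(mol)
    return PositionedMol.from_rdkit(mol, name=name or smiles)


@pytest.fixture
def benzene_3d():
    return mol_from_smiles_3d("c1ccccc1", seed=1, name="benzene")


def hit_of(mol: PositionedMol, hit_id: str = "") -> FragmentHit:
    return FragmentHit(mol, hit_id or mol.name)
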