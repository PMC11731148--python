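"""Deterministic synthetic fixtures: positioned ring pairs, a toy pocket,
covalent toys and a seeded drug-like corpus.

Everything here is generated programmatically so the whole suite runs
without downloads; geometry is idealised but force-field parseable.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .io import ProteinAtom, ProteinModel
from .model import Atom, Bond, DUMMY, FragmentHit, PositionedMol

FURAN_RADIUS = 1.157     # regular pentagon, 1.36 A sides
BENZENE_RADIUS = 1.39


def _ring(elements: list[str], radius: float, center=(0.0, 0.0, 0.0),
          start_angle_deg: float = 90.0, name: str = "") -> PositionedMol:
    center = np.asarray(center, dtype=float)
    n = len(elements)
    atoms = []
    for k, element in enumerate(elements):
        theta = np.radians(start_angle_deg + 360.0 * k / n)
        xyz = center + radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        atoms.append(Atom(element, xyz, aromatic=True))
    bonds = [Bond(atoms[k], atoms[(k + 1) % n], 1.5) for k in range(n)]
    return PositionedMol(atoms, bonds, name)


def furan(center=(0.0, 0.0, 0.0), name: str = "furan") -> PositionedMol:
    return _ring(["O", "C", "C", "C", "C"], FURAN_RADIUS, center, name=name)


def benzene(center=(0.0, 0.0, 0.0), name: str = "benzene") -> PositionedMol:
    return _ring(["C"] * 6, BENZENE_RADIUS, center, name=name)


def ring_pair_sweep(separations) -> list[tuple[FragmentHit, FragmentHit]]:
    """Furan/benzene pairs with centroids separated along x by each value."""
    pairs = []
    for sep in separations:
        f = furan((0.0, 0.0, 0.0), name=f"furan_{sep:g}")
        b = benzene((float(sep), 0.0, 0.0), name=f"benzene_{sep:g}")
        pairs.append((FragmentHit(f, f.name), FragmentHit(b, b.name)))
    return pairs


def overlap_pair() -> tuple[FragmentHit, FragmentHit]:
    """Toluene and phenol superposed on a shared benzene ring.

    The methyl sits para to the hydroxyl, so a 4-methylphenol candidate maps
    its ring to the larger-coverage hit, the methyl to toluene and the
    hydroxyl to phenol.
    """
    tol = _ring(["C"] * 6, BENZENE_RADIUS, start_angle_deg=0.0, name="toluene")
    methyl = Atom("C", (BENZENE_RADIUS + 1.50, 0.0, 0.0))
    tol.add_atom(methyl)
    tol.add_bond(tol.atoms[0], methyl, 1.0)

    phe = _ring(["C"] * 6, BENZENE_RADIUS, start_angle_deg=0.0, name="phenol")
    hydroxyl = Atom("O", (-(BENZENE_RADIUS + 1.36), 0.0, 0.0))
    phe.add_atom(hydroxyl)
    phe.add_bond(phe.atoms[3], hydroxyl, 1.0)
    return FragmentHit(tol, "toluene"), FragmentHit(phe, "phenol")


# --------------------------------------------------------------------------
# toy pocket
# --------------------------------------------------------------------------

_RES_TEMPLATES = {
    "ALA": [("N", "N", (0.000, 0.000, 0.000)),
            ("CA", "C", (1.458, 0.000, 0.000)),
            ("C", "C", (2.009, 1.420, 0.000)),
            ("O", "O", (1.251, 2.390, 0.000)),
            ("CB", "C", (2.000, -0.770, -1.200))],
    "SER": [("N", "N", (0.000, 0.000, 0.000)),
            ("CA", "C", (1.458, 0.000, 0.000)),
            ("C", "C", (2.009, 1.420, 0.000)),
            ("O", "O", (1.251, 2.390, 0.000)),
            ("CB", "C", (2.000, -0.770, -1.200)),
            ("OG", "O", (2.600, -1.500, -2.200))],
    "CYS": [("N", "N", (0.000, 0.000, 0.000)),
            ("CA", "C", (1.458, 0.000, 0.000)),
            ("C", "C", (2.009, 1.420, 0.000)),
            ("O", "O", (1.251, 2.390, 0.000)),
            ("CB", "C", (2.000, -0.770, -1.200)),
            ("SG", "S", (2.800, -1.770, -2.400))],
    "GLY": [("N", "N", (0.000, 0.000, 0.000)),
            ("CA", "C", (1.458, 0.000, 0.000)),
            ("C", "C", (2.009, 1.420, 0.000)),
            ("O", "O", (1.251, 2.390, 0.000))],
}


def _rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def toy_pocket(n_residues: int = 6, radius: float = 7.0,
               kinds: tuple[str, ...] = ("ALA", "SER"),
               name: str = "toy_pocket") -> ProteinModel:
    """A small cavity: residues on a circle with sidechains pointing inward.

    Residue templates sit with their CB roughly along -x in local frame
    after mirroring, so after placing each residue at angle theta the
    sidechain points towards the origin.
    """
    model = ProteinModel(name=name)
    for i in range(n_residues):
        resname = kinds[i % len(kinds)]
        theta = 2.0 * np.pi * i / n_residues
        rot = _rotation_z(theta)
        anchor = np.array([radius, 0.0, 0.0])
        for atom_name, element, local in _RES_TEMPLATES[resname]:
            local = np.asarray(local)
            # mirror x so the sidechain extends towards the pocket centre
            local = np.array([-local[0], local[1], local[2]])
            xyz = rot @ (anchor + local)
            model.atoms.append(ProteinAtom(
                name=atom_name, element=element, resname=resname,
                chain="A", resseq=i + 1, xyz=xyz))
    return model


def covalent_toy(radius: float = 7.5,
                 seed: int = 11) -> tuple[ProteinModel, FragmentHit]:
    """A pocket containing a cysteine plus a covalent acetamide stub.

    The hit's dummy atom sits on the cysteine S-gamma and the warhead
    carbons extend towards the pocket centre.  Internal geometry comes from
    a seeded embedded conformer so the stub is unstrained.
    """
    pocket = toy_pocket(6, radius, kinds=("ALA", "CYS", "SER"),
                        name="covalent_pocket")
    sg = next(a for a in pocket.atoms if a.name == "SG")
    toward = -sg.xyz / np.linalg.norm(sg.xyz)

    stub = Chem.AddHs(Chem.MolFromSmiles("CC(=O)NC"))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(stub, params)
    AllChem.MMFFOptimizeMolecule(stub)
    stub = Chem.RemoveHs(stub)
    conf = stub.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i))
                       for i in range(stub.GetNumAtoms())])
    # rigid-place: anchor carbon (atom 0) at 1.8 A from SG, its bond to the
    # carbonyl carbon pointing into the pocket
    anchor_pos = sg.xyz + 1.80 * toward
    v = coords[1] - coords[0]
    rot = _align_rotation(v / np.linalg.norm(v), toward)
    coords = (coords - coords[0]) @ rot.T
    # the axial orientation is otherwise free: pick the rotation about the
    # attachment axis that keeps the stub farthest from the pocket walls
    pocket_coords = pocket.coords()
    best = None
    for phi in np.linspace(0.0, 2.0 * np.pi, 36, endpoint=False):
        cand = coords @ _axis_rotation(toward, phi).T + anchor_pos
        dmin = np.linalg.norm(cand[:, None, :] - pocket_coords[None, :, :],
                              axis=-1)[1:].min()
        if best is None or dmin > best[0]:
            best = (dmin, cand)
    coords = best[1]

    dummy = Atom(DUMMY, sg.xyz.copy())
    atoms = [dummy] + [Atom(stub.GetAtomWithIdx(i).GetSymbol(), coords[i])
                       for i in range(stub.GetNumAtoms())]
    bonds = [Bond(dummy, atoms[1], 1.0)]
    for bond in stub.GetBonds():
        bonds.append(Bond(atoms[bond.GetBeginAtomIdx() + 1],
                          atoms[bond.GetEndAtomIdx() + 1],
                          bond.GetBondTypeAsDouble()))
    mol = PositionedMol(atoms, bonds, name="covalent_stub")
    return pocket, FragmentHit(mol, "covalent_stub")


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    ax = np.array([[0, -axis[2], axis[1]],
                   [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    return np.eye(3) * c + s * ax + (1 - c) * np.outer(axis, axis)


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``a`` onto unit vector ``b``."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.isclose(c, -1.0):
        axis = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            axis = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, axis)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# --------------------------------------------------------------------------
# drug-like corpus
# --------------------------------------------------------------------------

_SCAFFOLDS = [
    "c1ccc({R})cc1",
    "c1ccnc({R})c1",
    "c1ccc2cc({R})ccc2c1",
    "C1CCN({R})CC1",
    "c1ccc(-c2ccc({R})cc2)cc1",
    "O=C(c1ccccc1){R}",
    "c1cnc({R})[nH]1",
    "C1CCC({R})CC1",
    "c1ccc2[nH]c({R})cc2c1",
    "O=C1CCCN1{R}",
]

_SUBSTITUENTS = [
    "C", "CC", "CCO", "N", "OC", "Cl", "C(=O)N", "C(=O)OC",
    "CN(C)C", "CO", "F", "C#N",
]


def drug_like_smiles(n: int = 100) -> list[str]:
    out = []
    for scaffold in _SCAFFOLDS:
        for sub in _SUBSTITUENTS:
            smiles = scaffold.replace("{R}", sub)
            if Chem.MolFromSmiles(smiles) is not None:
                out.append(smiles)
            if len(out) >= n:
                return out
    return out


def corrupt(mol: PositionedMol, rng: np.random.Generator) -> PositionedMol:
    """Apply one random chemistry-breaking edit (for rectifier fuzzing).

    Edits mimic what naive coordinate merging produces: an extra bond onto a
    saturated atom (pentavalent carbons), geminal substituents on an
    aromatic atom, or a bumped bond order.
    """
    work, _ = mol.copy()
    kind = rng.integers(0, 4)
    heavies = [a for a in work.atoms if a.is_heavy and not a.is_dummy]
    if kind == 0 and len(heavies) >= 2:
        a, b = rng.choice(len(heavies), size=2, replace=False)
        if work.get_bond(heavies[a], heavies[b]) is None:
            work.add_bond(heavies[a], heavies[b], 1.0)
    elif kind == 1:
        aromatics = [a for a in work.atoms if a.aromatic]
        if aromatics:
            target = aromatics[int(rng.integers(0, len(aromatics)))]
            for offset in ((0.9, 1.2, 0.4), (0.9, 1.2, -0.4)):
                extra = Atom("C", target.xyz + np.array(offset))
                work.add_atom(extra)
                work.add_bond(target, extra, 1.0)
    elif kind == 2 and work.bonds:
        bond = work.bonds[int(rng.integers(0, len(work.bonds)))]
        if bond.order in (1.0, 2.0):
            bond.order += 1.0
    # kind == 3: no-op, valid molecules must pass through untouched
    return work


def drug_like_set(n: int = 100, seed: int = 7) -> list[PositionedMol]:
    """Seeded 3D drug-like molecules for round-trip and fuzz corpora."""
    mols = []
    for i, smiles in enumerate(drug_like_smiles(n)):
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + i
        if AllChem.EmbedMolecule(mol, params) != 0:
            continue
        mol = Chem.RemoveHs(mol)
        mols.append(PositionedMol.from_rdkit(mol, name=f"druglike_{i}"))
    return mols
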