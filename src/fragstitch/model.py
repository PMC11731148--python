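"""Core molecular data model.

``PositionedMol`` is the universal currency of the pipeline: a small molecule
whose atoms carry Cartesian coordinates in the protein frame.  It is a plain
object graph (atoms are identity-stable objects, bonds reference atoms) so the
stitching stages can splice molecules without fighting index bookkeeping;
conversion to and from RDKit happens at the boundaries.

Coordinates are Angstrom, in the same frame as the protein template.  No
re-superposition is ever performed: inputs are assumed pre-aligned.  Inputs
may omit hydrogens; everything here operates on heavy atoms, and hydrogens are
added only for minimisation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .errors import ParseError

#: sentinel element for covalent-attachment dummy atoms ("*" in SMILES, "R"
#: in SDF) and for collapsed-ring placeholders.
DUMMY = "*"

AROMATIC_ORDER = 1.5

_ORDER_TO_RDKIT = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
    AROMATIC_ORDER: Chem.BondType.AROMATIC,
}
_RDKIT_TO_ORDER = {v: k for k, v in _ORDER_TO_RDKIT.items()}

#: maximum bond-order sum for neutral atoms (used by the rectifier; RDKit
#: sanitisation remains the final validator).
MAX_VALENCE = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1, "Si": 4, "P": 5,
    "S": 6, "Cl": 1, "Br": 1, "I": 1,
}


def max_valence(element: str, charge: int = 0) -> float:
    base = MAX_VALENCE.get(element)
    if base is None:
        return float("inf")
    if element == "N":
        return base + charge
    if element == "O":
        return base + (1 if charge > 0 else -1 if charge < 0 else 0)
    if element == "C" and charge != 0:
        return base - abs(charge)
    return base


class Atom:
    """A single atom: element, formal charge, aromatic flag, xyz, free tags."""

    __slots__ = ("element", "charge", "aromatic", "xyz", "tags")

    def __init__(self, element: str, xyz, charge: int = 0,
                 aromatic: bool = False, tags: Optional[dict] = None):
        self.element = element
        self.charge = int(charge)
        self.aromatic = bool(aromatic)
        self.xyz = np.asarray(xyz, dtype=float)
        self.tags = dict(tags) if tags else {}

    @property
    def is_dummy(self) -> bool:
        return self.element == DUMMY

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def copy(self) -> "Atom":
        return Atom(self.element, self.xyz.copy(), self.charge,
                    self.aromatic, dict(self.tags))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        x, y, z = self.xyz
        return f"<Atom {self.element} ({x:.2f},{y:.2f},{z:.2f})>"


@dataclass
class Bond:
    a: Atom
    b: Atom
    order: float = 1.0

    @property
    def is_aromatic(self) -> bool:
        return self.order == AROMATIC_ORDER

    def other(self, atom: Atom) -> Atom:
        if atom is self.a:
            return self.b
        if atom is self.b:
            return self.a
        raise ValueError("atom not in bond")


class PositionedMol:
    """A 3D small molecule as an identity-stable atom/bond graph."""

    def __init__(self, atoms: Optional[Iterable[Atom]] = None,
                 bonds: Optional[Iterable[Bond]] = None, name: str = ""):
        self.atoms: list[Atom] = list(atoms) if atoms else []
        self.bonds: list[Bond] = list(bonds) if bonds else []
        self.name = name
        self._check()

    # -- construction -----------------------------------------------------
    def _check(self) -> None:
        seen = set()
        atom_ids = {id(a) for a in self.atoms}
        for bond in self.bonds:
            if id(bond.a) not in atom_ids or id(bond.b) not in atom_ids:
                raise ValueError("bond references atom outside molecule")
            if bond.a is bond.b:
                raise ValueError("self-bond")
            key = frozenset((id(bond.a), id(bond.b)))
            if key in seen:
                raise ValueError("duplicate bond")
            seen.add(key)
        for atom in self.atoms:
            if not np.all(np.isfinite(atom.xyz)):
                raise ValueError("non-finite coordinate")

    def add_atom(self, atom: Atom) -> Atom:
        self.atoms.append(atom)
        return atom

    def add_bond(self, a: Atom, b: Atom, order: float = 1.0) -> Bond:
        if a is b:
            raise ValueError("self-bond")
        existing = self.get_bond(a, b)
        if existing is not None:
            return existing
        bond = Bond(a, b, order)
        self.bonds.append(bond)
        return bond

    def remove_bond(self, bond: Bond) -> None:
        self.bonds.remove(bond)

    def remove_atom(self, atom: Atom) -> None:
        self.bonds = [b for b in self.bonds if b.a is not atom and b.b is not atom]
        self.atoms.remove(atom)

    # -- queries ----------------------------------------------------------
    def index(self, atom: Atom) -> int:
        for i, a in enumerate(self.atoms):
            if a is atom:
                return i
        raise ValueError("atom not in molecule")

    def get_bond(self, a: Atom, b: Atom) -> Optional[Bond]:
        for bond in self.bonds:
            if (bond.a is a and bond.b is b) or (bond.a is b and bond.b is a):
                return bond
        return None

    def bonds_of(self, atom: Atom) -> list[Bond]:
        return [b for b in self.bonds if b.a is atom or b.b is atom]

    def neighbors(self, atom: Atom) -> list[Atom]:
        return [b.other(atom) for b in self.bonds_of(atom)]

    def bond_order_sum(self, atom: Atom) -> float:
        return sum(b.order for b in self.bonds_of(atom))

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy and not a.is_dummy]

    def coords(self, atoms: Optional[Iterable[Atom]] = None) -> np.ndarray:
        pool = self.atoms if atoms is None else list(atoms)
        if not pool:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in pool], dtype=float)

    def centroid(self) -> np.ndarray:
        heavies = self.heavy_atoms() or self.atoms
        return self.coords(heavies).mean(axis=0)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, atom in enumerate(self.atoms):
            g.add_node(i, element=atom.element, charge=atom.charge,
                       aromatic=atom.aromatic, xyz=tuple(atom.xyz))
        for bond in self.bonds:
            g.add_edge(self.index(bond.a), self.index(bond.b), order=bond.order)
        return g

    def connected_components(self) -> list[list[Atom]]:
        g = nx.Graph()
        g.add_nodes_from(id(a) for a in self.atoms)
        g.add_edges_from((id(b.a), id(b.b)) for b in self.bonds)
        by_id = {id(a): a for a in self.atoms}
        return [[by_id[i] for i in comp] for comp in nx.connected_components(g)]

    def rings(self) -> list[list[Atom]]:
        """Smallest-set-of-smallest-rings style ring list (cycle basis)."""
        g = nx.Graph()
        g.add_nodes_from(id(a) for a in self.atoms)
        g.add_edges_from((id(b.a), id(b.b)) for b in self.bonds)
        by_id = {id(a): a for a in self.atoms}
        return [[by_id[i] for i in cyc] for cyc in nx.minimum_cycle_basis(g)]

    def n_rings(self) -> int:
        return len(self.rings())

    # -- copying ----------------------------------------------------------
    def copy(self) -> tuple["PositionedMol", dict]:
        """Deep copy; returns ``(copy, memo)`` mapping old atoms to new."""
        memo: dict[int, Atom] = {}
        new_atoms = []
        for atom in self.atoms:
            clone = atom.copy()
            memo[id(atom)] = clone
            new_atoms.append(clone)
        new_bonds = [Bond(memo[id(b.a)], memo[id(b.b)], b.order) for b in self.bonds]
        out = PositionedMol(new_atoms, new_bonds, self.name)
        # remap any atom references stashed inside tags (ring placeholders)
        for atom in new_atoms:
            stashes = atom.tags.get("ring_stashes")
            if stashes:
                atom.tags["ring_stashes"] = [s.remap(memo) for s in stashes]
        return out, memo

    # -- RDKit bridge -----------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, conf_id: int = 0, name: str = "") -> "PositionedMol":
        if mol is None:
            raise ParseError("RDKit molecule is None")
        if mol.GetNumConformers() == 0:
            raise ParseError("molecule has no conformer")
        conf = mol.GetConformer(conf_id)
        atoms: list[Atom] = []
        for rd_atom in mol.GetAtoms():
            pos = conf.GetAtomPosition(rd_atom.GetIdx())
            symbol = rd_atom.GetSymbol()
            if rd_atom.GetAtomicNum() == 0:
                symbol = DUMMY
            atom = Atom(symbol, (pos.x, pos.y, pos.z),
                        rd_atom.GetFormalCharge(),
                        rd_atom.GetIsAromatic())
            # pyrrole-type N is indistinguishable from pyridine-type once
            # hydrogens are stripped; keep the H count as a hint
            if atom.aromatic and symbol == "N":
                atom.tags["n_h"] = rd_atom.GetTotalNumHs()
            atoms.append(atom)
        bonds = []
        for rd_bond in mol.GetBonds():
            order = _RDKIT_TO_ORDER.get(rd_bond.GetBondType(),
                                        float(rd_bond.GetBondTypeAsDouble()))
            bonds.append(Bond(atoms[rd_bond.GetBeginAtomIdx()],
                              atoms[rd_bond.GetEndAtomIdx()], order))
        out = cls(atoms, bonds, name or (mol.GetProp("_Name")
                                         if mol.HasProp("_Name") else ""))
        return out

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        rw = Chem.RWMol()
        for atom in self.atoms:
            if atom.is_dummy:
                rd_atom = Chem.Atom(0)
            else:
                rd_atom = Chem.Atom(atom.element)
            rd_atom.SetFormalCharge(atom.charge)
            rd_atom.SetIsAromatic(atom.aromatic)
            if atom.aromatic and atom.element == "N" and "n_h" in atom.tags:
                rd_atom.SetNumExplicitHs(int(atom.tags["n_h"]))
            rw.AddAtom(rd_atom)
        for bond in self.bonds:
            bt = _ORDER_TO_RDKIT.get(bond.order, Chem.BondType.SINGLE)
            rw.AddBond(self.index(bond.a), self.index(bond.b), bt)
        conf = Chem.Conformer(len(self.atoms))
        for i, atom in enumerate(self.atoms):
            conf.SetAtomPosition(i, Point3D(*map(float, atom.xyz)))
        mol = rw.GetMol()
        mol.AddConformer(conf, assignId=True)
        if self.name:
            mol.SetProp("_Name", self.name)
        if sanitize:
            Chem.SanitizeMol(mol)
        else:
            mol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(mol)
        return mol

    def is_sanitizable(self) -> bool:
        try:
            self.to_rdkit(sanitize=True)
            return True
        except Exception:
            return False

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PositionedMol {self.name!r} {len(self.atoms)} atoms, {len(self.bonds)} bonds>"


@dataclass
class FragmentHit:
    """A positioned crystallographic fragment hit."""

    mol: PositionedMol
    hit_id: str
    covalent_attachment_index: Optional[int] = None

    def __post_init__(self):
        n_dummy = sum(1 for a in self.mol.atoms if a.is_dummy)
        if n_dummy > 1:
            raise ParseError(
                f"hit {self.hit_id!r} has {n_dummy} dummy atoms; at most one "
                "covalent attachment is allowed")
        if self.covalent_attachment_index is None and n_dummy == 1:
            self.covalent_attachment_index = next(
                i for i, a in enumerate(self.mol.atoms) if a.is_dummy)

    @property
    def is_covalent(self) -> bool:
        return self.covalent_attachment_index is not None


@dataclass
class Config:
    """All pipeline thresholds; defaults follow the published method."""

    map_threshold: float = 2.0       # A, positional one-to-one mapping
    join_cutoff: float = 5.0         # A, hit deferral cutoff during combine
    max_excluded: int = 3            # red-herring atoms droppable per pass
    linker_spacing: float = 1.22     # A per inserted linker atom
    linker_first_element: str = "N"  # first linker atom is a heteroatom
    neighbourhood_padding: float = 3.0   # A added to ligand length for mobility
    max_min_cycles: int = 15
    seed: int = 0
    heavy_restraint: float = 10.0    # kcal/mol/A^2, flat-bottom
    moderate_restraint: float = 2.0
    restraint_flat_bottom: float = 0.5   # A
    rectify_max_iter: int = 20

    def __post_init__(self):
        for attr in ("map_threshold", "join_cutoff", "linker_spacing",
                     "neighbourhood_padding"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.max_excluded < 0:
            raise ValueError("max_excluded must be >= 0")


def mol_from_smiles(smiles: str, name: str = "") -> Chem.Mol:
    """Parse SMILES into an RDKit topology (no coordinates), keeping dummies."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    if name:
        mol.SetProp("_Name", name)
    return mol


def ligand_length(mol: PositionedMol) -> float:
    """Maximum heavy-atom pairwise distance ('ligand length')."""
    coords = mol.coords(mol.heavy_atoms())
    if len(coords) < 2:
        return 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).max())
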