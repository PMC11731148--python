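"""Dummy-atom warhead mechanics for covalently bound hits and candidates.

A covalent ligand carries one wild-card atom (``*`` in SMILES, ``R`` in SDF)
marking where the protein nucleophile attaches.  The warhead — the dummy's
bonded neighbourhood up to the first rotatable bond — is protected during
merging: those atoms are never deleted, element-swapped or chosen as linker
attachment points, and their coordinates come only from the covalent hit.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .errors import CovalentConflict, ParseError
from .model import DUMMY, PositionedMol, mol_from_smiles


def mark_covalent(smiles: str) -> tuple[Chem.Mol, Optional[int], set[int]]:
    """Parse a candidate SMILES, flagging covalent mode when a dummy exists.

    Returns ``(topology, attachment_idx, warhead_atom_indices)``; attachment
    is ``None`` (non-covalent mode) when there is no dummy atom.  More than
    one dummy atom is an error.
    """
    mol = mol_from_smiles(smiles)
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) > 1:
        raise ParseError(f"{len(dummies)} dummy atoms in {smiles!r}; "
                         "at most one covalent attachment is allowed")
    if not dummies:
        return mol, None, set()
    attachment = dummies[0]
    warhead = warhead_atoms(mol, attachment)
    return mol, attachment, warhead


def _is_carbonyl_carbon(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "C":
        return False
    return any(b.GetBondTypeAsDouble() == 2.0
               and b.GetOtherAtom(atom).GetSymbol() == "O"
               for b in atom.GetBonds())


def _stops_warhead(mol: Chem.Mol, bond: Chem.Bond, toward: Chem.Atom) -> bool:
    """Rotatable bonds end the warhead walk, but an adjacent carbonyl group
    is swept in with it (the acyl unit moves as one rigid piece)."""
    if bond.IsInRing() or bond.GetBondTypeAsDouble() != 1.0:
        return False
    if toward.GetDegree() <= 1 or bond.GetOtherAtom(toward).GetDegree() <= 1:
        return False
    return not _is_carbonyl_carbon(toward)


def warhead_atoms(mol: Chem.Mol, attachment_idx: int) -> set[int]:
    """The dummy's bonded neighbourhood up to the first rotatable bond.

    Walks outward from the attachment atom, stopping at rotatable bonds;
    double-bonded decorations (e.g. the carbonyl oxygen of a chloroacetamide
    stub) are swept in with their carbon.
    """
    seen = {attachment_idx}
    frontier = [attachment_idx]
    while frontier:
        idx = frontier.pop()
        atom = mol.GetAtomWithIdx(idx)
        for bond in atom.GetBonds():
            other_atom = bond.GetOtherAtom(atom)
            other = other_atom.GetIdx()
            if other in seen:
                continue
            if _stops_warhead(mol, bond, other_atom):
                continue
            seen.add(other)
            frontier.append(other)
    return seen


def protect_hit(mol: PositionedMol, attachment_idx: int) -> None:
    """Tag the attachment dummy and its warhead as protected, in place."""
    rd = mol.to_rdkit(sanitize=False)
    for idx in warhead_atoms(rd, attachment_idx):
        mol.atoms[idx].tags["protected"] = True


def protect_during_merge(stitched, warhead_atoms_idx: Sequence[int]):
    """Assert warhead integrity on a stitched conformer.

    The combine/merge machinery honours ``protected`` tags as it goes; this
    re-checks the contract afterwards and raises :class:`CovalentConflict`
    if a protected atom was lost or its coordinates no longer come from the
    covalent hit.
    """
    mol = stitched.mol
    protected = [a for a in mol.atoms if a.tags.get("protected")]
    if len(protected) < len(set(warhead_atoms_idx)):
        raise CovalentConflict("a protected warhead atom was removed during "
                               "merging")
    for atom in protected:
        origin = atom.tags.get("origin")
        if origin in ("linker", "novel"):
            raise CovalentConflict(
                "a protected atom acquired non-covalent-hit coordinates")
    return stitched


def nearest_cysteine(protein, point: np.ndarray) -> Optional[str]:
    """Residue id of the cysteine whose S-gamma is nearest to ``point``."""
    best = None
    for atom in protein.atoms:
        if atom.resname == "CYS" and atom.name == "SG":
            d = float(np.linalg.norm(atom.xyz - point))
            if best is None or d < best[0]:
                best = (d, atom.residue_id)
    return best[1] if best else None
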