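"""Geometric protein-ligand interaction profiling, ranking and filters.

The profiler is rule-based with standard geometric cutoffs (config-exposed):
hydrogen bond donor-acceptor <= 3.5 A with a >= 120 degree D-H-A angle when
an explicit hydrogen is available, hydrophobic carbon-carbon <= 4.0 A, salt
bridge <= 4.5 A, aromatic-ring centroid stacking <= 4.5 A with near-parallel
planes, halogen bond <= 3.5 A.  Detection is deterministic and invariant
under rigid-body motion of the whole complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from rdkit import Chem

from .io import ProteinModel
from .model import PositionedMol

HBOND_CUTOFF = 3.5
HBOND_MIN_ANGLE = 120.0
HYDROPHOBIC_CUTOFF = 4.0
SALT_BRIDGE_CUTOFF = 4.5
PI_STACK_CUTOFF = 4.5
PI_STACK_MAX_TILT = 30.0
HALOGEN_CUTOFF = 3.5

_PROTEIN_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_ANIONIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CATIONIC = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}


class Contact(NamedTuple):
    kind: str           # hbond | hydrophobic | salt_bridge | pi_stack | halogen
    ligand_atom: int    # heavy-atom index in the ligand
    residue: str        # chain:RES:seq
    distance: float


@dataclass
class InteractionProfile:
    contacts: frozenset = frozenset()

    def keys(self) -> set[tuple[str, str]]:
        """(kind, residue) pairs — the currency of conservation counting."""
        return {(c.kind, c.residue) for c in self.contacts}

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class RankWeights:
    """Signs follow the published intent: penalise lost interactions, novel
    atoms, poor binding energy and rotatable bonds; favour conserved atoms
    and conserved interactions.  Magnitudes are ours."""

    w_lost_interactions: float = 1.0
    w_novel_atoms: float = 1.0
    w_dG: float = 1.0
    w_rotatable: float = 0.5
    w_conserved_atoms: float = 1.0
    w_conserved_interactions: float = 1.0


def _ligand_donors_acceptors(mol: PositionedMol):
    """Heavy-atom donor/acceptor indices; donor H positions when explicit."""
    donors, acceptors, h_pos = [], [], {}
    try:
        rd = mol.to_rdkit(sanitize=True)
        rd_h = Chem.AddHs(rd, addCoords=True)
        conf = rd_h.GetConformer()
        for atom in rd_h.GetAtoms():
            if atom.GetSymbol() not in ("N", "O"):
                continue
            idx = atom.GetIdx()
            if idx >= len(mol.atoms):
                continue
            hs = [list(conf.GetAtomPosition(nb.GetIdx()))
                  for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1]
            acceptors.append(idx)
            if hs:
                donors.append(idx)
                h_pos[idx] = np.array(hs)
    except Exception:
        for i, atom in enumerate(mol.atoms):
            if atom.element in ("N", "O"):
                donors.append(i)
                acceptors.append(i)
    return donors, acceptors, h_pos


def _ligand_rings(mol: PositionedMol) -> list[list[int]]:
    return [[mol.index(a) for a in ring] for ring in mol.rings()
            if all(a.aromatic for a in ring)]


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[2]


def detect_interactions(protein: ProteinModel,
                        ligand: PositionedMol) -> InteractionProfile:
    """Rule-based geometric interaction detection (deterministic)."""
    contacts: set[Contact] = set()
    lig_heavy = [(i, a) for i, a in enumerate(ligand.atoms)
                 if a.is_heavy and not a.is_dummy]
    donors, acceptors, h_pos = _ligand_donors_acceptors(ligand)

    for patom in protein.atoms:
        for i, latom in enumerate(ligand.atoms):
            if not latom.is_heavy or latom.is_dummy:
                continue
            d = float(np.linalg.norm(latom.xyz - patom.xyz))
            if d > SALT_BRIDGE_CUTOFF:
                continue
            rid = patom.residue_id
            if patom.element in ("N", "O") and d <= HBOND_CUTOFF:
                if i in donors:
                    hs = h_pos.get(i)
                    ok = True
                    if hs is not None:
                        angles = [_angle(latom.xyz, h, patom.xyz) for h in hs]
                        ok = max(angles) >= HBOND_MIN_ANGLE
                    if ok:
                        contacts.add(Contact("hbond", i, rid, round(d, 3)))
                elif i in acceptors:
                    contacts.add(Contact("hbond", i, rid, round(d, 3)))
            if patom.element == "C" and latom.element == "C" \
                    and d <= HYDROPHOBIC_CUTOFF:
                contacts.add(Contact("hydrophobic", i, rid, round(d, 3)))
            key = (patom.resname, patom.name)
            if d <= SALT_BRIDGE_CUTOFF:
                if key in _ANIONIC and latom.element == "N" \
                        and latom.charge >= 0:
                    contacts.add(Contact("salt_bridge", i, rid, round(d, 3)))
                elif key in _CATIONIC and latom.element == "O" \
                        and latom.charge <= 0:
                    contacts.add(Contact("salt_bridge", i, rid, round(d, 3)))
            if patom.element in ("N", "O") and \
                    latom.element in ("Cl", "Br", "I") and d <= HALOGEN_CUTOFF:
                contacts.add(Contact("halogen", i, rid, round(d, 3)))

    # aromatic stacking: ligand ring centroids vs residue ring centroids
    residues = protein.residues()
    for ring in _ligand_rings(ligand):
        lig_coords = np.array([ligand.atoms[i].xyz for i in ring])
        lig_centroid = lig_coords.mean(axis=0)
        lig_normal = _plane_normal(lig_coords)
        for rid, atoms in residues.items():
            resname = atoms[0].resname
            names = _PROTEIN_RING_ATOMS.get(resname)
            if not names:
                continue
            ring_atoms = [a for a in atoms if a.name in names]
            if len(ring_atoms) < len(names):
                continue
            coords = np.array([a.xyz for a in ring_atoms])
            centroid = coords.mean(axis=0)
            d = float(np.linalg.norm(centroid - lig_centroid))
            if d > PI_STACK_CUTOFF:
                continue
            tilt = _normal_angle(lig_normal, _plane_normal(coords))
            if tilt <= PI_STACK_MAX_TILT:
                contacts.add(Contact("pi_stack", ring[0], rid, round(d, 3)))
    return InteractionProfile(frozenset(contacts))


def _angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                     -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _normal_angle(n1, n2) -> float:
    cosang = abs(float(np.clip(n1 @ n2, -1.0, 1.0)))
    return float(np.degrees(np.arccos(cosang)))


# --------------------------------------------------------------------------
# conservation, ranking, filters
# --------------------------------------------------------------------------

def count_conserved(profile_ligand: InteractionProfile,
                    profiles_hits: Sequence[InteractionProfile]
                    ) -> tuple[int, int]:
    """(conserved, lost) hit contacts, by same-type same-residue identity."""
    hit_keys = set()
    for profile in profiles_hits:
        hit_keys |= profile.keys()
    lig_keys = profile_ligand.keys()
    conserved = len(hit_keys & lig_keys)
    lost = len(hit_keys - lig_keys)
    return conserved, lost


def n_rotatable(mol: PositionedMol) -> int:
    try:
        from rdkit.Chem import Descriptors
        return int(Descriptors.NumRotatableBonds(mol.to_rdkit(sanitize=True)))
    except Exception:
        count = 0
        for bond in mol.bonds:
            if bond.order != 1.0:
                continue
            if any(bond.a in ring and bond.b in ring for ring in mol.rings()):
                continue
            if len(mol.neighbors(bond.a)) > 1 and len(mol.neighbors(bond.b)) > 1:
                count += 1
        return count


def rank_score(placement, profile: InteractionProfile,
               hit_profiles: Sequence[InteractionProfile],
               weights: Optional[RankWeights] = None
               ) -> tuple[float, dict]:
    """Multiterm linear score; lower is better.  Returns (score, breakdown)."""
    w = weights or RankWeights()
    conserved, lost = count_conserved(profile, hit_profiles)
    n_conserved_atoms = sum(placement.hit_coverage.values()) \
        if placement.hit_coverage else \
        sum(1 for a in placement.mol.atoms
            if isinstance(a.tags.get("origin"), tuple))
    terms = {
        "lost_interactions": lost,
        "novel_atoms": placement.n_novel,
        "dG": placement.dG_bind,
        "rotatable": n_rotatable(placement.mol),
        "conserved_atoms": n_conserved_atoms,
        "conserved_interactions": conserved,
    }
    score = (w.w_lost_interactions * terms["lost_interactions"]
             + w.w_novel_atoms * terms["novel_atoms"]
             + w.w_dG * terms["dG"]
             + w.w_rotatable * terms["rotatable"]
             - w.w_conserved_atoms * terms["conserved_atoms"]
             - w.w_conserved_interactions * terms["conserved_interactions"])
    return float(score), terms


def acceptability(placement, hits) -> tuple[bool, str]:
    """The published quality filter.

    Accept iff every hit contributed at least one mapped atom, the combined
    RMSD against the hits is under 1 A, the predicted binding energy is
    negative, and the merger is strictly larger than the largest hit.
    """
    coverage = placement.hit_coverage or {}
    for hit in hits:
        if coverage.get(hit.hit_id, 0) < 1:
            return False, "unused hit"
    hac = len(placement.mol.heavy_atoms())
    largest = max(len(h.mol.heavy_atoms()) for h in hits) if hits else 0
    if hac <= largest:
        return False, "equal size"
    if placement.rmsd_vs_hits >= 1.0:
        return False, "strain/deviation"
    if not placement.dG_bind < 0:
        return False, "strain/deviation"
    return True, "acceptable"


def efficiency_metrics(placement, profile: InteractionProfile
                       ) -> tuple[float, float]:
    """(ligand efficiency, interactions per heavy atom)."""
    hac = len(placement.mol.heavy_atoms())
    if hac == 0:
        raise ValueError("heavy-atom count is zero")
    le = -placement.dG_bind / hac
    return float(le), float(len(profile) / hac)
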