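"""Atom correspondences between molecules.

Two flavours are produced: *positional* maps (hit vs hit, pure geometry,
used during combination) and *MCS-cascade* maps (candidate topology vs
positioned hits, used during placement).

The positional map is the minimum-total-distance one-to-one assignment of
heavy atoms, with pairs beyond the threshold forbidden; maximising the number
of feasible pairs takes priority over minimising total distance.  Any heavy
element may pair with any other — identity conflicts are resolved later by
the merge step.

The MCS cascade starts from a strict maximum-common-substructure match
(element- and bond-order-exact, ring membership respected) against every hit,
seeds the core with the largest match, then runs progressively laxer passes
(bond order, then element-within-group, then ring membership relaxed) that
extend the map while staying consistent with what is already mapped and with
the hits' mutual positional overlap.  During any pass a small number of
already-mapped atoms may be dropped if that strictly enlarges the total map
("red herring" removal).  User-supplied pairs are immutable and override all
automatic choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS
from scipy.optimize import linear_sum_assignment

from .errors import MappingFailure
from .model import Config, FragmentHit, PositionedMol

_INFEASIBLE = 1.0e6


@dataclass
class AtomMap:
    """One-to-one correspondence between atom indices of two molecules."""

    pairs: frozenset
    kind: str = "positional"     # positional | mcs | user
    left: str = ""
    right: str = ""

    def __post_init__(self):
        lefts = [p[0] for p in self.pairs]
        rights = [p[1] for p in self.pairs]
        if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
            raise ValueError("atom map is not one-to-one")

    @property
    def score(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[int, int]:
        return {l: r for l, r in self.pairs}

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)


def positional_atom_map(a: PositionedMol, b: PositionedMol,
                        threshold: float = 2.0,
                        pair_ok=None) -> AtomMap:
    """Optimal one-to-one heavy-atom assignment by inter-atom distance.

    ``pair_ok(atom_a, atom_b)`` may veto specific pairs (used to keep ring
    placeholders pairing only with ring placeholders).
    """
    atoms_a = [x for x in a.atoms if x.is_heavy]
    atoms_b = [x for x in b.atoms if x.is_heavy]
    if not atoms_a or not atoms_b:
        return AtomMap(frozenset(), "positional", a.name, b.name)
    ca = np.array([x.xyz for x in atoms_a])
    cb = np.array([x.xyz for x in atoms_b])
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    cost = np.where(dist <= threshold, dist, _INFEASIBLE)
    if pair_ok is not None:
        for i, x in enumerate(atoms_a):
            for j, y in enumerate(atoms_b):
                if not pair_ok(x, y):
                    cost[i, j] = _INFEASIBLE
    # deterministic tie-break: bias towards ascending (left, right) indices
    nb = len(atoms_b)
    eps = 1e-9 / (len(atoms_a) * nb + 1)
    tie = np.fromfunction(lambda i, j: (i * nb + j) * eps, cost.shape)
    rows, cols = linear_sum_assignment(cost + tie)
    pairs = []
    for i, j in zip(rows, cols):
        if dist[i, j] <= threshold and cost[i, j] < _INFEASIBLE:
            pairs.append((a.index(atoms_a[i]), b.index(atoms_b[j])))
    return AtomMap(frozenset(pairs), "positional", a.name, b.name)


# --------------------------------------------------------------------------
# MCS cascade
# --------------------------------------------------------------------------

_PERIODIC_GROUPS = {
    "F": 17, "Cl": 17, "Br": 17, "I": 17,
    "O": 16, "S": 16, "Se": 16,
    "N": 15, "P": 15, "As": 15,
    "C": 14, "Si": 14,
    "B": 13,
}


class _GroupAtomCompare(rdFMCS.MCSAtomCompare):
    """Atoms match if they share a periodic group (halogens with halogens...)."""

    def __call__(self, parameters, mol1, atom1, mol2, atom2):  # noqa: D102
        a = mol1.GetAtomWithIdx(atom1)
        b = mol2.GetAtomWithIdx(atom2)
        if a.GetAtomicNum() == b.GetAtomicNum():
            return True
        ga = _PERIODIC_GROUPS.get(a.GetSymbol())
        gb = _PERIODIC_GROUPS.get(b.GetSymbol())
        return ga is not None and ga == gb


def _mcs_params(relax_bonds: bool, relax_elements: bool,
                relax_rings: bool) -> rdFMCS.MCSParameters:
    p = rdFMCS.MCSParameters()
    p.Timeout = 5
    p.AtomCompareParameters.RingMatchesRingOnly = not relax_rings
    p.BondCompareParameters.RingMatchesRingOnly = not relax_rings
    if relax_elements:
        p.AtomTyper = _GroupAtomCompare()
    else:
        p.AtomTyper = rdFMCS.AtomCompare.CompareElements
    p.BondTyper = (rdFMCS.BondCompare.CompareAny if relax_bonds
                   else rdFMCS.BondCompare.CompareOrderExact)
    return p


#: the laxity ladder: each entry is (relax_bonds, relax_elements, relax_rings)
LAXITY_LADDER: tuple[tuple[bool, bool, bool], ...] = (
    (False, False, False),   # strict
    (True, False, False),    # bond order relaxed
    (True, True, False),     # element relaxed within periodic group
    (True, True, True),      # ring membership relaxed
)


def _mcs_correspondences(candidate: Chem.Mol, hit_mol: Chem.Mol,
                         laxity: tuple[bool, bool, bool],
                         max_matches: int = 64):
    """All candidate<->hit atom correspondences from one MCS pass."""
    res = rdFMCS.FindMCS([candidate, hit_mol], _mcs_params(*laxity))
    if res.canceled or res.numAtoms == 0:
        return []
    query = Chem.MolFromSmarts(res.smartsString)
    if query is None:
        return []
    cand_matches = candidate.GetSubstructMatches(
        query, uniquify=False, maxMatches=max_matches)
    hit_matches = hit_mol.GetSubstructMatches(
        query, uniquify=False, maxMatches=max_matches)
    out = []
    for cm in cand_matches:
        for hm in hit_matches:
            out.append(tuple(zip(cm, hm)))
    return out


@dataclass
class _Assignment:
    """Mutable global map: candidate atom -> (hit order index, hit atom, xyz)."""

    entries: dict = field(default_factory=dict)   # cand_idx -> (h, hit_idx)
    locked: set = field(default_factory=set)      # immutable cand indices
    used_hit_atoms: dict = field(default_factory=dict)  # h -> set(hit_idx)

    def position(self, hits, cand_idx):
        h, hit_idx = self.entries[cand_idx]
        return hits[h].mol.atoms[hit_idx].xyz

    def add(self, h, cand_idx, hit_idx):
        self.entries[cand_idx] = (h, hit_idx)
        self.used_hit_atoms.setdefault(h, set()).add(hit_idx)

    def drop(self, cand_idx):
        h, hit_idx = self.entries.pop(cand_idx)
        self.used_hit_atoms[h].discard(hit_idx)


def _hit_rdkit(hit: FragmentHit) -> Chem.Mol:
    try:
        return hit.mol.to_rdkit(sanitize=True)
    except Exception:
        return hit.mol.to_rdkit(sanitize=False)


def mcs_cascade_map(candidate: Chem.Mol, hits: Sequence[FragmentHit],
                    cfg: Optional[Config] = None,
                    user_map: Optional[dict[str, list[tuple[int, int]]]] = None,
                    ) -> list[AtomMap]:
    """Map a candidate topology onto positioned hits, one AtomMap per used hit.

    ``user_map`` is ``{hit_id: [(candidate_idx, hit_idx), ...]}`` with 0-based
    indices; its entries are immutable and override all automatic choices.
    """
    cfg = cfg or Config()
    if not hits:
        raise MappingFailure("no hits supplied")
    hit_mols = [_hit_rdkit(h) for h in hits]
    assignment = _Assignment()

    if user_map:
        hit_index = {h.hit_id: i for i, h in enumerate(hits)}
        for hit_id, pairs in user_map.items():
            if hit_id not in hit_index:
                raise MappingFailure(f"user map references unknown hit {hit_id!r}")
            h = hit_index[hit_id]
            for cand_idx, hit_idx in pairs:
                assignment.add(h, int(cand_idx), int(hit_idx))
                assignment.locked.add(int(cand_idx))

    # strict pass against every hit: largest match seeds the core
    strict = LAXITY_LADDER[0]
    seed_scores = []
    for h, hit_mol in enumerate(hit_mols):
        corrs = _mcs_correspondences(candidate, hit_mol, strict)
        best = max((len(c) for c in corrs), default=0)
        seed_scores.append(best)
    order = sorted(range(len(hits)), key=lambda h: (-seed_scores[h], h))

    for laxity in LAXITY_LADDER:
        for h in order:
            corrs = _mcs_correspondences(candidate, hit_mols[h], laxity)
            _apply_best_correspondence(assignment, hits, h, corrs, cfg)

    if not assignment.entries:
        raise MappingFailure("no hit yields any MCS match with the candidate")

    per_hit: dict[int, set] = {}
    for cand_idx, (h, hit_idx) in assignment.entries.items():
        per_hit.setdefault(h, set()).add((cand_idx, hit_idx))
    return [AtomMap(frozenset(pairs), "mcs", "candidate", hits[h].hit_id)
            for h, pairs in sorted(per_hit.items())]


def _apply_best_correspondence(assignment: _Assignment, hits, h, corrs, cfg):
    """Pick the correspondence that adds the most consistent new atoms."""
    best = None
    for corr in sorted(corrs):
        added, kept, dropped = _evaluate(assignment, hits, h, corr, cfg)
        if added is None:
            continue
        gain = len(added) - len(dropped)
        key = (gain, len(kept), tuple(sorted(added)))
        if gain > 0 and (best is None or key > best[0]):
            best = (key, added, dropped)
    if best is None:
        return
    _, added, dropped = best
    for cand_idx in dropped:
        assignment.drop(cand_idx)
    for cand_idx, hit_idx in added.items():
        assignment.add(h, cand_idx, hit_idx)


def _evaluate(assignment: _Assignment, hits, h, corr, cfg):
    """Classify one correspondence against the current global assignment.

    Returns ``(added, kept, dropped)`` where ``added`` maps new candidate
    atoms to hit atoms, ``kept`` are pairs consistent with what exists and
    ``dropped`` are existing entries that must be excluded (red herrings) —
    or ``(None, None, None)`` if the correspondence is inadmissible.
    """
    added: dict[int, int] = {}
    kept: set[int] = set()
    dropped: set[int] = set()
    used = set(assignment.used_hit_atoms.get(h, set()))
    for cand_idx, hit_idx in corr:
        pos = hits[h].mol.atoms[hit_idx].xyz
        if cand_idx in assignment.entries:
            prev = assignment.position(hits, cand_idx)
            if np.linalg.norm(pos - prev) <= cfg.map_threshold:
                kept.add(cand_idx)        # agrees with the overlap; keep as is
            elif cand_idx in assignment.locked:
                return None, None, None   # cannot touch a user-locked atom
            else:
                dropped.add(cand_idx)     # red herring on the existing side
                if hit_idx not in used and hit_idx not in added.values():
                    added[cand_idx] = hit_idx
        else:
            if hit_idx in used:
                continue
            if cand_idx in added:
                continue
            if hit_idx in added.values():
                continue
            added[cand_idx] = hit_idx
    if len(dropped) > cfg.max_excluded:
        return None, None, None
    return added, kept, dropped
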