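"""Merge/link fragment hits into one molecule by coordinate stitching.

The combination route works on *ring-collapsed* molecules: every smallest
ring is replaced by a single placeholder pseudo-atom at the ring centroid
which remembers the ring's atoms, internal bonds and external attachments.
Hits are folded together pairwise in input order (a hit too distant from the
accumulated merger is deferred to the end of the queue once), placeholders
are re-expanded, disconnected parts are bridged with a short alkyl chain
whose first atom is a heteroatom, and the resulting molecule is repaired
("rectified") until it passes RDKit sanitisation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .errors import (DistanceFailure, LinkFailure, RectificationFailure)
from .mapping import AtomMap, positional_atom_map
from .model import (AROMATIC_ORDER, Atom, Bond, Config, DUMMY, FragmentHit,
                    PositionedMol, max_valence)


def is_placeholder(atom: Atom) -> bool:
    return atom.is_dummy and "ring_stashes" in atom.tags


class RingStash:
    """Contents of one collapsed ring.

    ``members`` are detached copies of the ring atoms (original coordinates
    and tags); ``bonds`` are (member_i, member_j, order) internal to the ring;
    ``ext`` are (member_i, outside_atom_ref, order) attachments to the rest
    of the molecule (the outside ref may itself be a placeholder).
    """

    __slots__ = ("members", "bonds", "ext")

    def __init__(self, members, bonds, ext):
        self.members: list[Atom] = members
        self.bonds: list[tuple[int, int, float]] = bonds
        self.ext: list[tuple[int, Atom, float]] = ext

    def remap(self, memo: dict) -> "RingStash":
        members = [m.copy() for m in self.members]
        ext = [(mi, memo.get(id(ref), ref), order) for mi, ref, order in self.ext]
        return RingStash(members, list(self.bonds), ext)


@dataclass
class CollapsedMol:
    """A PositionedMol whose rings are centroid placeholders."""

    mol: PositionedMol
    map_threshold: float = 2.0

    def placeholders(self) -> list[Atom]:
        return [a for a in self.mol.atoms if is_placeholder(a)]

    def all_positions(self) -> np.ndarray:
        """Coordinates of every real atom, with stashed ring atoms included."""
        coords = [a.xyz for a in self.mol.atoms if not is_placeholder(a)
                  and a.is_heavy and not a.is_dummy]
        for ph in self.placeholders():
            for stash in ph.tags["ring_stashes"]:
                coords.extend(m.xyz for m in stash.members if m.is_heavy)
        return np.array(coords) if coords else np.zeros((0, 3))

    def copy(self) -> tuple["CollapsedMol", dict]:
        mol, memo = self.mol.copy()
        return CollapsedMol(mol, self.map_threshold), memo


@dataclass
class StitchedConformer:
    """The raw merged/placed molecule with per-atom provenance.

    Provenance lives in each atom's ``tags["origin"]``: ``(hit_id, atom_idx)``
    for hit-derived atoms, ``"linker"`` or ``"novel"`` otherwise.
    """

    mol: PositionedMol
    covalent_attachment_index: Optional[int] = None
    processing_order: list[str] = field(default_factory=list)

    def provenance(self) -> list:
        return [a.tags.get("origin") for a in self.mol.atoms]

    def n_novel(self) -> int:
        return sum(1 for a in self.mol.atoms
                   if a.tags.get("origin") in ("linker", "novel"))


# --------------------------------------------------------------------------
# collapse / expand
# --------------------------------------------------------------------------

def collapse_rings(m: PositionedMol, map_threshold: float = 2.0) -> CollapsedMol:
    """Replace each smallest ring by a centroid placeholder pseudo-atom."""
    work, memo = m.copy()
    rings = work.rings()
    if not rings:
        return CollapsedMol(work, map_threshold)

    ring_sets = [set(id(a) for a in ring) for ring in rings]
    atom_first_ring: dict[int, int] = {}
    for ri, rset in enumerate(ring_sets):
        for aid in rset:
            atom_first_ring.setdefault(aid, ri)

    placeholders: list[Atom] = []
    stashes: list[RingStash] = []
    member_index: list[dict[int, int]] = []   # per ring: id(atom) -> slot
    for ring in rings:
        centroid = np.mean([a.xyz for a in ring], axis=0)
        members = [a.copy() for a in ring]
        idx = {id(a): i for i, a in enumerate(ring)}
        stash = RingStash(members, [], [])
        ph = Atom(DUMMY, centroid, tags={"ring_stashes": [stash]})
        placeholders.append(ph)
        stashes.append(stash)
        member_index.append(idx)

    in_ring = set().union(*ring_sets)
    for bond in list(work.bonds):
        ia, ib = id(bond.a), id(bond.b)
        internal_rings = [ri for ri, rset in enumerate(ring_sets)
                          if ia in rset and ib in rset]
        if internal_rings:
            for ri in internal_rings:
                stashes[ri].bonds.append((member_index[ri][ia],
                                          member_index[ri][ib], bond.order))
            continue
        if ia in in_ring and ib in in_ring:
            # direct bond between two different rings (e.g. biphenyl)
            ra, rb = atom_first_ring[ia], atom_first_ring[ib]
            stashes[ra].ext.append((member_index[ra][ia], placeholders[rb], bond.order))
            stashes[rb].ext.append((member_index[rb][ib], placeholders[ra], bond.order))
        elif ia in in_ring:
            ri = atom_first_ring[ia]
            stashes[ri].ext.append((member_index[ri][ia], bond.b, bond.order))
        elif ib in in_ring:
            ri = atom_first_ring[ib]
            stashes[ri].ext.append((member_index[ri][ib], bond.a, bond.order))

    by_id = {id(a): a for a in work.atoms}
    for aid in in_ring:
        work.remove_atom(by_id[aid])
    for ph in placeholders:
        work.add_atom(ph)
    # graph bonds mirroring ext attachments (placeholder connectivity)
    for ph, stash in zip(placeholders, stashes):
        for _, outside, _order in stash.ext:
            if outside in work.atoms:
                work.add_bond(ph, outside, 1.0)
    return CollapsedMol(work, map_threshold)


def _valence_allows(mol: PositionedMol, atom: Atom, order: float) -> bool:
    slack = 0.5 if atom.aromatic else 0.0
    return mol.bond_order_sum(atom) + order <= \
        max_valence(atom.element, atom.charge) + slack


def expand_rings(c: CollapsedMol) -> PositionedMol:
    """Restore stashed ring atoms; unify duplicates from merged placeholders.

    Atoms of a later stash within ``map_threshold`` of an already-restored
    atom of the same placeholder are unified (earlier side wins identity);
    a restored atom exactly duplicating one from another placeholder (shared
    fused-ring atoms) is unified bit-exactly.  An appended ring atom that
    straddles a bonded pair of restored atoms is spliced into the ring
    (the direct bond is removed) rather than left as a bridge.
    """
    work, _ = c.mol.copy()
    exact_registry: dict[tuple, Atom] = {}    # (element, xyz bytes) -> atom
    rep: dict[tuple[int, int], Atom] = {}     # (id(stash), slot) -> atom
    ph_restored: dict[int, list[Atom]] = {}   # id(placeholder) -> atoms
    all_ext: list[tuple[RingStash, int, Atom, float]] = []

    placeholders = [a for a in work.atoms if is_placeholder(a)]
    for ph in placeholders:
        restored_here: list[Atom] = []
        appended_later: list[Atom] = []
        for si, stash in enumerate(ph.tags["ring_stashes"]):
            matched: dict[int, Atom] = {}
            if si > 0 and restored_here:
                prev = PositionedMol(list(restored_here))
                cur = PositionedMol([m.copy() for m in stash.members])
                amap = positional_atom_map(prev, cur, c.map_threshold)
                for pi, mi in amap.pairs:
                    matched[mi] = restored_here[pi]
            for mi, member in enumerate(stash.members):
                if mi in matched:
                    rep[(id(stash), mi)] = matched[mi]
                    continue
                key = (member.element, member.xyz.tobytes())
                if key in exact_registry:
                    rep[(id(stash), mi)] = exact_registry[key]
                    continue
                atom = member
                work.add_atom(atom)
                exact_registry[key] = atom
                rep[(id(stash), mi)] = atom
                restored_here.append(atom)
                if si > 0:
                    atom.tags["needs_rectification"] = True
                    appended_later.append(atom)
            for mi, mj, order in stash.bonds:
                a1, a2 = rep[(id(stash), mi)], rep[(id(stash), mj)]
                if a1 is a2 or work.get_bond(a1, a2) is not None:
                    continue
                if si > 0 and mi in matched and mj in matched:
                    # merge-derived bond between unified atoms: only add it
                    # if valence allows (aromatic atoms get half a unit slack)
                    if not (_valence_allows(work, a1, order)
                            and _valence_allows(work, a2, order)):
                        a1.tags["needs_rectification"] = True
                        a2.tags["needs_rectification"] = True
                        continue
                work.add_bond(a1, a2, order)
            for mi, outside, order in stash.ext:
                all_ext.append((stash, mi, outside, order))
        # ring splice: appended atom bridging two directly-bonded ring atoms
        for atom in appended_later:
            ring_nb = [n for n in work.neighbors(atom) if n in restored_here]
            if len(ring_nb) == 2:
                direct = work.get_bond(ring_nb[0], ring_nb[1])
                if direct is not None:
                    work.remove_bond(direct)
        ph_restored[id(ph)] = restored_here

    for stash, mi, outside, order in all_ext:
        target = rep[(id(stash), mi)]
        if is_placeholder(outside):
            pool = ph_restored.get(id(outside), [])
            if not pool:
                continue
            dists = [np.linalg.norm(a.xyz - target.xyz) for a in pool]
            outside = pool[int(np.argmin(dists))]
        if outside is target:
            continue
        if outside in work.atoms and work.get_bond(target, outside) is None:
            work.add_bond(target, outside, order)

    for ph in placeholders:
        work.remove_atom(ph)
    return work


# --------------------------------------------------------------------------
# merging
# --------------------------------------------------------------------------

def placeholder_pair_ok(x: Atom, y: Atom) -> bool:
    """Placeholders pair only with placeholders; covalent dummies likewise."""
    if is_placeholder(x) != is_placeholder(y):
        return False
    if x.is_dummy != y.is_dummy:
        return False
    return True


def merge_pair(a: CollapsedMol, b: CollapsedMol, amap: AtomMap) -> CollapsedMol:
    """Absorb ``b`` into ``a`` under a positional atom map.

    Unmapped ``b`` atoms are appended with their coordinates; bonds among
    appended atoms are copied, bonds to mapped atoms are redirected to the
    ``a``-side partner.  On mapped pairs the ``a``-side identity wins, unless
    the ``b`` atom is protected (covalent warhead), in which case ``b`` wins.
    """
    out_col, _memo = a.copy()
    out = out_col.mol
    b_memo: dict[int, Atom] = {}
    mapped_b = set()
    for i, j in amap.sorted_pairs():
        a_atom = out.atoms[i]
        b_atom = b.mol.atoms[j]
        mapped_b.add(id(b_atom))
        if b_atom.tags.get("protected") and not a_atom.tags.get("protected"):
            a_atom.element = b_atom.element
            a_atom.charge = b_atom.charge
            a_atom.aromatic = b_atom.aromatic
            a_atom.xyz = b_atom.xyz.copy()
            a_atom.tags = dict(b_atom.tags)
        if is_placeholder(b_atom) and is_placeholder(a_atom):
            pass   # stashes merged below once the memo is complete
        b_memo[id(b_atom)] = a_atom

    for b_atom in b.mol.atoms:
        if id(b_atom) in mapped_b:
            continue
        clone = b_atom.copy()
        out.add_atom(clone)
        b_memo[id(b_atom)] = clone

    # now that every b atom has an image, remap ring stashes
    for b_atom in b.mol.atoms:
        image = b_memo[id(b_atom)]
        if is_placeholder(b_atom):
            remapped = [s.remap(b_memo) for s in b_atom.tags["ring_stashes"]]
            if id(b_atom) in mapped_b:
                image.tags["ring_stashes"] = (image.tags["ring_stashes"]
                                              + remapped)
            else:
                image.tags["ring_stashes"] = remapped

    for bond in b.mol.bonds:
        ta, tb = b_memo[id(bond.a)], b_memo[id(bond.b)]
        if ta is tb:
            continue
        if out.get_bond(ta, tb) is None:
            out.add_bond(ta, tb, bond.order)
            for atom in (ta, tb):
                if not is_placeholder(atom) and not atom.is_dummy:
                    if out.bond_order_sum(atom) > max_valence(atom.element,
                                                              atom.charge):
                        atom.tags["needs_rectification"] = True
    return out_col


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def _substitutable(mol: PositionedMol, atom: Atom) -> bool:
    if not atom.is_heavy or atom.is_dummy:
        return False
    if atom.tags.get("protected"):
        return False
    return mol.bond_order_sum(atom) < max_valence(atom.element, atom.charge)


def linker_atom_count(distance: float, spacing: float = 1.22) -> int:
    """Number of chain atoms bridging a gap: round(d / spacing) - 1, >= 0.

    Half-way cases round down so that d = 1.5 * spacing (1.83 A at the
    default) still gives a direct bond.
    """
    return max(0, int(np.ceil(distance / spacing - 0.5)) - 1)


def link_if_disconnected(s: StitchedConformer, cfg: Optional[Config] = None
                         ) -> StitchedConformer:
    """Bridge disconnected components with short alkyl chains.

    The globally closest inter-component pair of substitutable atoms is
    joined; ``n = round(d/1.22) - 1`` chain atoms are inserted evenly spaced
    on the segment, the first being ``cfg.linker_first_element`` (default
    nitrogen), the rest carbon, all single-bonded.
    """
    cfg = cfg or Config()
    mol = s.mol
    while True:
        comps = mol.connected_components()
        if len(comps) <= 1:
            return s
        best = None
        for ci in range(len(comps)):
            for cj in range(ci + 1, len(comps)):
                for x in comps[ci]:
                    if not _substitutable(mol, x):
                        continue
                    for y in comps[cj]:
                        if not _substitutable(mol, y):
                            continue
                        d = float(np.linalg.norm(x.xyz - y.xyz))
                        if best is None or d < best[0]:
                            best = (d, x, y)
        if best is None:
            raise LinkFailure("no substitutable atom pair between components")
        d, x, y = best
        n = linker_atom_count(d, cfg.linker_spacing)
        prev = x
        for k in range(1, n + 1):
            frac = k / (n + 1)
            xyz = x.xyz + (y.xyz - x.xyz) * frac
            element = cfg.linker_first_element if k == 1 else "C"
            atom = Atom(element, xyz, tags={"origin": "linker"})
            mol.add_atom(atom)
            mol.add_bond(prev, atom, 1.0)
            prev = atom
        mol.add_bond(prev, y, 1.0)


# --------------------------------------------------------------------------
# rectification
# --------------------------------------------------------------------------

def _ring_membership(mol: PositionedMol) -> dict[int, list[list[Atom]]]:
    rings = mol.rings()
    out: dict[int, list[list[Atom]]] = {}
    for ring in rings:
        for atom in ring:
            out.setdefault(id(atom), []).append(ring)
    return out


def _order_ring(mol: PositionedMol, ring: list[Atom]) -> list[Atom]:
    """Walk a ring atom set into cyclic order."""
    members = set(id(a) for a in ring)
    start = ring[0]
    ordered = [start]
    prev = None
    cur = start
    while len(ordered) < len(ring):
        nxt = [n for n in mol.neighbors(cur)
               if id(n) in members and n is not prev]
        if not nxt:
            return ring   # not a clean cycle; give up on ordering
        prev, cur = cur, nxt[0]
        ordered.append(cur)
    return ordered


def _has_double(mol: PositionedMol, atom: Atom) -> bool:
    return any(b.order >= 2.0 and b.order != AROMATIC_ORDER
               for b in mol.bonds_of(atom))


def _dearomatise_ring(mol: PositionedMol, ring: list[Atom],
                      sp3: set[int]) -> None:
    """Kekulise a ring with the given atoms forced sp3 (single bonds)."""
    ordered = _order_ring(mol, ring)
    n = len(ordered)
    for atom in ordered:
        atom.aromatic = False
    ring_bonds = []
    for i in range(n):
        bond = mol.get_bond(ordered[i], ordered[(i + 1) % n])
        if bond is not None:
            ring_bonds.append((bond, ordered[i], ordered[(i + 1) % n]))
    for bond, _, _ in ring_bonds:
        if bond.order == AROMATIC_ORDER:
            bond.order = 1.0
    # alternate doubles where both endpoints can still take one
    for bond, u, v in ring_bonds:
        if id(u) in sp3 or id(v) in sp3:
            continue
        if _has_double(mol, u) or _has_double(mol, v):
            continue
        if u.element in ("O", "S") or v.element in ("O", "S"):
            continue
        spare_u = max_valence(u.element, u.charge) - mol.bond_order_sum(u)
        spare_v = max_valence(v.element, v.charge) - mol.bond_order_sum(v)
        if spare_u >= 1 and spare_v >= 1:
            bond.order = 2.0


def _fix_geminal_aromatics(mol: PositionedMol) -> bool:
    """Dearomatise rings whose aromatic atoms carry two exocyclic groups."""
    changed = False
    membership = _ring_membership(mol)
    for atom in list(mol.atoms):
        if not atom.aromatic:
            continue
        rings = membership.get(id(atom), [])
        if not rings:
            atom.aromatic = False
            changed = True
            continue
        ring_atoms = set()
        for ring in rings:
            ring_atoms |= {id(a) for a in ring}
        exo = [n for n in mol.neighbors(atom)
               if n.is_heavy and id(n) not in ring_atoms]
        if len(exo) >= 2:
            for ring in rings:
                _dearomatise_ring(mol, ring, {id(atom)})
            changed = True
    return changed


def _fix_texas_carbons(mol: PositionedMol, protected_ok: bool = True) -> bool:
    """Pentavalent carbons lose their geometrically longest bond."""
    changed = False
    for atom in list(mol.atoms):
        if atom.element != "C" or atom.aromatic:
            continue
        if any(b.is_aromatic for b in mol.bonds_of(atom)):
            continue
        while mol.bond_order_sum(atom) > max_valence("C", atom.charge):
            candidates = [b for b in mol.bonds_of(atom)
                          if not (b.a.tags.get("protected")
                                  and b.b.tags.get("protected"))]
            if not candidates:
                break
            longest = max(candidates,
                          key=lambda b: float(np.linalg.norm(b.a.xyz - b.b.xyz)))
            mol.remove_bond(longest)
            changed = True
    return changed


def _fix_overfull(mol: PositionedMol) -> bool:
    """Charge-adjust or shift a group off aliphatic atoms with bad valence."""
    changed = False
    for atom in list(mol.atoms):
        if atom.is_dummy or atom.aromatic or atom.element == "C":
            continue
        if any(b.is_aromatic for b in mol.bonds_of(atom)):
            continue
        excess = mol.bond_order_sum(atom) - max_valence(atom.element, atom.charge)
        if excess <= 0:
            continue
        if atom.element == "N" and atom.charge == 0 and \
                mol.bond_order_sum(atom) <= 4:
            atom.charge = 1
            changed = True
            continue
        if atom.element == "O" and atom.charge == 0 and \
                mol.bond_order_sum(atom) <= 3:
            atom.charge = 1
            changed = True
            continue
        # migrate one substituent to an adjacent atom with spare valence
        moved = False
        bonds = sorted(mol.bonds_of(atom),
                       key=lambda b: -float(np.linalg.norm(b.a.xyz - b.b.xyz)))
        for bond in bonds:
            other = bond.other(atom)
            if other.tags.get("protected"):
                continue
            for host in mol.neighbors(atom):
                if host is other or host.is_dummy:
                    continue
                spare = max_valence(host.element, host.charge) - \
                    mol.bond_order_sum(host)
                if spare >= bond.order and mol.get_bond(host, other) is None:
                    mol.remove_bond(bond)
                    mol.add_bond(host, other, bond.order)
                    moved = True
                    break
            if moved:
                break
        if moved:
            changed = True
            continue
        # last resort: drop the longest bond
        if bonds and not (bonds[0].a.tags.get("protected")
                          and bonds[0].b.tags.get("protected")):
            mol.remove_bond(bonds[0])
            changed = True
    return changed


def _sanitize_error(mol: PositionedMol) -> Optional[str]:
    try:
        mol.to_rdkit(sanitize=True)
        return None
    except Exception as exc:
        return str(exc)


def _fix_unkekulizable(mol: PositionedMol, message: str) -> bool:
    """Fallback: dearomatise rings implicated in a kekulisation failure."""
    indices = [int(tok) for tok in re.findall(r"\b(\d+)\b", message)
               if int(tok) < len(mol.atoms)]
    flagged = {id(mol.atoms[i]) for i in indices}
    changed = False
    for ring in mol.rings():
        ring_ids = {id(a) for a in ring}
        aromatic = any(a.aromatic for a in ring)
        if not aromatic:
            continue
        if flagged and not (ring_ids & flagged):
            continue
        hetero = {id(a) for a in ring if a.element not in ("C", "N")}
        _dearomatise_ring(mol, ring, hetero or {id(ring[0])})
        changed = True
    return changed


def _fix_explicit_valence(mol: PositionedMol, message: str) -> bool:
    """Target the atom named in an RDKit explicit-valence error."""
    match = re.search(r"atom\s*#\s*(\d+)", message)
    if not match:
        return False
    idx = int(match.group(1))
    if idx >= len(mol.atoms):
        return False
    atom = mol.atoms[idx]
    if atom.aromatic or any(b.is_aromatic for b in mol.bonds_of(atom)):
        membership = _ring_membership(mol)
        rings = membership.get(id(atom), [])
        for ring in rings:
            _dearomatise_ring(mol, ring, {id(atom)})
        atom.aromatic = False
        if rings:
            return True
    excess = mol.bond_order_sum(atom) - max_valence(atom.element, atom.charge)
    changed = False
    while excess > 0:
        bonds = [b for b in mol.bonds_of(atom)
                 if not (b.a.tags.get("protected") and b.b.tags.get("protected"))]
        if not bonds:
            break
        longest = max(bonds, key=lambda b: float(np.linalg.norm(b.a.xyz - b.b.xyz)))
        mol.remove_bond(longest)
        changed = True
        excess = mol.bond_order_sum(atom) - max_valence(atom.element, atom.charge)
    return changed


def rectify(m: PositionedMol, cfg: Optional[Config] = None) -> PositionedMol:
    """Repair chemistry until the molecule passes RDKit sanitisation.

    Applied iteratively to fixpoint: geminal-substituted arenes are
    dearomatised with the offending atom sp3, overfull aliphatic atoms are
    charge-adjusted or have a group shifted to a neighbour, pentavalent
    carbons lose their longest bond.  Raises :class:`RectificationFailure`
    if no fixpoint is reached.
    """
    cfg = cfg or Config()
    work, _ = m.copy()
    for _ in range(cfg.rectify_max_iter):
        changed = False
        changed |= _fix_geminal_aromatics(work)
        changed |= _fix_texas_carbons(work)
        changed |= _fix_overfull(work)
        error = _sanitize_error(work)
        if error is None:
            for atom in work.atoms:
                atom.tags.pop("needs_rectification", None)
            return work
        if ("kekulize" in error.lower() or "aromatic" in error.lower()):
            changed |= _fix_unkekulizable(work, error)
        if "valence" in error.lower():
            changed |= _fix_explicit_valence(work, error)
        if not changed:
            raise RectificationFailure(
                f"no further repair possible: {error}")
    raise RectificationFailure(
        f"fixpoint not reached in {cfg.rectify_max_iter} iterations")


# --------------------------------------------------------------------------
# full combination
# --------------------------------------------------------------------------

def _tag_origins(hit: FragmentHit) -> PositionedMol:
    mol, _ = hit.mol.copy()
    mol.name = hit.hit_id
    for i, atom in enumerate(mol.atoms):
        atom.tags.setdefault("origin", (hit.hit_id, i))
    return mol


def _min_distance(a: CollapsedMol, b: CollapsedMol) -> float:
    pa, pb = a.all_positions(), b.all_positions()
    if len(pa) == 0 or len(pb) == 0:
        return 0.0
    return float(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1).min())


def combine(hits: Sequence[FragmentHit], cfg: Optional[Config] = None,
            do_rectify: bool = True) -> StitchedConformer:
    """Merge/link hits pairwise in input order into a stitched conformer.

    A hit whose minimum inter-atom distance to the accumulated merger exceeds
    ``cfg.join_cutoff`` is deferred to the end of the queue once; if it is
    still beyond the cutoff at its second visit a :class:`DistanceFailure`
    is raised.  Covalent attachment and warhead atoms are never altered.
    """
    from .covalent import protect_hit   # deferred import; small helper

    cfg = cfg or Config()
    if not hits:
        raise ValueError("at least one hit is required")
    tagged = []
    for hit in hits:
        mol = _tag_origins(hit)
        if hit.is_covalent:
            protect_hit(mol, hit.covalent_attachment_index)
        tagged.append((hit.hit_id, collapse_rings(mol, cfg.map_threshold)))

    order: list[str] = [tagged[0][0]]
    acc = tagged[0][1]
    queue = list(tagged[1:])
    deferred: set[str] = set()
    while queue:
        hit_id, col = queue.pop(0)
        dmin = _min_distance(acc, col)
        if dmin > cfg.join_cutoff:
            if hit_id in deferred:
                raise DistanceFailure(hit_id, dmin)
            deferred.add(hit_id)
            queue.append((hit_id, col))
            continue
        amap = positional_atom_map(acc.mol, col.mol, cfg.map_threshold,
                                   pair_ok=placeholder_pair_ok)
        acc = merge_pair(acc, col, amap)
        order.append(hit_id)

    expanded = expand_rings(acc)
    stitched = StitchedConformer(expanded, processing_order=order)
    stitched = link_if_disconnected(stitched, cfg)
    if do_rectify:
        stitched = StitchedConformer(rectify(stitched.mol, cfg),
                                     processing_order=order)
    for i, atom in enumerate(stitched.mol.atoms):
        if atom.is_dummy and not is_placeholder(atom):
            stitched.covalent_attachment_index = i
            break
    return stitched
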