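"""Constrained placement: hit-faithful conformers for candidate molecules.

A candidate topology is mapped onto the positioned hits by the MCS cascade;
mapped atoms inherit their hit atoms' coordinates directly, and each
connected patch of unmapped ("novel") atoms borrows coordinates from a
seeded generated conformer rigidly superposed onto the three mapped atoms
nearest the patch.  The stitched conformer is then pre-minimised against a
frozen pocket cutout and run through in-pocket cycles.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .combine import StitchedConformer
from .covalent import mark_covalent, nearest_cysteine
from .errors import MappingFailure, PlacementFailure
from .geometry import apply_rigid, kabsch, rmsd
from .io import ProteinModel
from .mapping import AtomMap, mcs_cascade_map
from .minimize import (MinimizedPlacement, build_restraints,
                       pocket_min_cycles, premin_frozen_neighbourhood)
from .model import Config, FragmentHit, PositionedMol

SUPERPOSITION_RESIDUAL_LIMIT = 1.0   # A; above this, try more conformers


def _seeded_conformers(topology: Chem.Mol, seed: int, n: int) -> list[np.ndarray]:
    """Heavy-atom coordinate sets from seeded distance-geometry embedding."""
    mol = Chem.AddHs(Chem.Mol(topology))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params)
    if not ids:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params)
    if not ids:
        raise PlacementFailure("conformer generation failed for candidate")
    mol = Chem.RemoveHs(mol)
    out = []
    for cid in ids:
        conf = mol.GetConformer(cid)
        out.append(np.array([list(conf.GetAtomPosition(i))
                             for i in range(mol.GetNumAtoms())]))
    return out


def stitch_candidate(candidate: Chem.Mol, maps: Sequence[AtomMap],
                     hits: Sequence[FragmentHit],
                     cfg: Optional[Config] = None) -> StitchedConformer:
    """Assemble candidate coordinates from the hit maps.

    Mapped atoms take their hit atom's coordinates verbatim (the
    larger-coverage map wins any conflict); unmapped patches are filled from
    a generated conformer superposed, per patch, on the three mapped atoms
    nearest the patch's attachment point.
    """
    cfg = cfg or Config()
    if not maps or all(m.score == 0 for m in maps):
        raise MappingFailure("no mapped atoms; cannot stitch candidate")
    hit_by_id = {h.hit_id: h for h in hits}

    n = candidate.GetNumAtoms()
    coords = np.full((n, 3), np.nan)
    origin: list = [None] * n
    for amap in sorted(maps, key=lambda m: -m.score):
        hit = hit_by_id[amap.right]
        for cand_idx, hit_idx in amap.sorted_pairs():
            if origin[cand_idx] is None:
                coords[cand_idx] = hit.mol.atoms[hit_idx].xyz
                origin[cand_idx] = (hit.hit_id, hit_idx)

    unmapped = [i for i in range(n) if origin[i] is None]
    if unmapped:
        _fill_novel_patches(candidate, coords, origin, unmapped, cfg)

    mol = PositionedMol.from_rdkit(_with_coords(candidate, coords))
    for i, atom in enumerate(mol.atoms):
        atom.tags["origin"] = origin[i]
    stitched = StitchedConformer(mol)
    for i, atom in enumerate(mol.atoms):
        if atom.is_dummy:
            stitched.covalent_attachment_index = i
            break
    return stitched


def _with_coords(topology: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    mol = Chem.Mol(topology)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*map(float, xyz)))
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)
    return mol


def _patches(candidate: Chem.Mol, unmapped: list[int]) -> list[list[int]]:
    pool = set(unmapped)
    patches = []
    while pool:
        seed = min(pool)
        patch = {seed}
        frontier = [seed]
        while frontier:
            idx = frontier.pop()
            for nb in candidate.GetAtomWithIdx(idx).GetNeighbors():
                j = nb.GetIdx()
                if j in pool and j not in patch:
                    patch.add(j)
                    frontier.append(j)
        pool -= patch
        patches.append(sorted(patch))
    return patches


def _fill_novel_patches(candidate, coords, origin, unmapped, cfg) -> None:
    conformers = _seeded_conformers(candidate, cfg.seed, 1)
    mapped = [i for i in range(candidate.GetNumAtoms()) if origin[i] is not None]
    for patch in _patches(candidate, unmapped):
        # graph-then-space: the mapped neighbour of the patch is the anchor,
        # then the three mapped atoms spatially nearest to it are the frame
        anchors = []
        for idx in patch:
            for nb in candidate.GetAtomWithIdx(idx).GetNeighbors():
                if origin[nb.GetIdx()] is not None:
                    anchors.append(nb.GetIdx())
        anchor = anchors[0] if anchors else mapped[0]
        ref = coords[anchor]
        frame = sorted(mapped, key=lambda i: (np.linalg.norm(coords[i] - ref), i))
        frame = frame[:3]
        if len(frame) < 3:
            frame = (frame * 3)[:3]

        best = None
        for trial, conf_coords in enumerate(conformers):
            rot, trans = kabsch(conf_coords[frame], coords[frame])
            residual = rmsd(apply_rigid(conf_coords[frame], rot, trans),
                            coords[frame])
            placed = apply_rigid(conf_coords[patch], rot, trans)
            if best is None or residual < best[0]:
                best = (residual, placed)
            if residual <= SUPERPOSITION_RESIDUAL_LIMIT:
                break
        if best[0] > SUPERPOSITION_RESIDUAL_LIMIT and len(conformers) == 1:
            conformers = _seeded_conformers(candidate, cfg.seed, 10)
            for conf_coords in conformers[1:]:
                rot, trans = kabsch(conf_coords[frame], coords[frame])
                residual = rmsd(apply_rigid(conf_coords[frame], rot, trans),
                                coords[frame])
                if residual < best[0]:
                    best = (residual,
                            apply_rigid(conf_coords[patch], rot, trans))
        for k, idx in enumerate(patch):
            coords[idx] = best[1][k]
            origin[idx] = "novel"


def rmsd_vs_hits(mol: PositionedMol, maps: Sequence[AtomMap],
                 hits: Sequence[FragmentHit]) -> float:
    """Combined RMSD of mapped atoms against their hit positions."""
    hit_by_id = {h.hit_id: h for h in hits}
    sq = []
    for amap in maps:
        hit = hit_by_id[amap.right]
        for cand_idx, hit_idx in amap.pairs:
            d = mol.atoms[cand_idx].xyz - hit.mol.atoms[hit_idx].xyz
            sq.append(float(d @ d))
    if not sq:
        return 0.0
    return float(np.sqrt(np.mean(sq)))


def place(candidate_smiles: str, hits: Sequence[FragmentHit],
          template: Optional[ProteinModel] = None,
          cfg: Optional[Config] = None,
          user_map: Optional[dict] = None,
          minimise: bool = True,
          name: str = "") -> MinimizedPlacement:
    """Full placement pipeline: map, stitch, pre-minimise, pocket cycles.

    A dummy atom in the SMILES triggers covalent mode (attachment to the
    nearest cysteine S-gamma).  Returns a :class:`MinimizedPlacement`; any
    stage failure raises its typed exception.
    """
    from .interactions import acceptability   # late import: sibling module

    cfg = cfg or Config()
    topology, attachment, warhead = mark_covalent(candidate_smiles)
    maps = mcs_cascade_map(topology, hits, cfg, user_map=user_map)
    stitched = stitch_candidate(topology, maps, hits, cfg)
    stitched.mol.name = name or candidate_smiles
    for idx in warhead:
        stitched.mol.atoms[idx].tags["protected"] = True

    covalent_bond = None
    if attachment is not None and template is not None:
        residue = nearest_cysteine(template, stitched.mol.atoms[attachment].xyz)
        if residue is not None:
            neighbours = stitched.mol.neighbors(stitched.mol.atoms[attachment])
            if neighbours:
                covalent_bond = (stitched.mol.index(neighbours[0]), residue)

    coverage = {m.right: m.score for m in maps}
    if not minimise:
        result = MinimizedPlacement(
            mol=stitched.mol, cycles=0, engine="none",
            rmsd_vs_hits=rmsd_vs_hits(stitched.mol, maps, hits),
            hit_coverage=coverage,
            n_novel=stitched.n_novel())
        if covalent_bond is not None:
            result.covalent_residue = covalent_bond[1]
        return result

    restraints = build_restraints(stitched, cfg)
    preminned = premin_frozen_neighbourhood(stitched, restraints, template,
                                            cfg, covalent_bond=covalent_bond)
    result = pocket_min_cycles(stitched, restraints, template, cfg,
                               covalent_bond=covalent_bond, start=preminned)
    result.rmsd_vs_hits = rmsd_vs_hits(result.mol, maps, hits)
    result.hit_coverage = coverage
    verdict, reason = acceptability(result, hits)
    result.acceptable = verdict
    result.reason = reason
    return result
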