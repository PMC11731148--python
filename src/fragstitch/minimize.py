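"""Two-stage constrained minimisation.

Stage one minimises the ligand with a generic force field against a frozen
protein cutout, under tiered flat-bottom positional restraints towards the
stitched coordinates (heavy for exocyclic mapped atoms, moderate for ring
atoms, none for amide/urea/ester atoms and novel atoms) plus a torsional
penalty keeping exocyclic secondary amides trans.  Stage two repeats the
minimisation with nearby residues mobile, halving the global restraint scale
each cycle until the predicted binding energy goes negative.

The engine contract is pluggable; the default is RDKit MMFF with a UFF
fallback (no licensed dependency).  The predicted binding energy is a single
snapshot difference of bound minus unbound states, always recomputed
restraint-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import MinimisationFailure
from .geometry import rmsd
from .io import ProteinAtom, ProteinModel
from .model import Config, PositionedMol, ligand_length

TRANS_WINDOW = 30.0      # degrees around 180 allowed for secondary amides
FAR_OFFSET = 500.0       # A; ligand translation defining the unbound snapshot

_AMIDE_ESTER_UREA = (
    "[NX3][CX3]=[OX1]",          # amide
    "[OX2][CX3]=[OX1]",          # ester
    "[NX3][CX3](=[OX1])[NX3]",   # urea
)
_SECONDARY_AMIDE_TORSION = "[!#1;!$([OX1]):1][CX3:2](=[OX1])[NX3;H1:3][!#1:4]"


@dataclass
class PositionalRestraint:
    atom_index: int
    weight: float            # kcal/mol/A^2 flat-bottom force constant
    tier: str                # heavy | moderate | none
    target: np.ndarray = None


@dataclass
class TorsionRestraint:
    atoms: tuple[int, int, int, int]
    target_deg: float = 180.0
    window_deg: float = TRANS_WINDOW
    weight: float = 20.0


@dataclass
class RestraintSet:
    positional: list[PositionalRestraint] = field(default_factory=list)
    torsional: list[TorsionRestraint] = field(default_factory=list)
    scale: float = 1.0
    flat_bottom: float = 0.5

    def by_atom(self) -> dict[int, PositionalRestraint]:
        return {r.atom_index: r for r in self.positional}


@dataclass
class MinimizedPlacement:
    """Final pose with its diagnostics and acceptability verdict."""

    mol: PositionedMol
    dG_bind: float = 0.0
    rmsd_vs_hits: float = 0.0
    rmsd_vs_start: float = 0.0
    cycles: int = 0
    engine: str = "rdkit"
    acceptable: bool = False
    reason: str = ""
    scale_schedule: list[float] = field(default_factory=list)
    dg_history: list[float] = field(default_factory=list)
    covalent_residue: Optional[str] = None
    covalent_bond_length: Optional[float] = None
    hit_coverage: dict = field(default_factory=dict)
    n_novel: int = 0
    protein_final: Optional[ProteinModel] = None   # minimised pocket cutout


# --------------------------------------------------------------------------
# restraint construction
# --------------------------------------------------------------------------

def build_restraints(stitched, cfg: Optional[Config] = None) -> RestraintSet:
    """Tiered restraints from per-atom provenance.

    Novel/linker atoms and amide/urea/ester atoms are unrestrained; ring
    atoms get the moderate weight, remaining (exocyclic) mapped atoms the
    heavy weight.  Exocyclic secondary amides get a trans torsion penalty.
    """
    cfg = cfg or Config()
    mol = stitched.mol
    try:
        rd = mol.to_rdkit(sanitize=True)
    except Exception:
        rd = mol.to_rdkit(sanitize=False)

    relaxed: set[int] = set()
    for smarts in _AMIDE_ESTER_UREA:
        patt = Chem.MolFromSmarts(smarts)
        for match in rd.GetSubstructMatches(patt):
            relaxed.update(match)
    ring_atoms = {mol.index(a) for ring in mol.rings() for a in ring}

    restraints = RestraintSet(flat_bottom=cfg.restraint_flat_bottom)
    for i, atom in enumerate(mol.atoms):
        origin = atom.tags.get("origin")
        if origin in ("novel", "linker") or origin is None:
            tier, weight = "none", 0.0
        elif i in relaxed:
            tier, weight = "none", 0.0
        elif i in ring_atoms:
            tier, weight = "moderate", cfg.moderate_restraint
        else:
            tier, weight = "heavy", cfg.heavy_restraint
        restraints.positional.append(PositionalRestraint(
            i, weight, tier, atom.xyz.copy()))

    patt = Chem.MolFromSmarts(_SECONDARY_AMIDE_TORSION)
    mapped_positions = [a.GetIdx() for a in patt.GetAtoms()
                        if a.GetAtomMapNum() > 0]
    mapped_positions.sort(key=lambda i:
                          patt.GetAtomWithIdx(i).GetAtomMapNum())
    for match in rd.GetSubstructMatches(patt):
        atoms = tuple(match[i] for i in mapped_positions)
        restraints.torsional.append(TorsionRestraint(atoms))
    return restraints


# --------------------------------------------------------------------------
# force-field engine (RDKit MMFF with UFF fallback)
# --------------------------------------------------------------------------

def _ligand_with_hs(mol: PositionedMol,
                    anchor: Optional[int] = None) -> tuple[Chem.Mol, list[int]]:
    """Sanitised RDKit ligand with explicit hydrogens added on coordinates.

    Dummy atoms (covalent attachment markers standing in for the protein
    nucleophile) are stripped before force-field setup; when ``anchor`` (the
    dummy's neighbour, original indexing) is given, one hydrogen slot is
    reserved on it for the covalent bond to the protein.  Returns
    ``(mol_with_h, kept)`` where ``kept`` lists the original indices of the
    retained heavy atoms, in order.
    """
    kept = [i for i, a in enumerate(mol.atoms) if not a.is_dummy]
    sub = PositionedMol(
        [mol.atoms[i] for i in kept],
        [b for b in mol.bonds if not b.a.is_dummy and not b.b.is_dummy])
    # note: sub shares atom objects with mol; only used to build the RDKit mol
    rd = sub.to_rdkit(sanitize=True)
    if anchor is not None:
        sub_idx = kept.index(anchor)
        rd_anchor = rd.GetAtomWithIdx(sub_idx)
        n_h = rd_anchor.GetTotalNumHs()
        if n_h > 0:
            rd_anchor.SetNoImplicit(True)
            rd_anchor.SetNumExplicitHs(n_h - 1)
            Chem.SanitizeMol(rd)
    rd_h = Chem.AddHs(rd, addCoords=True)
    return rd_h, kept


def _pocket_rdkit(protein: ProteinModel) -> Chem.Mol:
    block = protein.to_pdb_block()
    mol = Chem.MolFromPDBBlock(block, sanitize=False, removeHs=False,
                               proximityBonding=True)
    if mol is None:
        raise MinimisationFailure("protein cutout could not be parsed")
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    return mol


class RdkitEngine:
    """Default engine: one combined molecule, MMFF when parameterised, UFF
    otherwise.  Implements the pluggable contract: given atoms + restraints,
    return minimised coordinates and restraint-free energies."""

    name = "rdkit-mmff/uff"

    def __init__(self, ligand: PositionedMol,
                 protein: Optional[ProteinModel] = None,
                 covalent_bond: Optional[tuple[int, str]] = None):
        self._full_coords = ligand.coords()
        anchor = covalent_bond[0] if (covalent_bond is not None
                                      and protein is not None) else None
        lig_h, self.kept = _ligand_with_hs(ligand, anchor=anchor)
        self._orig_to_sub = {orig: i for i, orig in enumerate(self.kept)}
        self.protein = protein
        self.covalent_pair: Optional[tuple[int, int]] = None
        self._lig_h = lig_h
        self._pocket: Optional[Chem.Mol] = None
        if protein is not None and protein.atoms:
            pocket = _pocket_rdkit(protein)
            self._pocket = pocket
            combined = Chem.RWMol(Chem.CombineMols(lig_h, pocket))
            self.n_ligand = lig_h.GetNumAtoms()
            if covalent_bond is not None:
                lig_idx, residue_id = covalent_bond
                sg = self._find_protein_atom(residue_id, "SG")
                if sg is None:
                    raise MinimisationFailure(
                        f"no SG atom in residue {residue_id}")
                # the covalent link is a real bond in the engine topology
                combined.AddBond(self._orig_to_sub[lig_idx],
                                 self.n_ligand + sg, Chem.BondType.SINGLE)
                self.covalent_pair = (self._orig_to_sub[lig_idx],
                                      self.n_ligand + sg)
            self.mol = combined.GetMol()
            try:
                Chem.SanitizeMol(self.mol)
            except Exception:
                self.mol.UpdatePropertyCache(strict=False)
                Chem.FastFindRings(self.mol)
        else:
            self.mol = lig_h
            self.n_ligand = lig_h.GetNumAtoms()

    def _find_protein_atom(self, residue_id: str, name: str) -> Optional[int]:
        for i, atom in enumerate(self.protein.atoms):
            if atom.residue_id == residue_id and atom.name == name:
                return i
        return None

    def _forcefield(self, mol: Chem.Mol):
        try:
            props = AllChem.MMFFGetMoleculeProperties(mol)
            if props is not None:
                ff = AllChem.MMFFGetMoleculeForceField(
                    mol, props, nonBondedThresh=100.0,
                    ignoreInterfragInteractions=False)
                if ff is not None:
                    return ff, "mmff"
        except Exception:
            pass
        try:
            ff = AllChem.UFFGetMoleculeForceField(
                mol, vdwThresh=100.0, ignoreInterfragInteractions=False)
            if ff is None:
                raise MinimisationFailure("UFF setup returned None")
            return ff, "uff"
        except MinimisationFailure:
            raise
        except Exception as exc:
            raise MinimisationFailure(f"force-field setup failed: {exc}")

    # -- coordinates ------------------------------------------------------
    def ligand_coords(self) -> np.ndarray:
        """Full-length ligand heavy-atom coordinates (original indexing).

        Stripped dummy atoms keep their input coordinates.
        """
        conf = self.mol.GetConformer()
        out = self._full_coords.copy()
        for orig, sub in self._orig_to_sub.items():
            out[orig] = list(conf.GetAtomPosition(sub))
        return out

    def _apply_restraints(self, ff, kind: str, restraints: RestraintSet,
                          scale: float) -> None:
        add_tors = (ff.MMFFAddTorsionConstraint if kind == "mmff"
                    else ff.UFFAddTorsionConstraint)
        add_dist = (ff.MMFFAddDistanceConstraint if kind == "mmff"
                    else ff.UFFAddDistanceConstraint)
        for r in restraints.positional:
            if r.weight <= 0 or r.atom_index not in self._orig_to_sub:
                continue
            # flat-bottom restraint towards the stitched target: a fixed
            # extra point at the target tied to the atom by a 0..bottom
            # distance constraint
            ep = ff.AddExtraPoint(float(r.target[0]), float(r.target[1]),
                                  float(r.target[2]), fixed=True)
            idx = self._orig_to_sub[r.atom_index]
            add_dist(idx, ep - 1, False, 0.0,
                     restraints.flat_bottom, r.weight * scale)
            # weak inner harmonic: negligible at working scales, pins the
            # atom to its target in the scale -> infinity limit
            add_dist(idx, ep - 1, False, 0.0, 0.0,
                     0.1 * r.weight * scale)
        for t in restraints.torsional:
            if any(i not in self._orig_to_sub for i in t.atoms):
                continue
            lo = t.target_deg - t.window_deg
            hi = t.target_deg + t.window_deg
            atoms = tuple(self._orig_to_sub[i] for i in t.atoms)
            add_tors(*atoms, False, lo, hi, t.weight * scale)

    def minimize(self, restraints: Optional[RestraintSet] = None,
                 scale: float = 1.0,
                 frozen: Optional[Sequence[int]] = None,
                 max_its: int = 500) -> None:
        ff, kind = self._forcefield(self.mol)
        if restraints is not None:
            self._apply_restraints(ff, kind, restraints, scale)
        if frozen is not None:
            for idx in frozen:
                ff.AddFixedPoint(int(idx))
        ff.Initialize()
        ff.Minimize(maxIts=max_its)

    # -- energies (always restraint-free) ---------------------------------
    def energy(self) -> float:
        ff, _ = self._forcefield(self.mol)
        return float(ff.CalcEnergy())

    def _sync_fragment(self, template: Chem.Mol, offset: int) -> Chem.Mol:
        out = Chem.Mol(template)
        src = self.mol.GetConformer()
        dst = out.GetConformer()
        for i in range(out.GetNumAtoms()):
            dst.SetAtomPosition(i, src.GetAtomPosition(offset + i))
        return out

    def binding_delta_g(self) -> float:
        """Single snapshot bound-minus-unbound energy difference (kcal/mol).

        Unbound: the same coordinates scored as separated fragments (pocket
        alone plus ligand alone), so the difference collects exactly the
        cross terms.  Restraints never enter: fresh force fields are built
        for the snapshots.  All three systems must use the same force-field
        flavour; UFF is forced otherwise.
        """
        if self.protein is None or not self.protein.atoms:
            return 0.0
        lig = self._sync_fragment(self._lig_h, 0)
        pocket = self._sync_fragment(self._pocket, self.n_ligand)
        systems = [self.mol, lig, pocket]
        ffs = [self._forcefield(s) for s in systems]
        # a covalent link changes MMFF atom typing between the complex and
        # the separated fragments; UFF typing is local and stays consistent
        if self.covalent_pair is not None or len({k for _, k in ffs}) > 1:
            ffs = [(AllChem.UFFGetMoleculeForceField(
                s, vdwThresh=100.0, ignoreInterfragInteractions=False),
                "uff") for s in systems]
        e_complex, e_lig, e_pocket = (float(ff.CalcEnergy()) for ff, _ in ffs)
        return delta_g(e_complex, e_lig + e_pocket)

    def pocket_final(self) -> Optional[ProteinModel]:
        """The protein cutout with its minimised coordinates."""
        if self.protein is None or not self.protein.atoms:
            return None
        conf = self.mol.GetConformer()
        out = ProteinModel(name=self.protein.name)
        for i, atom in enumerate(self.protein.atoms):
            moved = ProteinAtom(atom.name, atom.element, atom.resname,
                                atom.chain, atom.resseq,
                                np.array(list(conf.GetAtomPosition(
                                    self.n_ligand + i))), atom.occupancy)
            out.atoms.append(moved)
        return out

    def covalent_bond_length(self) -> Optional[float]:
        if self.covalent_pair is None:
            return None
        conf = self.mol.GetConformer()
        a = np.array(list(conf.GetAtomPosition(self.covalent_pair[0])))
        b = np.array(list(conf.GetAtomPosition(self.covalent_pair[1])))
        return float(np.linalg.norm(a - b))


def delta_g(bound_energy: float, unbound_energy: float) -> float:
    """Predicted binding energy: bound minus unbound, same engine."""
    return float(bound_energy) - float(unbound_energy)


# --------------------------------------------------------------------------
# stage one: frozen-neighbourhood pre-minimisation
# --------------------------------------------------------------------------

def _write_back(ligand: PositionedMol, coords: np.ndarray) -> PositionedMol:
    out, _ = ligand.copy()
    for atom, xyz in zip(out.atoms, coords):
        atom.xyz = np.asarray(xyz, dtype=float)
    return out


def _cutout(protein: Optional[ProteinModel], ligand: PositionedMol,
            cfg: Config) -> Optional[ProteinModel]:
    if protein is None or not protein.atoms:
        return None
    radius = ligand_length(ligand) + cfg.neighbourhood_padding
    rids = protein.residues_near(ligand.centroid(), radius)
    sub = protein.subset(rids)
    return sub if sub.atoms else None


def premin_frozen_neighbourhood(stitched, restraints: RestraintSet,
                                protein: Optional[ProteinModel] = None,
                                cfg: Optional[Config] = None,
                                scale: float = 1.0,
                                covalent_bond: Optional[tuple[int, str]] = None
                                ) -> PositionedMol:
    """Minimise the ligand under restraints with the protein cutout rigid."""
    cfg = cfg or Config()
    ligand = stitched.mol
    cutout = _cutout(protein, ligand, cfg)
    engine = RdkitEngine(ligand, cutout,
                         covalent_bond=covalent_bond if cutout else None)
    frozen = range(engine.n_ligand, engine.mol.GetNumAtoms())
    engine.minimize(restraints, scale=scale, frozen=frozen)
    return _write_back(ligand, engine.ligand_coords())


# --------------------------------------------------------------------------
# stage two: in-pocket cycles with halving restraint weights
# --------------------------------------------------------------------------

def pocket_min_cycles(stitched, restraints: RestraintSet,
                      protein: Optional[ProteinModel] = None,
                      cfg: Optional[Config] = None,
                      covalent_bond: Optional[tuple[int, str]] = None,
                      start: Optional[PositionedMol] = None,
                      ) -> MinimizedPlacement:
    """Iterate minimise / score / halve-restraints until dG_bind < 0.

    Residues whose representative atom lies within (ligand length + padding)
    of the ligand centroid are mobile; the rest of the cutout is rigid.  The
    per-cycle restraint scales are recorded in the result.
    """
    cfg = cfg or Config()
    ligand = start if start is not None else stitched.mol
    cutout = _cutout(protein, ligand, cfg)
    mobile_rids: set[str] = set()
    if cutout is not None:
        radius = ligand_length(ligand) + cfg.neighbourhood_padding
        mobile_rids = set(cutout.residues_near(ligand.centroid(), radius))
    engine = RdkitEngine(ligand, cutout, covalent_bond=covalent_bond)

    frozen = []
    if cutout is not None:
        for i, atom in enumerate(cutout.atoms):
            if atom.residue_id not in mobile_rids:
                frozen.append(engine.n_ligand + i)

    scale = 1.0
    schedule: list[float] = []
    dg_history: list[float] = []
    dg = 0.0
    cycles = 0
    for cycle in range(cfg.max_min_cycles):
        schedule.append(scale)
        engine.minimize(restraints, scale=scale, frozen=frozen)
        dg = engine.binding_delta_g()
        dg_history.append(dg)
        cycles = cycle + 1
        if dg < 0:
            break
        scale /= 2.0

    final = _write_back(ligand, engine.ligand_coords())
    start_coords = (start or stitched.mol).coords()
    result = MinimizedPlacement(
        mol=final,
        dG_bind=dg,
        rmsd_vs_start=rmsd(final.coords(), start_coords),
        cycles=cycles,
        engine=engine.name,
        scale_schedule=schedule,
        dg_history=dg_history,
        protein_final=engine.pocket_final(),
        n_novel=sum(1 for a in final.atoms
                    if a.tags.get("origin") in ("novel", "linker")),
    )
    if covalent_bond is not None:
        result.covalent_residue = covalent_bond[1]
    result.mol.name = stitched.mol.name
    result.covalent_bond_length = engine.covalent_bond_length()
    return result
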