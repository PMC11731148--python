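"""Worked retrospective case on deposited crystal structures.

Requires four PDB entries placed as plain-text files under a data directory
(they are not shipped with the package and need a one-off download):

    5qh1.pdb   parent hit NU181        (ligand component H5G, covalent)
    5qh9.pdb   parent hit PCM-0102716  (ligand component GZY)
    5qhh.pdb   crystal merger NU443    (ligand component H5D, S enantiomer)
    5qhg.pdb   crystal merger NU442    (ligand component H17, R enantiomer)

e.g. ``curl -O https://files.rcsb.org/download/5QH1.pdb`` (and so on), all
deposited in one crystal frame per entry.  The entries belong to different
crystals, so each structure is first superposed onto the 5qh1 protein frame
via common C-alpha atoms.  All computed quantities:

    t1  heavy-atom symmetry-aware RMSD, placed NU443 vs crystal NU443
    t2  aggregated mapped-atom RMSD, placed NU443 vs the two parent hits
    t3  aggregated mapped-atom RMSD, crystal NU443 vs the two parent hits
    t4  S-gamma displacement of the attached cysteine after placing NU442
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDetermineBonds, rdMolAlign

from .errors import ParseError
from .geometry import kabsch, apply_rigid
from .io import ProteinModel, read_template
from .mapping import mcs_cascade_map
from .model import Config, FragmentHit, PositionedMol
from .place import place, rmsd_vs_hits

CASE_FILES = {
    "5qh1": "H5G",   # NU181
    "5qh9": "GZY",   # PCM-0102716
    "5qhh": "H5D",   # NU443
    "5qhg": "H17",   # NU442
}
ATTACHED_CYS_RESSEQ = 73


def data_available(data_dir) -> bool:
    data_dir = Path(data_dir)
    return all((data_dir / f"{code}.pdb").exists() for code in CASE_FILES)


def _hetatm_mol(pdb_path: Path, resname: str) -> Chem.Mol:
    """Extract one HETATM component and perceive its bonds from geometry."""
    lines = [l for l in pdb_path.read_text().splitlines()
             if l.startswith("HETATM") and l[17:20].strip() == resname]
    if not lines:
        raise ParseError(f"no {resname} HETATM records in {pdb_path}")
    block = "\n".join(lines) + "\nEND\n"
    mol = Chem.MolFromPDBBlock(block, sanitize=False, removeHs=True,
                               proximityBonding=False)
    if mol is None:
        raise ParseError(f"could not parse {resname} from {pdb_path}")
    rdDetermineBonds.DetermineBonds(mol, charge=0)
    return mol


def _superpose_onto_reference(model: ProteinModel, reference: ProteinModel):
    """Rigid transform mapping ``model``'s frame onto the reference via
    shared C-alpha atoms."""
    ref_ca = {(a.chain, a.resseq): a.xyz for a in reference.atoms
              if a.name == "CA"}
    mob, ref = [], []
    for atom in model.atoms:
        if atom.name == "CA" and (atom.chain, atom.resseq) in ref_ca:
            mob.append(atom.xyz)
            ref.append(ref_ca[(atom.chain, atom.resseq)])
    if len(mob) < 3:
        raise ParseError("too few shared C-alpha atoms for superposition")
    return kabsch(np.array(mob), np.array(ref))


def _load_entry(data_dir: Path, code: str, reference: Optional[ProteinModel]):
    protein = read_template(data_dir / f"{code}.pdb")
    ligand = _hetatm_mol(data_dir / f"{code}.pdb", CASE_FILES[code])
    if reference is not None:
        rot, trans = _superpose_onto_reference(protein, reference)
        for atom in protein.atoms:
            atom.xyz = rot @ atom.xyz + trans
        conf = ligand.GetConformer()
        for i in range(ligand.GetNumAtoms()):
            pos = np.array(list(conf.GetAtomPosition(i)))
            conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(
                *(rot @ pos + trans)))
    return protein, ligand


def _covalent_smiles(ligand: Chem.Mol, protein: ProteinModel) -> str:
    """SMILES of the ligand with a dummy atom replacing the Cys-S bond."""
    sg = next((a for a in protein.atoms
               if a.resname == "CYS" and a.resseq == ATTACHED_CYS_RESSEQ
               and a.name == "SG"), None)
    rw = Chem.RWMol(ligand)
    if sg is not None:
        conf = rw.GetConformer()
        dists = [np.linalg.norm(np.array(list(conf.GetAtomPosition(i)))
                                - sg.xyz) for i in range(rw.GetNumAtoms())]
        anchor = int(np.argmin(dists))
        if dists[anchor] < 2.2:
            dummy = rw.AddAtom(Chem.Atom(0))
            rw.AddBond(anchor, dummy, Chem.BondType.SINGLE)
            conf2 = rw.GetConformer()
            conf2.SetAtomPosition(dummy, Chem.rdGeometry.Point3D(*sg.xyz))
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _as_hit(ligand: Chem.Mol, hit_id: str,
            protein: ProteinModel) -> FragmentHit:
    pmol = PositionedMol.from_rdkit(ligand, name=hit_id)
    sg = next((a for a in protein.atoms
               if a.resname == "CYS" and a.resseq == ATTACHED_CYS_RESSEQ
               and a.name == "SG"), None)
    if sg is not None:
        dists = [np.linalg.norm(a.xyz - sg.xyz) for a in pmol.atoms]
        if min(dists) < 2.2:
            from .model import Atom, DUMMY
            anchor = pmol.atoms[int(np.argmin(dists))]
            dummy = Atom(DUMMY, sg.xyz.copy())
            pmol.add_atom(dummy)
            pmol.add_bond(anchor, dummy, 1.0)
    return FragmentHit(pmol, hit_id)


def run_case(data_dir, seed: int = 1) -> dict:
    """Compute t1-t4 from the four deposited entries; all values in A."""
    data_dir = Path(data_dir)
    if not data_available(data_dir):
        raise FileNotFoundError(
            f"case data missing under {data_dir}; download "
            "5QH1/5QH9/5QHH/5QHG from the PDB as plain .pdb files")
    cfg = Config(seed=seed)

    template, hit1_mol = _load_entry(data_dir, "5qh1", None)
    _, hit2_mol = _load_entry(data_dir, "5qh9", template)
    crystal_prot, crystal_mol = _load_entry(data_dir, "5qhh", template)
    _, r_enantiomer_mol = _load_entry(data_dir, "5qhg", template)

    hits = [_as_hit(hit1_mol, "NU181", template),
            _as_hit(hit2_mol, "PCM-0102716", template)]

    smiles_s = _covalent_smiles(crystal_mol, crystal_prot)
    placed = place(smiles_s, hits, template, cfg, name="NU443")

    placed_rd = placed.mol.to_rdkit(sanitize=False)
    t1 = float(rdMolAlign.CalcRMS(placed_rd, crystal_mol))

    t2 = placed.rmsd_vs_hits

    crystal_pmol = PositionedMol.from_rdkit(crystal_mol, name="NU443_xtal")
    crystal_maps = mcs_cascade_map(crystal_mol, hits, cfg)
    t3 = rmsd_vs_hits(crystal_pmol, crystal_maps, hits)

    smiles_r = _covalent_smiles(r_enantiomer_mol, crystal_prot)
    placed_r = place(smiles_r, hits, template, cfg, name="NU442")
    sg_parent = next(a for a in template.atoms
                     if a.resname == "CYS" and a.resseq == ATTACHED_CYS_RESSEQ
                     and a.name == "SG")
    sg_after = next((a for a in placed_r.protein_final.atoms
                     if a.resname == "CYS"
                     and a.resseq == ATTACHED_CYS_RESSEQ
                     and a.name == "SG"), None)
    t4 = (float(np.linalg.norm(sg_after.xyz - sg_parent.xyz))
          if sg_after is not None else float("nan"))

    return {"t1": t1, "t2": t2, "t3": t3, "t4": t4}
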