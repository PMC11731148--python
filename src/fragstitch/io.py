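"""Readers and writers for the structure formats the pipeline touches.

SDF (V2000) for hits and outputs, PDB for the protein template, and a JSON
sidecar for scores and diagnostics.  Hit order always equals file order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom
from rdkit import Chem

from .errors import ParseError
from .model import DUMMY, FragmentHit, PositionedMol


# --------------------------------------------------------------------------
# protein template
# --------------------------------------------------------------------------

@dataclass
class ProteinAtom:
    name: str
    element: str
    resname: str
    chain: str
    resseq: int
    xyz: np.ndarray
    occupancy: float = 1.0

    @property
    def residue_id(self) -> str:
        return f"{self.chain}:{self.resname}:{self.resseq}"


@dataclass
class ProteinModel:
    """A flat list of protein heavy atoms with residue identity."""

    atoms: list[ProteinAtom] = field(default_factory=list)
    name: str = ""

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def residues(self) -> dict[str, list[ProteinAtom]]:
        out: dict[str, list[ProteinAtom]] = {}
        for atom in self.atoms:
            out.setdefault(atom.residue_id, []).append(atom)
        return out

    def residues_near(self, point: np.ndarray, radius: float) -> list[str]:
        """Residues whose representative (CA, else first) atom is within radius."""
        hits = []
        for rid, atoms in self.residues().items():
            rep = next((a for a in atoms if a.name == "CA"), atoms[0])
            if np.linalg.norm(rep.xyz - point) <= radius:
                hits.append(rid)
        return hits

    def subset(self, residue_ids: list[str]) -> "ProteinModel":
        keep = set(residue_ids)
        return ProteinModel([a for a in self.atoms if a.residue_id in keep],
                            self.name)

    def to_pdb_block(self) -> str:
        lines = []
        for i, atom in enumerate(self.atoms, start=1):
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {i:5d} {name:<4s}{atom.resname:>4s} {atom.chain:1s}"
                f"{atom.resseq:4d}    {atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}"
                f"{atom.xyz[2]:8.3f}{atom.occupancy:6.2f}  0.00"
                f"          {atom.element:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def read_template(path, strip_waters: bool = True) -> ProteinModel:
    """Parse a PDB file into a :class:`ProteinModel`.

    Altloc conflicts keep the highest-occupancy conformer (with a warning);
    hydrogens are dropped; waters are stripped unless requested otherwise.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ParseError(f"empty or missing PDB file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = ProteinModel(name=path.stem)
    try:
        first_model = next(structure.get_models())
    except StopIteration:
        raise ParseError(f"no ATOM/HETATM records in {path}") from None
    for chain in first_model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if strip_waters and resname in ("HOH", "WAT"):
                continue
            for atom in residue:
                if isinstance(atom, DisorderedAtom):
                    children = sorted(atom.disordered_get_list(),
                                      key=lambda a: -(a.get_occupancy() or 0.0))
                    warnings.warn(
                        f"altloc conflict on {resname}{residue.id[1]} atom "
                        f"{atom.get_id()}: keeping highest occupancy")
                    atom = children[0]
                element = (atom.element or "").strip() or atom.get_id()[0]
                if element == "H":
                    continue
                model.atoms.append(ProteinAtom(
                    name=atom.get_id(),
                    element=element,
                    resname=resname,
                    chain=chain.id if chain.id.strip() else "A",
                    resseq=residue.id[1],
                    xyz=np.asarray(atom.get_coord(), dtype=float),
                    occupancy=atom.get_occupancy() or 1.0,
                ))
    if not model.atoms:
        raise ParseError(f"no ATOM/HETATM records in {path}")
    return model


# --------------------------------------------------------------------------
# fragment hits
# --------------------------------------------------------------------------

def read_hits(path) -> list[FragmentHit]:
    """Read positioned fragment hits from an SDF file, in file order.

    Dummy atoms (``*`` in SMILES, ``R`` in SDF) are recorded as the covalent
    attachment point.  2D-only records are rejected.
    """
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    hits: list[FragmentHit] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"unparsable SDF record {i + 1} in {path}")
        if mol.GetNumConformers() == 0 or not mol.GetConformer().Is3D():
            raise ParseError(
                f"record {i + 1} in {path} has no 3D coordinates")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        pmol = PositionedMol.from_rdkit(mol, name=name or f"hit_{i + 1}")
        hits.append(FragmentHit(mol=pmol, hit_id=pmol.name))
    return hits


def write_hits(hits: list[FragmentHit], path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for hit in hits:
            try:
                writer.write(hit.mol.to_rdkit(sanitize=True))
            except Exception:
                writer.write(hit.mol.to_rdkit(sanitize=False))
    finally:
        writer.close()


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

def write_result(placement, out_prefix) -> tuple[Path, Path]:
    """Write a minimised placement as ``<prefix>.sdf`` + ``<prefix>.json``.

    The JSON sidecar schema is documented in the README; it round-trips the
    quantities needed to re-rank without re-running the pipeline.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sdf_path = out_prefix.with_suffix(".sdf")
    json_path = out_prefix.with_suffix(".json")

    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(False)
    try:
        try:
            writer.write(placement.mol.to_rdkit(sanitize=True))
        except Exception:
            writer.write(placement.mol.to_rdkit(sanitize=False))
    finally:
        writer.close()

    n_novel = sum(1 for a in placement.mol.atoms
                  if a.tags.get("origin") in ("linker", "novel"))
    payload = {
        "name": placement.mol.name,
        "dG_bind": placement.dG_bind,
        "rmsd_vs_hits": placement.rmsd_vs_hits,
        "rmsd_vs_start": placement.rmsd_vs_start,
        "n_novel_atoms": n_novel,
        "n_atoms": len(placement.mol.atoms),
        "cycles": placement.cycles,
        "engine": placement.engine,
        "acceptable": placement.acceptable,
        "reason": placement.reason,
        "scale_schedule": placement.scale_schedule,
    }
    if getattr(placement, "covalent_residue", None) is not None:
        payload["covalent"] = {"residue": placement.covalent_residue}
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return sdf_path, json_path
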