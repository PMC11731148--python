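# fragstitch

Fragment-hit merging/linking ("combination") and constrained candidate
placement by coordinate stitching.  Given crystallographic fragment hits
positioned in a protein frame, fragstitch builds a conformer directly from
the hits' atomic coordinates, repairs its chemistry, minimises it in place
under hit-derived restraints, and scores the result by fidelity and
protein–ligand interactions.

## How it works

**Combination** (merge/link): rings are collapsed to centroid placeholder
pseudo-atoms, hits are folded together pairwise in input order via an
optimal positional one-to-one atom map (default threshold 2 Å; hits more
than 5 Å away are deferred once, then rejected), placeholders are expanded
back (overlapping ring atoms unified), disconnected parts are bridged with
a short alkyl chain whose first atom is a heteroatom (N by default,
`round(d/1.22) − 1` chain atoms), and the molecule is *rectified* —
geminal-substituted arenes dearomatised, overfull atoms charge-adjusted or
relieved of a substituent, pentavalent carbons stripped of their longest
bond — until it passes RDKit sanitisation.

**Placement**: a candidate SMILES is mapped onto the hits by a multistep
MCS cascade (strict → bond-order-relaxed → element-within-group-relaxed →
ring-relaxed, with up to 3 "red herring" atoms droppable per pass and
user-supplied map overrides honoured verbatim); mapped atoms inherit hit
coordinates, novel patches borrow coordinates from a seeded generated
conformer superposed on the three nearest mapped atoms.

**Minimisation**: a frozen-neighbourhood pre-minimisation under tiered
flat-bottom restraints (heavy for exocyclic mapped atoms, moderate for ring
atoms, none for amide/urea/ester and novel atoms, plus a trans restraint on
secondary amides), then in-pocket cycles in which nearby residues are
mobile and the restraint scale is halved each cycle until the predicted
binding energy — a single-snapshot bound-minus-unbound difference, always
rescored restraint-free — goes negative.  The default engine is RDKit MMFF
with a UFF fallback; the engine contract is pluggable.

Covalent ligands mark their protein attachment with a dummy atom (`*` in
SMILES, `R` in SDF); the warhead is protected during merging and the bond
to the nearest cysteine Sγ becomes part of the engine topology.

## CLI

```sh
# merge/link hits (exit codes: 3 distance, 4 rectification, 5 minimisation, 6 mapping)
fragstitch combine --hits hits.sdf --template prot.pdb --out out/ [--pairwise] [--cutoff 5.0] [--no-minimise]

# place candidates
fragstitch place --smiles cands.smi --hits hits.sdf --template prot.pdb --out out/ \
    [--user-map map.json] [--max-excluded 3] [--threshold 2.0]

# synthetic fixtures (deterministic at fixed seed)
fragstitch fixtures --kind ring_pair_sweep --sep 0,2,4,6,8 --seed 42 --out fixtures/
```

Every run writes `run_log.json` (config echo, per-candidate outcomes,
failure taxonomy).  The user map JSON format is
`{"hit_id": [[candidate_idx, hit_idx], ...]}` with 0-based indices.

### Result sidecar schema

`write_result` emits `<prefix>.sdf` (the pose) and `<prefix>.json` with:
`dG_bind` (kcal/mol), `rmsd_vs_hits`, `rmsd_vs_start` (Å), `n_novel_atoms`,
`cycles`, `scale_schedule` (per-cycle restraint scales), `engine`,
`acceptable`, `reason`, and for covalent placements
`covalent.residue` (`chain:RES:seq`).

A placement is *acceptable* when every hit contributed ≥ 1 mapped atom,
combined RMSD vs hits < 1 Å, predicted binding energy < 0 kcal/mol, and the
molecule is strictly larger than the largest hit.

## Layout

| module | contents |
| --- | --- |
| `model` / `io` | `PositionedMol`, `FragmentHit`, `Config`; SDF/PDB/JSON readers and writers |
| `mapping` | positional optimal-assignment maps, MCS cascade |
| `combine` | ring collapse/expand, pairwise merge, linker insertion, rectifier |
| `place` | candidate stitching and the full placement pipeline |
| `minimize` | restraint construction, two-stage minimisation, ΔG |
| `interactions` | geometric interaction profiler, ranking score, acceptability filter, efficiency metrics |
| `covalent` | dummy-atom warhead mechanics |
| `cli` / `fixtures` | command-line front end, synthetic fixture generators |
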