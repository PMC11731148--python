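import numpy as np
import pytest

from fragstitch import (Config, FragmentHit, PositionedMol, build_restraints,
                        delta_g, mcs_cascade_map, pocket_min_cycles,
                        premin_frozen_neighbourhood, stitch_candidate)
from fragstitch import fixtures as fx
from fragstitch.geometry import rmsd
from fragstitch.combine import StitchedConformer
from fragstitch.model import mol_from_smiles

from conftest import hit_of, mol_from_smiles_3d


def self_stitched(smiles, seed=0, name="hit"):
    hit = hit_of(mol_from_smiles_3d(smiles, seed=seed, name=name))
    cand = mol_from_smiles(smiles)
    cfg = Config(seed=seed)
    maps = mcs_cascade_map(cand, [hit], cfg)
    return stitch_candidate(cand, maps, [hit], cfg), hit, cfg


class TestBuildRestraints:
    def test_all_novel_molecule_gets_zero_weights(self):
        mol = mol_from_smiles_3d("CCO", seed=1)
        for atom in mol.atoms:
            atom.tags["origin"] = "novel"
        restraints = build_restraints(StitchedConformer(mol))
        assert all(r.weight == 0 for r in restraints.positional)

    def test_n_methylbenzamide_classification(self):
        # oracle: classify atoms by substructure by hand — ring carbons are
        # 'moderate', amide N/C/O unrestrained, exocyclic methyl 'heavy'
        st, _, _ = self_stitched("CNC(=O)c1ccccc1", seed=2)
        restraints = build_restraints(st)
        mol = st.mol
        tiers = {i: r.tier for i, r in enumerate(restraints.positional)}
        ring = [i for i, a in enumerate(mol.atoms) if a.aromatic]
        assert all(tiers[i] == "moderate" for i in ring)
        carbonyl_o = next(i for i, a in enumerate(mol.atoms)
                          if a.element == "O")
        amide_n = next(i for i, a in enumerate(mol.atoms)
                       if a.element == "N")
        assert tiers[carbonyl_o] == "none"
        assert tiers[amide_n] == "none"
        methyl = 0        # SMILES atom order: methyl carbon first
        assert tiers[methyl] == "heavy"

    def test_secondary_amide_gets_torsion_restraint(self):
        st, _, _ = self_stitched("CNC(=O)c1ccccc1", seed=3)
        restraints = build_restraints(st)
        assert len(restraints.torsional) == 1

    def test_weights_non_negative_and_targets_are_stitched_coords(self):
        st, _, _ = self_stitched("Cc1ccccc1", seed=4)
        restraints = build_restraints(st)
        for r in restraints.positional:
            assert r.weight >= 0
            np.testing.assert_array_equal(r.target,
                                          st.mol.atoms[r.atom_index].xyz)


class TestPremin:
    def test_minimal_ethane_barely_moves(self):
        st, _, cfg = self_stitched("CC", seed=5)
        # relax the stitched conformer itself first so it is near-minimal
        restraints = build_restraints(st)
        relaxed = premin_frozen_neighbourhood(st, restraints, None, cfg)
        st2 = StitchedConformer(relaxed)
        out = premin_frozen_neighbourhood(st2, build_restraints(st2), None, cfg)
        assert rmsd(out.coords(), relaxed.coords()) < 0.05

    def test_displaced_benzene_returns_planar(self):
        st, _, cfg = self_stitched("c1ccccc1", seed=6)
        st.mol.atoms[0].xyz = st.mol.atoms[0].xyz + np.array([0.0, 0.0, 0.4])
        for atom in st.mol.atoms:
            atom.tags["origin"] = "novel"   # unrestrained: pure relaxation
        restraints = build_restraints(st)
        out = premin_frozen_neighbourhood(st, restraints, None, cfg)
        coords = out.coords()
        centred = coords - coords.mean(axis=0)
        _, sv, _ = np.linalg.svd(centred)
        assert sv[2] < 0.1          # flat to within 0.1 A

    def test_graph_invariant(self, toy_pocket):
        st, _, cfg = self_stitched("Cc1ccccc1", seed=7)
        n_atoms, n_bonds = len(st.mol.atoms), len(st.mol.bonds)
        out = premin_frozen_neighbourhood(st, build_restraints(st),
                                          toy_pocket, cfg)
        assert (len(out.atoms), len(out.bonds)) == (n_atoms, n_bonds)

    @pytest.mark.parametrize("seed", range(10))
    def test_heavy_restrained_atoms_drift_below_half_angstrom(self, seed):
        smiles = ["Cc1ccccc1", "CCc1ccccc1", "Cc1ccc(O)cc1", "CC(C)c1ccccc1",
                  "CCOc1ccccc1"][seed % 5]
        st, _, cfg = self_stitched(smiles, seed=seed)
        restraints = build_restraints(st)
        out = premin_frozen_neighbourhood(st, restraints, None, cfg)
        for r in restraints.positional:
            if r.tier == "heavy":
                drift = np.linalg.norm(out.atoms[r.atom_index].xyz - r.target)
                assert drift < 0.5, (smiles, r.atom_index, drift)

    def test_cis_secondary_amide_driven_to_trans(self):
        from rdkit import Chem
        from rdkit.Chem import AllChem
        from rdkit.Chem import rdMolTransforms
        mol = Chem.AddHs(Chem.MolFromSmiles("CNC(=O)C"))
        params = AllChem.ETKDGv3()
        params.randomSeed = 8
        AllChem.EmbedMolecule(mol, params)
        heavy = Chem.RemoveHs(mol)
        # force the cis (E) form: O=C-N-C torsion 0 degrees
        conf = heavy.GetConformer()
        rdMolTransforms.SetDihedralDeg(conf, 4, 2, 1, 0, 0.0)
        pmol = PositionedMol.from_rdkit(heavy, name="cis_amide")
        st = StitchedConformer(pmol)
        for atom in st.mol.atoms:
            atom.tags["origin"] = ("h", 0)   # mapped: torsion applies
        cfg = Config(seed=8)
        out = premin_frozen_neighbourhood(st, build_restraints(st, cfg),
                                          None, cfg)
        rd = out.to_rdkit(sanitize=True)
        tors = abs(rdMolTransforms.GetDihedralDeg(rd.GetConformer(),
                                                  4, 2, 1, 0))
        assert tors > 150.0   # within 30 degrees of trans


class TestPocketCycles:
    def test_stops_at_first_negative_dg(self, overlap_pair, toy_pocket):
        tol, phe = overlap_pair
        cand = mol_from_smiles("Cc1ccc(O)cc1")
        cfg = Config(seed=1)
        maps = mcs_cascade_map(cand, [tol, phe], cfg)
        st = stitch_candidate(cand, maps, [tol, phe], cfg)
        res = pocket_min_cycles(st, build_restraints(st, cfg), toy_pocket, cfg)
        assert res.dG_bind < 0
        assert res.cycles == len(res.scale_schedule)
        assert all(dg >= 0 for dg in res.dg_history[:-1])

    def test_halving_schedule_is_exactly_geometric(self, overlap_pair,
                                                   toy_pocket):
        tol, phe = overlap_pair
        st, _, cfg = self_stitched("Cc1ccccc1", seed=2)
        # clash the restraint targets into a wall so several cycles run
        shift = np.array([3.5, 0.0, 0.0])
        for atom in st.mol.atoms:
            atom.xyz = atom.xyz + shift
        restraints = build_restraints(st, cfg)
        res = pocket_min_cycles(st, restraints, toy_pocket, cfg)
        for k, scale in enumerate(res.scale_schedule):
            assert scale == pytest.approx(2.0 ** (-k), rel=0, abs=0)

    def test_clash_resolved_and_dg_drops(self, toy_pocket):
        st, _, cfg = self_stitched("Cc1ccccc1", seed=3)
        shift = np.array([3.5, 0.0, 0.0])     # ~1.5 A from the nearest wall
        for atom in st.mol.atoms:
            atom.xyz = atom.xyz + shift
        restraints = build_restraints(st, cfg)
        res = pocket_min_cycles(st, restraints, toy_pocket, cfg)
        assert res.dg_history[-1] <= res.dg_history[0]
        assert res.dG_bind < 0
        # the clash resolves against the *minimised* pocket (the offending
        # residue is mobile and yields alongside the ligand)
        pocket_coords = res.protein_final.coords()
        lig_coords = res.mol.coords()
        dmin = np.linalg.norm(lig_coords[:, None, :]
                              - pocket_coords[None, :, :], axis=-1).min()
        assert dmin > 2.0

    def test_restraint_limit_reproduces_stitched_pose(self, overlap_pair,
                                                      toy_pocket):
        tol, _ = overlap_pair
        cand = mol_from_smiles("Cc1ccccc1")
        cfg = Config(seed=4)
        maps = mcs_cascade_map(cand, [tol], cfg)
        st = stitch_candidate(cand, maps, [tol], cfg)
        restraints = build_restraints(st, cfg)
        out = premin_frozen_neighbourhood(st, restraints, toy_pocket, cfg,
                                          scale=1.0e6)
        assert rmsd(out.coords(), st.mol.coords()) < 0.05

    def test_chemistry_conserved_through_minimisation(self, overlap_pair,
                                                      toy_pocket):
        import networkx as nx
        tol, phe = overlap_pair
        cand = mol_from_smiles("Cc1ccc(O)cc1")
        cfg = Config(seed=5)
        maps = mcs_cascade_map(cand, [tol, phe], cfg)
        st = stitch_candidate(cand, maps, [tol, phe], cfg)
        res = pocket_min_cycles(st, build_restraints(st, cfg), toy_pocket, cfg)
        g1, g2 = st.mol.to_graph(), res.mol.to_graph()
        nm = lambda a, b: a["element"] == b["element"]
        em = lambda a, b: a["order"] == b["order"]
        assert nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)

    def test_dg_excludes_restraint_energy(self, overlap_pair, toy_pocket):
        # with and without restraints applied during minimisation, the
        # reported dG is always a restraint-free rescoring: rescoring the
        # same pose twice gives the same number
        from fragstitch.minimize import RdkitEngine, _cutout
        tol, _ = overlap_pair
        st, _, cfg = self_stitched("Cc1ccccc1", seed=6)
        cut = _cutout(toy_pocket, st.mol, cfg)
        engine = RdkitEngine(st.mol, cut)
        dg1 = engine.binding_delta_g()
        dg2 = engine.binding_delta_g()
        assert dg1 == dg2
        assert np.isfinite(dg1)


class TestDeltaG:
    def test_equal_energies_give_zero(self):
        assert delta_g(-10.0, -10.0) == 0.0

    def test_arithmetic(self):
        assert delta_g(-10.0, -4.0) == -6.0

    def test_far_ligand_has_negligible_dg(self, toy_pocket):
        from fragstitch.minimize import RdkitEngine
        mol = mol_from_smiles_3d("Cc1ccccc1", seed=7)
        for atom in mol.atoms:
            atom.xyz = atom.xyz + np.array([150.0, 0.0, 0.0])
        engine = RdkitEngine(mol, toy_pocket)
        assert abs(engine.binding_delta_g()) < 1e-3
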