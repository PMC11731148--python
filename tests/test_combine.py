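import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from fragstitch import (Atom, Bond, Config, DistanceFailure, FragmentHit,
                        LinkFailure, PositionedMol, RectificationFailure,
                        collapse_rings, combine, expand_rings,
                        link_if_disconnected, merge_pair, rectify)
from fragstitch import fixtures as fx
from fragstitch.combine import StitchedConformer, linker_atom_count
from fragstitch.mapping import positional_atom_map
from fragstitch.combine import placeholder_pair_ok

from conftest import hit_of, mol_from_smiles_3d


def graphs_equal(a: PositionedMol, b: PositionedMol) -> bool:
    def nm(x, y):
        return (x["element"] == y["element"] and x["charge"] == y["charge"]
                and x["xyz"] == y["xyz"])

    def em(x, y):
        return x["order"] == y["order"]

    return nx.is_isomorphic(a.to_graph(), b.to_graph(),
                            node_match=nm, edge_match=em)


class TestCollapse:
    def test_acyclic_unchanged(self):
        propane = mol_from_smiles_3d("CCC", seed=1, name="propane")
        col = collapse_rings(propane)
        assert len(col.placeholders()) == 0
        assert graphs_equal(col.mol, propane)

    def test_benzene_placeholder_at_centroid(self, benzene_3d):
        col = collapse_rings(benzene_3d)
        assert len(col.placeholders()) == 1
        # oracle: centroid is the arithmetic mean of the six carbons
        expected = np.mean([a.xyz for a in benzene_3d.atoms], axis=0)
        np.testing.assert_allclose(col.placeholders()[0].xyz, expected,
                                   atol=1e-12)

    def test_naphthalene_two_placeholders_share_two_atoms(self):
        naph = mol_from_smiles_3d("c1ccc2ccccc2c1", seed=2, name="naphthalene")
        # oracle: RDKit SSSR sees two six-rings sharing an edge
        rd = naph.to_rdkit(sanitize=True)
        sssr = Chem.GetSymmSSSR(rd)
        assert len(sssr) == 2
        shared = set(sssr[0]) & set(sssr[1])
        assert len(shared) == 2
        col = collapse_rings(naph)
        assert len(col.placeholders()) == 2
        stash_sizes = [len(ph.tags["ring_stashes"][0].members)
                       for ph in col.placeholders()]
        assert sorted(stash_sizes) == [6, 6]

    def test_exocyclic_bond_reattached_to_placeholder(self):
        tol = mol_from_smiles_3d("Cc1ccccc1", seed=3, name="toluene")
        col = collapse_rings(tol)
        ph = col.placeholders()[0]
        methyl = next(a for a in col.mol.atoms if a.element == "C"
                      and not a.aromatic)
        assert col.mol.get_bond(ph, methyl) is not None


class TestExpandRoundTrip:
    @pytest.mark.parametrize("smiles", [
        "CCC", "c1ccccc1", "Cc1ccccc1", "c1ccc2ccccc2c1",
        "Cn1cnc2c1c(=O)n(C)c(=O)n2C",          # caffeine
        "CC(=O)Oc1ccccc1C(=O)O",               # aspirin
        "c1ccc(-c2ccccc2)cc1",                 # biphenyl (ring-ring bond)
        "C1CC2(C1)CCC2",                       # spiro
    ])
    def test_graph_and_coordinates_identical(self, smiles):
        mol = mol_from_smiles_3d(smiles, seed=4)
        back = expand_rings(collapse_rings(mol))
        assert graphs_equal(mol, back)
        # coordinates are bit-equal (same float64 payload), not just close
        orig = sorted(map(tuple, mol.coords().tolist()))
        new = sorted(map(tuple, back.coords().tolist()))
        assert orig == new


class TestMergePair:
    def test_merge_with_exact_copy_is_identity(self, benzene_3d):
        a = collapse_rings(benzene_3d)
        clone, _ = benzene_3d.copy()
        b = collapse_rings(clone)
        amap = positional_atom_map(a.mol, b.mol, 2.0,
                                   pair_ok=placeholder_pair_ok)
        merged = merge_pair(a, b, amap)
        out = expand_rings(merged)
        assert graphs_equal(out, benzene_3d)

    def test_fully_overlapping_benzenes_give_single_placeholder(self, benzene_3d):
        a = collapse_rings(benzene_3d)
        shifted, _ = benzene_3d.copy()
        for atom in shifted.atoms:
            atom.xyz = atom.xyz + np.array([0.1, 0.0, 0.0])
        b = collapse_rings(shifted)
        amap = positional_atom_map(a.mol, b.mol, 2.0,
                                   pair_ok=placeholder_pair_ok)
        merged = merge_pair(a, b, amap)
        assert len(merged.placeholders()) == 1
        out = expand_rings(merged)
        assert len(out.heavy_atoms()) == 6

    def test_cocentred_furan_benzene_single_ring_with_oxygen(self):
        f, b = fx.furan(), fx.benzene()
        ca, cb = collapse_rings(f.copy()[0]), collapse_rings(b.copy()[0])
        amap = positional_atom_map(ca.mol, cb.mol, 2.0,
                                   pair_ok=placeholder_pair_ok)
        out = expand_rings(merge_pair(ca, cb, amap))
        assert out.n_rings() == 1
        elements = sorted(a.element for a in out.atoms)
        assert elements.count("O") == 1
        assert len(out.atoms) == 6


class TestLink:
    def test_connected_conformer_unchanged(self):
        mol = mol_from_smiles_3d("CCO", seed=5)
        before = len(mol.atoms)
        out = link_if_disconnected(StitchedConformer(mol))
        assert len(out.mol.atoms) == before

    def test_linker_count_rule(self):
        # off-by-one chain: round(d / 1.22) - 1 atoms
        assert linker_atom_count(2.44) == 1
        assert linker_atom_count(1.50) == 0
        assert linker_atom_count(1.83) == 0
        assert linker_atom_count(4.88) == 3

    def test_two_carbons_bridged_by_one_nitrogen(self):
        a = Atom("C", (0.0, 0.0, 0.0))
        b = Atom("C", (2.44, 0.0, 0.0))
        mol = PositionedMol([a, b])
        out = link_if_disconnected(StitchedConformer(mol), Config())
        assert len(out.mol.atoms) == 3
        inserted = out.mol.atoms[2]
        assert inserted.element == "N"
        assert inserted.tags["origin"] == "linker"
        np.testing.assert_allclose(inserted.xyz, (1.22, 0.0, 0.0))
        assert len(out.mol.connected_components()) == 1

    def test_first_linker_element_override(self):
        a = Atom("C", (0.0, 0.0, 0.0))
        b = Atom("C", (4.88, 0.0, 0.0))
        mol = PositionedMol([a, b])
        cfg = Config(linker_first_element="O")
        out = link_if_disconnected(StitchedConformer(mol), cfg)
        chain = out.mol.atoms[2:]
        assert [x.element for x in chain] == ["O", "C", "C"]

    def test_no_substitutable_pair_raises(self):
        # two F2 molecules: every atom is at full valence
        mols = []
        atoms = []
        for x0 in (0.0, 6.0):
            f1, f2 = Atom("F", (x0, 0, 0)), Atom("F", (x0 + 1.4, 0, 0))
            atoms += [f1, f2]
        mol = PositionedMol(atoms, [Bond(atoms[0], atoms[1]),
                                    Bond(atoms[2], atoms[3])])
        with pytest.raises(LinkFailure):
            link_if_disconnected(StitchedConformer(mol), Config())


class TestRectify:
    def test_valid_aspirin_unchanged(self):
        aspirin = mol_from_smiles_3d("CC(=O)Oc1ccccc1C(=O)O", seed=6)
        out = rectify(aspirin)
        assert graphs_equal(out, aspirin)

    def test_pentavalent_carbon_loses_longest_bond(self):
        c = Atom("C", (0.0, 0.0, 0.0))
        subs = [Atom("C", xyz) for xyz in
                [(1.5, 0, 0), (-1.5, 0, 0), (0, 1.5, 0), (0, -1.5, 0),
                 (0, 0, 1.9)]]                 # deliberately the longest
        mol = PositionedMol([c] + subs, [Bond(c, s) for s in subs])
        out = rectify(mol)
        centre = out.atoms[0]
        assert out.bond_order_sum(centre) == 4
        # the atom at distance 1.9 lost its bond
        far = next(a for a in out.atoms if a.xyz[2] == 1.9)
        assert out.get_bond(centre, far) is None

    def test_geminal_arene_dearomatised(self, benzene_3d):
        mol, _ = benzene_3d.copy()
        target = mol.atoms[0]
        for offset in ((0.9, 1.2, 0.4), (0.9, 1.2, -0.4)):
            methyl = Atom("C", target.xyz + np.array(offset))
            mol.add_atom(methyl)
            mol.add_bond(target, methyl, 1.0)
        out = rectify(mol)
        assert out.is_sanitizable()
        assert not out.atoms[0].aromatic
        ring_bonds = out.bonds_of(out.atoms[0])
        assert all(b.order == 1.0 for b in ring_bonds)

    def test_unfixable_raises_typed_failure(self):
        # a protected hyper-valent cage nothing may touch
        c = Atom("C", (0, 0, 0), tags={"protected": True})
        subs = [Atom("C", xyz, tags={"protected": True}) for xyz in
                [(1.5, 0, 0), (-1.5, 0, 0), (0, 1.5, 0), (0, -1.5, 0),
                 (0, 0, 1.5)]]
        mol = PositionedMol([c] + subs, [Bond(c, s) for s in subs])
        with pytest.raises(RectificationFailure):
            rectify(mol)


class TestCombine:
    def test_single_hit_round_trips(self):
        mol = mol_from_smiles_3d("Cc1ccc(O)cc1", seed=7, name="h")
        out = combine([hit_of(mol)])
        assert graphs_equal(out.mol, mol)

    def test_distant_hit_deferred_then_merged(self):
        # B is far from A but close to C; processing order becomes A, C, B
        a = mol_from_smiles_3d("CCO", seed=8, name="A")
        b, _ = a.copy(); b.name = "B"
        c, _ = a.copy(); c.name = "C"
        for atom in b.atoms:
            atom.xyz = atom.xyz + np.array([12.0, 0.0, 0.0])
        for atom in c.atoms:
            atom.xyz = atom.xyz + np.array([8.0, 0.0, 0.0])
        cfg = Config(join_cutoff=9.0)
        out = combine([hit_of(a), hit_of(b), hit_of(c)], cfg)
        assert out.processing_order == ["A", "C", "B"]
        assert len(out.mol.connected_components()) == 1

    def test_six_angstrom_gap_is_distance_failure(self):
        a = mol_from_smiles_3d("CCO", seed=9, name="A")
        b, _ = a.copy(); b.name = "B"
        span = max(np.linalg.norm(x.xyz - y.xyz)
                   for x in a.atoms for y in a.atoms)
        for atom in b.atoms:
            atom.xyz = atom.xyz + np.array([span + 6.0, 0.0, 0.0])
        with pytest.raises(DistanceFailure):
            combine([hit_of(a), hit_of(b)], Config())

    def test_atom_conservation_via_provenance(self, overlap_pair):
        tol, phe = overlap_pair
        out = combine([tol, phe], Config())
        for atom in out.mol.atoms:
            origin = atom.tags.get("origin")
            assert origin is not None
            if isinstance(origin, tuple):
                assert origin[0] in ("toluene", "phenol")

    def test_output_is_valence_legal_or_typed_failure(self, overlap_pair):
        tol, phe = overlap_pair
        out = combine([tol, phe], Config())
        assert out.mol.is_sanitizable()


class TestSweepBehaviour:
    def test_angled_ring_overlap_flags_rectification(self):
        # a cyclopentane tilted through a benzene: appended atoms from the
        # merged placeholder are flagged before rectification
        benz = fx.benzene()
        penta = mol_from_smiles_3d("C1CCCC1", seed=10, name="cp")
        centre = penta.coords().mean(axis=0)
        theta = np.radians(90.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        for atom in penta.atoms:
            atom.xyz = rot @ (atom.xyz - centre) + np.array([0.0, 0.0, 1.2])
        ca = collapse_rings(benz.copy()[0])
        cb = collapse_rings(penta)
        amap = positional_atom_map(ca.mol, cb.mol, 2.0,
                                   pair_ok=placeholder_pair_ok)
        assert amap.score == 1   # the two placeholders merge
        out = expand_rings(merge_pair(ca, cb, amap))
        assert any(a.tags.get("needs_rectification") for a in out.atoms)
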