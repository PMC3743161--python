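import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from binqsar import descriptors as D
from binqsar.descriptors import (
    INDICATOR_NAMES,
    VSA_BLOCK_NAMES,
    ScaffoldAmbiguityError,
    approximate_vsa,
    compute_descriptor_matrix,
    count_atoms_bonds,
    descriptor_vector,
    peoe_charges,
    rotatable_bond_counts,
    scaffold_indicators,
    vsa_descriptor_block,
    wiener_polarity,
)

from conftest import mol


class TestCounts:
    @pytest.mark.parametrize(
        "smiles,a,b,bs",
        [
            ("C", 5, 4, 4),        # methane: C + 4 implicit H
            ("CC", 8, 7, 7),       # ethane: 1 C-C + 6 C-H
            ("c1ccccc1", 12, 12, 6),  # benzene: aromatic bonds not single
        ],
    )
    def test_counts_include_implicit_hydrogens(self, smiles, a, b, bs):
        assert count_atoms_bonds(mol(smiles)) == (a, b, bs)

    @pytest.mark.parametrize(
        "smiles,b_rotn,b_1rotn,rigid",
        [
            ("CC", 0, 0, 0),          # terminal bond not rotatable
            ("CCCC", 1, 1, 0),        # n-butane: the central bond
            ("c1ccccc1", 0, 0, 6),    # all ring bonds rigid
            ("CCCCC", 2, 2, 0),
            ("CC(=O)NC", 1, 0, 1),    # amide C-N: rotatable but not 'single-rotatable'
        ],
    )
    def test_rotatable_and_rigid(self, smiles, b_rotn, b_1rotn, rigid):
        rn, _, r1n, _, rigid_got = rotatable_bond_counts(mol(smiles))
        assert (rn, r1n, rigid_got) == (b_rotn, b_1rotn, rigid)

    def test_fractions_divide_by_heavy_bonds(self):
        _, b_rotr, _, b_1rotr, _ = rotatable_bond_counts(mol("CCCC"))
        assert b_rotr == pytest.approx(1 / 3)
        assert b_1rotr == pytest.approx(1 / 3)
        _, b_rotr, _, _, _ = rotatable_bond_counts(mol("C"))
        assert b_rotr == 0.0


class TestWienerPolarity:
    @pytest.mark.parametrize(
        "smiles,expected",
        [("C", 0), ("CCCC", 1), ("C1CCCCC1", 3), ("CC(C)C", 0), ("CCCCC", 2)],
    )
    def test_known_molecules(self, smiles, expected):
        assert wiener_polarity(mol(smiles)) == expected

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        """wienerPol equals an all-pairs shortest-path count on 200 random
        heavy-atom graphs of <= 30 atoms."""
        for _ in range(200):
            n = int(rng.integers(2, 31))
            mw = Chem.RWMol()
            for _ in range(n):
                mw.AddAtom(Chem.Atom(6))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            # random tree + a few chords, max degree 4 (carbon valence)
            for v in range(1, n):
                u = int(rng.integers(0, v))
                if mw.GetAtomWithIdx(u).GetDegree() >= 4:
                    u = min(range(v), key=lambda k: mw.GetAtomWithIdx(k).GetDegree())
                mw.AddBond(u, v, Chem.BondType.SINGLE)
                g.add_edge(u, v)
            for _ in range(int(rng.integers(0, 3))):
                u, v = int(rng.integers(0, n)), int(rng.integers(0, n))
                if (u != v and not g.has_edge(u, v)
                        and mw.GetAtomWithIdx(u).GetDegree() < 4
                        and mw.GetAtomWithIdx(v).GetDegree() < 4):
                    mw.AddBond(u, v, Chem.BondType.SINGLE)
                    g.add_edge(u, v)
            m = mw.GetMol()
            Chem.SanitizeMol(m)
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            oracle = sum(
                1 for i in range(n) for j in range(i + 1, n)
                if lengths[i].get(j) == 3
            )
            assert wiener_polarity(m) == oracle


class TestPeoeCharges:
    def test_symmetry_equivalent_atoms(self):
        q = peoe_charges(mol("CC"))
        assert q[0] == pytest.approx(q[1])

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "CC(=O)O", "CCN"])
    def test_neutral_molecules_conserve_charge(self, smiles):
        assert peoe_charges(mol(smiles)).sum() == pytest.approx(0.0, abs=1e-6)

    def test_cation_sums_to_formal_charge(self):
        assert peoe_charges(mol("C[N+](C)(C)C")).sum() == pytest.approx(1.0, abs=1e-6)

    def test_methanol_sign_pattern(self):
        # O more electronegative than C and H: q(O) < 0 < q(H on O)
        m = Chem.AddHs(mol("CO"))
        q = peoe_charges(mol("CO"))
        o_idx = next(a.GetIdx() for a in m.GetAtoms() if a.GetSymbol() == "O")
        oh_idx = next(
            a.GetIdx() for a in m.GetAtoms()
            if a.GetSymbol() == "H" and a.GetNeighbors()[0].GetSymbol() == "O"
        )
        assert q[o_idx] < 0 < q[oh_idx]


class TestApproximateVsa:
    def test_single_atom_full_sphere(self):
        areas, total = approximate_vsa(mol("[Ne]"))
        r = Chem.GetPeriodicTable().GetRvdw(10)
        assert total == pytest.approx(4 * np.pi * r**2)

    def test_symmetric_atoms_equal_contributions(self):
        areas, _ = approximate_vsa(mol("CC"))
        assert areas[0] == pytest.approx(areas[1])

    def test_bonded_carbon_below_full_sphere(self):
        areas, _ = approximate_vsa(mol("C"))
        r = Chem.GetPeriodicTable().GetRvdw(6)
        assert 0 < areas[0] < 4 * np.pi * r**2


class TestVsaBlock:
    def test_32_columns(self):
        block, _, _ = vsa_descriptor_block(mol("CCO"))
        assert len(block) == 32
        assert set(block) == set(VSA_BLOCK_NAMES)

    def test_bin_families_partition_surface(self, random_library):
        """Each of the three bin families sums to vdw_area (1e-6 relative)
        for every molecule of a 500-compound random synthetic library."""
        for rec in random_library:
            block, vdw_area, _ = vsa_descriptor_block(rec.mol)
            for names in (D.SLOGP_NAMES, D.SMR_NAMES, D.PEOE_NAMES):
                family = sum(block[n] for n in names)
                assert family == pytest.approx(vdw_area, rel=1e-6)

    def test_fppos_zero_without_strongly_positive_atoms(self):
        # an alkane has no atom at charge >= +0.20
        _, _, fppos = vsa_descriptor_block(mol("CCCCC"))
        assert fppos == 0.0

    def test_fppos_in_unit_interval(self, random_library):
        for rec in random_library[:50]:
            _, _, fppos = vsa_descriptor_block(rec.mol)
            assert 0.0 <= fppos <= 1.0


class TestScaffoldIndicators:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("OC(=O)[C@@H]1CCCNC1", (1, 0, 0)),  # R-nipecotic acid
            ("OC(=O)[C@H]1CCCNC1", (0, 1, 0)),   # S-nipecotic acid
            ("OC(=O)C1=CCCNC1", (0, 0, 1)),      # guvacine
            ("OC(=O)[C@@H]1CCCN(CCCC)C1", (1, 0, 0)),  # N-substituted
        ],
    )
    def test_scaffold_assignment(self, smiles, expected):
        assert scaffold_indicators(mol(smiles)) == expected

    def test_no_scaffold_warns(self):
        with pytest.warns(UserWarning, match="no amino-acid scaffold"):
            assert scaffold_indicators(mol("c1ccccc1")) == (0, 0, 0)

    def test_unspecified_stereo_is_an_error(self):
        with pytest.raises(ScaffoldAmbiguityError):
            scaffold_indicators(mol("OC(=O)C1CCCNC1"))

    def test_ester_does_not_match(self):
        with pytest.warns(UserWarning):
            assert scaffold_indicators(mol("COC(=O)[C@@H]1CCCNC1")) == (0, 0, 0)

    def test_exclusivity_on_synthetic_library(self, random_library):
        for rec in random_library:
            assert sum(scaffold_indicators(rec.mol)) <= 1


class TestDescriptorMatrix:
    def test_vsa_ind_has_35_columns(self, benchmark_library):
        records, _ = benchmark_library
        matrix = compute_descriptor_matrix(records[:2], "vsa_ind")
        assert matrix.frame.shape == (2, 35)
        assert list(matrix.frame.columns) == list(VSA_BLOCK_NAMES + INDICATOR_NAMES)

    def test_physchem16_has_16_columns(self, benchmark_library):
        records, _ = benchmark_library
        matrix = compute_descriptor_matrix(records[:2], "physchem16")
        assert matrix.frame.shape == (2, 16)

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_descriptor_matrix([], "vsa_ind")

    def test_determinism(self):
        smiles = "C(c1ccccc1)(c1ccccc1)=NOCCCN1CCC[C@@H](C(O)=O)C1"
        v1 = descriptor_vector(mol(smiles))
        v2 = descriptor_vector(mol(smiles))
        assert v1 == v2

    def test_csv_round_trip(self, tmp_path, benchmark_library):
        records, _ = benchmark_library
        matrix = compute_descriptor_matrix(records[:3], "vsa_ind")
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        back = D.DescriptorMatrix.from_csv(path)
        assert back.ids == matrix.ids
        np.testing.assert_allclose(back.values, matrix.values, rtol=1e-12)
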