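import numpy as np
import pytest

from binqsar.splitting import (
    ClusterAssignment,
    Split,
    cluster_fingerprints,
    diversity_split,
    maccs_fingerprint,
    random_split,
    tanimoto,
)

from conftest import mol


class TestMaccs:
    def test_deterministic(self):
        a = maccs_fingerprint(mol("CCOc1ccccc1"))
        b = maccs_fingerprint(mol("CCOc1ccccc1"))
        assert np.array_equal(a, b)
        assert a.shape == (166,)

    def test_popcount_bounds(self):
        fp = maccs_fingerprint(mol("C"))
        assert 0 <= fp.sum() < 166

    def test_aromatic_keys_differ(self):
        assert not np.array_equal(
            maccs_fingerprint(mol("c1ccccc1")), maccs_fingerprint(mol("C1CCCCC1"))
        )


class TestTanimoto:
    def test_identical_vectors(self):
        a = np.zeros(166, dtype=bool)
        a[:5] = True
        assert tanimoto(a, a) == 1.0

    def test_disjoint_vectors(self):
        a = np.zeros(8, dtype=bool)
        b = np.zeros(8, dtype=bool)
        a[0], b[1] = True, True
        assert tanimoto(a, b) == 0.0

    def test_hand_counted_ratio(self):
        a = np.array([1, 1, 1, 1, 0, 0], dtype=bool)
        b = np.array([1, 1, 1, 0, 1, 1], dtype=bool)
        assert tanimoto(a, b) == 0.5  # 3 common / 6 in union

    def test_both_empty_convention(self):
        z = np.zeros(10, dtype=bool)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(4, dtype=bool), np.zeros(5, dtype=bool))


def _block_fingerprints():
    """Two 5-member blocks: within-block Tanimoto >= 0.8, between < 0.3."""
    fps = []
    base_a = np.zeros(166, dtype=bool)
    base_a[:40] = True
    base_b = np.zeros(166, dtype=bool)
    base_b[100:140] = True
    for base, start in ((base_a, 40), (base_b, 140)):
        for k in range(5):
            fp = base.copy()
            fp[start + k] = True
            fps.append(fp)
    return fps


class TestClustering:
    def test_identical_fingerprints_one_cluster(self):
        fp = maccs_fingerprint(mol("CCO"))
        assignment = cluster_fingerprints([fp] * 6)
        assert len(set(assignment.cluster_ids)) == 1

    def test_threshold_one_all_singletons(self):
        fps = [maccs_fingerprint(mol(s)) for s in ("CCO", "CCC", "c1ccccc1", "CCN")]
        assignment = cluster_fingerprints(fps, 1.0)
        assert len(set(assignment.cluster_ids)) == 4

    def test_two_blocks_recovered(self):
        fps = _block_fingerprints()
        sims = np.array([[tanimoto(a, b) for b in fps] for a in fps])
        # verify the constructed similarity structure by brute force
        assert sims[:5, :5].min() >= 0.8 and sims[5:, 5:].min() >= 0.8
        assert sims[:5, 5:].max() < 0.3
        assignment = cluster_fingerprints(fps, 0.75)
        ids = assignment.cluster_ids
        assert len(set(ids)) == 2
        assert len(set(ids[:5])) == 1 and len(set(ids[5:])) == 1

    def test_deterministic_and_exhaustive(self):
        fps = _block_fingerprints()
        a1 = cluster_fingerprints(fps, 0.75)
        a2 = cluster_fingerprints(fps, 0.75)
        assert a1.cluster_ids == a2.cluster_ids
        assert all(c >= 0 for c in a1.cluster_ids)

    def test_refinement_at_higher_threshold(self):
        # raising the threshold never merges clusters found at the lower one
        fps = _block_fingerprints()
        coarse = cluster_fingerprints(fps, 0.5)
        fine = cluster_fingerprints(fps, 0.9)
        for cid in set(fine.cluster_ids):
            members = [i for i, c in enumerate(fine.cluster_ids) if c == cid]
            assert len({coarse.cluster_ids[i] for i in members}) == 1

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            cluster_fingerprints([np.zeros(166, dtype=bool)], 0.0)


class TestDiversitySplit:
    def test_cluster_of_five_gives_one_test_compound(self):
        clusters = ClusterAssignment([0] * 5, 0.75)
        split = diversity_split(clusters, [1, 1, 0, 0, 0])
        assert len(split.test) == 1

    def test_cluster_of_four_gives_none(self):
        clusters = ClusterAssignment([0] * 4 + [1] * 5, 0.75)
        labels = [1, 0, 0, 0] + [1, 1, 0, 0, 0]
        split = diversity_split(clusters, labels)
        assert all(i >= 4 for i in split.test)

    def test_largest_remainder_apportionment(self):
        # cluster of 20 with 5 actives / 15 inactives -> 2 test compounds,
        # remainders tie (0.5 vs 0.5): active class wins the seat -> 1 + 1
        clusters = ClusterAssignment([0] * 20, 0.75)
        labels = [1] * 5 + [0] * 15
        split = diversity_split(clusters, labels)
        assert split.class_counts["test"] == {"active": 1, "inactive": 1}

    def test_all_small_clusters_is_an_error(self):
        clusters = ClusterAssignment([0, 0, 1, 1], 0.75)
        with pytest.raises(ValueError, match="test set would be empty"):
            diversity_split(clusters, [1, 0, 1, 0])

    def test_partition_and_determinism(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            clusters = ClusterAssignment(rng.integers(0, 4, n).tolist(), 0.75)
            labels = rng.integers(0, 2, n).tolist()
            if sum(labels) < 2 or n - sum(labels) < 2:
                continue
            sizes = np.bincount(clusters.cluster_ids)
            if (sizes < 5).all():
                continue
            try:
                s1 = diversity_split(clusters, labels)
            except ValueError:
                continue  # degenerate class layout
            s2 = diversity_split(clusters, labels)
            assert s1.train == s2.train and s1.test == s2.test
            assert sorted(s1.train + s1.test) == list(range(n))


class TestRandomSplit:
    def test_paper_scheme_16_compound_test_set(self):
        labels = [1] * 57 + [0] * 105
        split = random_split(labels, seed=1)
        assert len(split.test) == 16
        assert split.class_counts["test"] == {"active": 6, "inactive": 10}
        assert len(split.train) == 146

    def test_reproducible_from_seed(self):
        labels = [1] * 57 + [0] * 105
        s1, s2 = random_split(labels, seed=3), random_split(labels, seed=3)
        assert s1.test == s2.test
        assert random_split(labels, seed=4).test != s1.test

    def test_ten_seed_scheme_is_stratified(self):
        labels = [1] * 57 + [0] * 105
        for seed in range(1, 11):
            split = random_split(labels, seed=seed)
            assert split.class_counts["test"] == {"active": 6, "inactive": 10}
            assert sorted(split.train + split.test) == list(range(162))

    def test_insufficient_class_counts(self):
        with pytest.raises(ValueError, match="available"):
            random_split([1] * 5 + [0] * 20, n_test_active=6)

    def test_training_set_must_keep_both_classes(self):
        with pytest.raises(ValueError, match="lose a class"):
            random_split([1] * 6 + [0] * 20, n_test_active=6)


class TestSplitType:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Split(train=[0, 1], test=[1, 2], method="random")
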