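"""Jaccard similarity, dendrograms, VI and threshold selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cavnet as cn
from _oracles import brute_average_linkage, brute_jaccard, brute_vi_bits


class TestJaccard:
    def test_worked_example_values(self, worked_example):
        sim = cn.jaccard_similarity(worked_example)
        assert sim.J_S[0, 1] == 1.0            # identical histories
        assert sim.J_S[0, 4] == pytest.approx(2 / 3)
        assert sim.J_S[1, 4] == pytest.approx(2 / 3)
        assert sim.J_S[0, 2] == 0.0            # disjoint histories

    def test_silent_pair_scores_zero(self):
        X = np.zeros((2, 4), dtype=np.uint8)
        sim = cn.jaccard_similarity(X)
        assert sim.J_S[0, 1] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_sets(self, seed):
        rng = np.random.default_rng(seed)
        X = (rng.random((rng.integers(2, 9), rng.integers(1, 12))) < 0.4).astype(np.uint8)
        np.testing.assert_allclose(cn.jaccard_similarity(X).J_S, brute_jaccard(X))


class TestNormalizedDistance:
    def test_identical_dense_rows_are_close(self):
        rng = np.random.default_rng(0)
        row = (rng.random(60) < 0.5).astype(np.uint8)
        X = np.tile(row, (4, 1))
        sim = cn.normalized_jaccard_distance(X, n_surrogates=200, seed=1)
        off = ~np.eye(4, dtype=bool)
        assert np.all(sim.D_norm[off] < 0.5)

    def test_independent_rows_are_uninformative(self):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = (rng.random((20, 300)) < 0.3).astype(np.uint8)
            sim = cn.normalized_jaccard_distance(X, n_surrogates=200, seed=seed)
            off = ~np.eye(20, dtype=bool)
            vals.append(sim.D_norm[off].mean())
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_seed_determinism(self, worked_example):
        a = cn.normalized_jaccard_distance(worked_example, n_surrogates=50, seed=3)
        b = cn.normalized_jaccard_distance(worked_example, n_surrogates=50, seed=3)
        np.testing.assert_array_equal(a.D_norm, b.D_norm)

    def test_silent_clusters_become_distant_singletons(self):
        rng = np.random.default_rng(4)
        X = (rng.random((6, 40)) < 0.5).astype(np.uint8)
        X[2] = 0
        sim = cn.normalized_jaccard_distance(X, n_surrogates=100, seed=5)
        assert np.all(sim.D_norm[2, [i for i in range(6) if i != 2]] == 1.0)
        dend = cn.build_dendrogram(sim.D_norm)
        scan, part = cn.select_threshold(dend)
        assert np.sum(part.labels == part.labels[2]) == 1  # singleton


class TestDendrogram:
    def test_two_leaves_single_merge(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        dend = cn.build_dendrogram(D)
        assert dend.linkage.shape[0] == 1
        assert dend.linkage[0, 2] == pytest.approx(0.4)

    def test_identical_histories_merge_at_zero(self, worked_example):
        dend = cn.build_dendrogram(cn.jaccard_similarity(worked_example).J_D)
        heights = dend.linkage[:, 2]
        assert np.count_nonzero(heights == 0.0) == 2  # {1,2} and {3,4}

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        D = rng.uniform(0.05, 1.0, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        dend = cn.build_dendrogram(D)
        np.testing.assert_allclose(
            sorted(dend.linkage[:, 2]), brute_average_linkage(D), rtol=1e-10
        )

    def test_nan_distance_raises(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            cn.build_dendrogram(D)


class TestCutDendrogram:
    def test_moduli_monotone_in_threshold(self, worked_example):
        dend = cn.build_dendrogram(cn.jaccard_similarity(worked_example).J_D)
        counts = [cn.cut_dendrogram(dend, d).n_moduli for d in np.arange(0, 1.2, 0.05)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_extreme_thresholds(self):
        rng = np.random.default_rng(2)
        D = rng.uniform(0.2, 1.0, (5, 5))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        dend = cn.build_dendrogram(D)
        assert cn.cut_dendrogram(dend, 0.0).n_moduli == 5
        assert cn.cut_dendrogram(dend, dend.max_height).n_moduli == 1


class TestVariationOfInformation:
    def test_identical_partitions_zero(self):
        assert cn.variation_of_information([1, 1, 2, 2], [5, 5, 9, 9]) == 0.0

    def test_reference_value(self):
        assert cn.variation_of_information([1, 1, 2, 2, 2], [1, 1, 1, 2, 2]) == \
            pytest.approx(1.1019550008653875, abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cn.variation_of_information([1, 2], [1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_symmetry_triangle_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        p = [rng.integers(0, 4, n) for _ in range(3)]
        v01 = cn.variation_of_information(p[0], p[1])
        assert v01 == pytest.approx(cn.variation_of_information(p[1], p[0]))
        assert v01 == pytest.approx(brute_vi_bits(p[0], p[1]), abs=1e-9)
        v02 = cn.variation_of_information(p[0], p[2])
        v12 = cn.variation_of_information(p[1], p[2])
        assert v01 <= v02 + v12 + 1e-9


class TestSelectThreshold:
    def test_worked_example_selects_two_moduli(self, worked_example):
        dend = cn.build_dendrogram(cn.jaccard_similarity(worked_example).J_D)
        scan, part = cn.select_threshold(dend)
        assert part.n_moduli == 2
        labels = part.labels
        assert labels[0] == labels[1] == labels[4]
        assert labels[2] == labels[3] != labels[0]

    def test_leaf_relabeling_preserves_moduli_count(self, worked_example):
        D = cn.jaccard_similarity(worked_example).J_D
        perm = np.array([3, 0, 4, 1, 2])
        Dp = D[np.ix_(perm, perm)]
        _, p1 = cn.select_threshold(cn.build_dendrogram(D))
        _, p2 = cn.select_threshold(cn.build_dendrogram(Dp))
        assert p1.n_moduli == p2.n_moduli

    def test_planted_blocks_recovered(self):
        # two well-separated blocks: selected partition matches exactly
        D = np.ones((8, 8)) * 0.9
        D[:4, :4] = 0.1
        D[4:, 4:] = 0.1
        np.fill_diagonal(D, 0.0)
        scan, part = cn.select_threshold(cn.build_dendrogram(D))
        truth = [1, 1, 1, 1, 2, 2, 2, 2]
        assert cn.variation_of_information(part, cn.Partition(np.array(truth))) == 0.0

    def test_trivial_dendrogram_raises(self):
        D = np.zeros((3, 3))  # everything merges at height 0
        with pytest.raises(ValueError):
            cn.select_threshold(cn.build_dendrogram(D))


class TestComparePartitions:
    def test_identical(self):
        p = cn.Partition(np.array([1, 1, 2, 2]))
        rep = cn.compare_partitions(p, p)
        assert rep["n_splits"] == 0 and rep["vi_bits"] == 0.0

    def test_one_to_three_split(self):
        before = cn.Partition(np.ones(15, dtype=int))
        after = cn.Partition(np.repeat([1, 2, 3], 5))
        rep = cn.compare_partitions(before, after)
        assert rep["n_splits"] == 1
        assert rep["n_moduli_after"] == 3
        assert rep["mapping"][1] == {1: 5, 2: 5, 3: 5}
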