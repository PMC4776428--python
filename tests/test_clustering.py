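"""Dissimilarity, average-link clustering, centrotypes and model selection."""

import io

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from stabica import (
    cca_project,
    centrotype,
    cut_dendrogram,
    extract_centrotypes,
    hca_average_link,
    quality_index,
    select_cluster_number,
    spearman_dissimilarity,
)
from stabica.clustering import dendrogram_to_newick


class TestSpearmanDissimilarity:
    def test_self_distance_zero_and_monotone_invariance(self, rng):
        x = rng.random(20)
        bank = np.column_stack([x, -np.exp(x), x**3])
        D = spearman_dissimilarity(bank)
        assert D[0, 0] == 0.0
        # strictly decreasing and strictly increasing monotone transforms
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_hand_ranked_oracle(self):
        bank = np.column_stack([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]])
        D = spearman_dissimilarity(bank)
        assert D[0, 1] == pytest.approx(0.2, abs=1e-12)  # 1 - 0.8

    def test_matches_scipy_pairwise(self, rng):
        bank = rng.random((15, 6))
        D = spearman_dissimilarity(bank)
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else 1 - abs(spearmanr(bank[:, i], bank[:, j]).statistic)
                assert D[i, j] == pytest.approx(expected, abs=1e-10)
        assert np.all((D >= 0) & (D <= 1))
        np.testing.assert_allclose(D, D.T)

    def test_constant_column_error_names_offender(self, rng):
        bank = rng.random((10, 3))
        bank[:, 2] = 7.0
        with pytest.raises(ValueError, match="column 2"):
            spearman_dissimilarity(bank)


def _naive_average_link_heights(D):
    """O(N^3) agglomeration oracle: returns sorted merge heights."""
    clusters = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


class TestAverageLink:
    def test_two_tight_pairs_merge_first_at_pair_distances(self):
        D = np.full((4, 4), 0.9)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        D[2, 3] = D[3, 2] = 0.2
        Z = hca_average_link(D)
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.2)

    def test_heights_match_naive_oracle(self, rng):
        X = rng.random((10, 3))
        D = squareform(pdist(X))
        Z = hca_average_link(D)
        np.testing.assert_allclose(sorted(Z[:, 2]), _naive_average_link_heights(D),
                                   atol=1e-10)

    def test_extreme_cuts(self, rng):
        D = squareform(pdist(rng.random((7, 2))))
        Z = hca_average_link(D)
        assert cut_dendrogram(Z, 7).c == 7   # all singletons
        assert cut_dendrogram(Z, 1).c == 1   # root
        part = cut_dendrogram(Z, 3)
        assert sorted(np.unique(part.labels)) == [1, 2, 3]

    def test_newick_export_is_parseable(self, rng):
        from Bio import Phylo

        D = squareform(pdist(rng.random((6, 2))))
        newick = dendrogram_to_newick(hca_average_link(D), [f"c{i}" for i in range(6)])
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == [f"c{i}" for i in range(6)]


class TestCentrotype:
    def test_singleton(self, rng):
        D = squareform(pdist(rng.random((5, 2))))
        assert centrotype(D, [3]) == 3

    def test_restricted_row_sum_oracle(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = 0.2
        D[0, 2] = D[2, 0] = 0.7
        D[1, 2] = D[2, 1] = 0.2
        # row sums restricted to all members: (0.9, 0.4, 0.9) -> member 1
        assert centrotype(D, [0, 1, 2]) == 1

    def test_exhaustive_search_oracle(self, rng):
        D = squareform(pdist(rng.random((50, 3))))
        members = rng.choice(50, size=20, replace=False)
        expected = min(members, key=lambda i: (D[i, members].sum(), i))
        assert centrotype(D, members) == expected

    def test_equilateral_tie_takes_smallest_index(self):
        D = np.full((4, 4), 0.5)
        np.fill_diagonal(D, 0.0)
        assert centrotype(D, [1, 2, 3]) == 1


class TestQualityIndex:
    def test_brute_force_oracle_on_toy_configuration(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]], float)
        labels = np.array([1, 1, 1, 2, 2, 2])
        got = quality_index(coords, labels)
        # direct double loop
        dist = squareform(pdist(coords))
        within = []
        for lab in (1, 2):
            idx = np.flatnonzero(labels == lab)
            pairs = [dist[i, j] for i in idx for j in idx if i != j]
            within.append(np.mean(pairs))
        between = [dist[i, j] for i in range(6) for j in range(6)
                   if labels[i] != labels[j]]
        assert got == pytest.approx(np.mean(within) / np.mean(between), abs=1e-12)

    def test_merging_separated_clusters_increases_index(self):
        coords = np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5], [10, 0], [10.1, 0]], float)
        labels3 = np.array([1, 1, 2, 2, 3, 3])
        merged = np.array([1, 1, 2, 2, 2, 2])
        assert quality_index(coords, merged) > quality_index(coords, labels3)

    def test_far_separation_drives_index_to_zero(self):
        coords = np.array([[0, 0], [1e-3, 0], [1e6, 0], [1e6, 1e-3]], float)
        idx = quality_index(coords, np.array([1, 1, 2, 2]))
        assert idx < 1e-8

    def test_singletons_contribute_zero(self):
        coords = np.array([[0, 0], [1, 0], [1, 1]], float)
        # clusters: {0,1} and singleton {2}: numerator = (d01 + 0) / 2
        got = quality_index(coords, np.array([1, 1, 2]))
        d = squareform(pdist(coords))
        expected = (d[0, 1] / 2) / np.mean([d[0, 2], d[1, 2]])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError):
            quality_index(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_dissimilarity_variant_matches_double_loop(self, rng):
        D = squareform(pdist(rng.random((8, 2))))
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3])
        got = quality_index(None, labels, on="dissimilarity", D=D)
        withins = []
        for lab in (1, 2, 3):
            idx = np.flatnonzero(labels == lab)
            withins.append(np.mean([D[i, j] for i in idx for j in idx if i != j]))
        between = np.mean([D[i, j] for i in range(8) for j in range(8)
                           if labels[i] != labels[j]])
        assert got == pytest.approx(np.mean(withins) / between, abs=1e-12)


class TestSelectClusterNumber:
    def test_planted_bank_selects_true_component_count(self, rng):
        # bank of 3 recurring components with estimate jitter
        true = rng.standard_normal((30, 3))
        cols = [true[:, j] + 0.3 * rng.standard_normal(30)
                for j in range(3) for _ in range(20)]
        D = spearman_dissimilarity(np.column_stack(cols))
        proj = cca_project(D, seed=4)
        c, curve = select_cluster_number(D, proj.coords, (2, 3))
        assert c == 3
        assert curve[3] < 0.5 * curve[2]  # isolating the components is decisive

    def test_degenerate_single_candidate_warns_flat(self, rng, caplog):
        D = squareform(pdist(rng.random((3, 2))))
        with caplog.at_level("WARNING", logger="stabica.clustering"):
            c, curve = select_cluster_number(D, rng.random((3, 2)), (2, 2))
        assert c == 2 and list(curve) == [2]
        assert "flat" in caplog.text

    def test_invalid_range_rejected(self, rng):
        D = squareform(pdist(rng.random((5, 2))))
        with pytest.raises(ValueError):
            select_cluster_number(D, rng.random((5, 2)), (2, 5))


class TestExtractCentrotypes:
    def test_members_and_sizes_consistent(self, small_run):
        result, _ = small_run
        oc = result.centrotypes
        assert oc.OC.shape == (result.X.n_samples, result.c)
        assert oc.cluster_size.sum() == result.bank.S.shape[1]
        for a in range(oc.c):
            members = np.flatnonzero(oc.labels == a + 1)
            assert oc.member_column[a] in members
            np.testing.assert_array_equal(
                oc.OC[:, a], result.bank.S[:, oc.member_column[a]])
            assert oc.member_column[a] == centrotype(result.D, members)
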