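"""Promoter TFBS similarity: matrix build, PCA, clustering, group tests."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import adjusted_rand_score, silhouette_score

from kgxpress.errors import KgXpressError
from kgxpress.kg_query import HomologExpressionPair, classify_concordance
from kgxpress.promoter_similarity import (
    TFBSMatrix,
    build_tfbs_matrix,
    correlation_matrix,
    cut_clusters,
    drop_ubiquitous_families,
    find_absent_families,
    hierarchical_cluster,
    linkage_to_newick,
    pair_group_similarity,
    pca,
)
from tests.conftest import two_cluster_matrix


def matrix_from_rows(genes, rows):
    rows = np.asarray(rows, dtype=np.int8)
    return TFBSMatrix(
        genes=list(genes),
        families=[f"F{i:02d}" for i in range(rows.shape[1])],
        values=rows,
    )


def make_pair(a, b, dir_a="decreased", dir_b="decreased"):
    return HomologExpressionPair(
        exposure="PECO:0007404", gene_a=a, gene_b=b, taxon_a="", taxon_b="",
        direction_a=dir_a, direction_b=dir_b,
        concordance=classify_concordance(dir_a, dir_b),
    )


class TestBuildMatrix:
    def test_positive_count_is_presence(self):
        m = build_tfbs_matrix([("g1", "bHLH", 3)])
        assert m.values.tolist() == [[1]]

    def test_zero_count_is_absence(self):
        m = build_tfbs_matrix([("g1", "bHLH", 0), ("g1", "Dof", 2)])
        assert m.families == ["Dof", "bHLH"]
        assert m.values.tolist() == [[1, 0]]

    def test_motif_to_family_aggregation(self):
        m = build_tfbs_matrix(
            [("g1", "MYB4-motif", 0), ("g1", "MYB77-motif", 2)],
            family_map={"MYB4-motif": "MYB", "MYB77-motif": "MYB"},
        )
        assert m.families == ["MYB"]
        assert m.values.tolist() == [[1]]

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            build_tfbs_matrix([("g1", "bHLH", -1)])

    def test_generator_table_matches_manifest(self, default_bundle):
        bundle, truth = default_bundle
        m = build_tfbs_matrix(bundle.tfbs_rows)
        assert set(m.families) >= set(truth.ubiquitous_families)
        for family in truth.ubiquitous_families:
            assert m.values[:, m.families.index(family)].all()


class TestDropUbiquitous:
    def test_all_present_family_removed(self):
        m = matrix_from_rows(["a", "b"], [[1, 1], [1, 0]])
        reduced, removed = drop_ubiquitous_families(m)
        assert removed == ["F00"]
        assert reduced.families == ["F01"]

    def test_family_absent_in_one_gene_retained(self):
        m = matrix_from_rows(["a", "b"], [[1, 1], [0, 1]])
        _, removed = drop_ubiquitous_families(m)
        assert removed == ["F01"]

    def test_idempotent(self):
        m = matrix_from_rows(["a", "b", "c"], [[1, 1, 0], [1, 0, 1], [1, 1, 1]])
        once, _ = drop_ubiquitous_families(m)
        twice, removed_again = drop_ubiquitous_families(once)
        assert removed_again == []
        assert twice.values.tolist() == once.values.tolist()

    def test_all_ubiquitous_is_error(self):
        m = matrix_from_rows(["a", "b"], [[1, 1], [1, 1]])
        with pytest.raises(KgXpressError):
            drop_ubiquitous_families(m)

    def test_planted_twelve_families_recovered(self, default_bundle):
        bundle, truth = default_bundle
        m = build_tfbs_matrix(bundle.tfbs_rows)
        _, removed = drop_ubiquitous_families(m)
        assert removed == truth.ubiquitous_families
        assert len(removed) == 12


class TestPCA:
    def test_duplicate_rows_get_identical_coordinates(self, rng):
        base = (rng.random((5, 12)) < 0.5).astype(float)
        X = np.vstack([base, base[0]])
        result = pca(X, n_components=2)
        np.testing.assert_allclose(result.coordinates[0], result.coordinates[-1], atol=1e-10)

    def test_complete_data_matches_plain_svd(self, rng):
        X = rng.random((15, 30))
        result = pca(X, n_components=3)
        assert result.n_iterations == 0
        sk = SkPCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            result.variance_fractions, sk.explained_variance_ratio_, atol=1e-10
        )
        scores = sk.transform(X)
        for k in range(3):
            ours, theirs = result.coordinates[:, k], scores[:, k]
            if np.dot(ours, theirs) < 0:
                theirs = -theirs
            np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_variance_fractions_non_increasing_and_bounded(self, rng):
        X = rng.random((10, 20))
        result = pca(X, n_components=5)
        fractions = result.variance_fractions
        assert np.all(fractions[:-1] >= fractions[1:] - 1e-12)
        assert 0 < fractions.sum() <= 1 + 1e-12

    def test_imputation_recovers_low_rank_entries(self, rng):
        # rank-2 matrix with 10% missing: imputed entries should be close
        U = rng.normal(size=(30, 2))
        V = rng.normal(size=(2, 20))
        X = U @ V
        missing = rng.random(X.shape) < 0.1
        X_obs = np.where(missing, np.nan, X)
        result = pca(X_obs, n_components=2, tol=1e-9, max_iter=500)
        assert result.n_iterations > 0
        assert result.variance_fractions.sum() > 0.99

    def test_planted_clusters_separate_on_pc1(self, rng):
        genes, rows, labels = two_cluster_matrix(rng)
        result = pca(rows.astype(float), n_components=2)
        score = silhouette_score(result.coordinates[:, :1], labels)
        assert score > 0

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            pca(np.ones((4, 4)), n_components=2)


class TestCorrelationAndClustering:
    def test_correlation_matrix_symmetric_unit_diagonal(self, rng):
        genes, rows, _ = two_cluster_matrix(rng, n_per_cluster=5)
        corr = correlation_matrix(matrix_from_rows(genes, rows))
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_zero_variance_row_error_names_gene(self):
        m = matrix_from_rows(["flat", "ok"], [[1, 1, 1], [0, 1, 0]])
        with pytest.raises(KgXpressError, match="flat"):
            correlation_matrix(m)

    def test_identical_rows_merge_at_distance_zero(self):
        m = matrix_from_rows(["a", "b", "c"], [[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        result = hierarchical_cluster(m)
        first_merge = result.linkage[0]
        assert first_merge[2] == pytest.approx(0.0)
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_anticorrelated_rows_merge_at_distance_two(self):
        m = matrix_from_rows(["a", "b"], [[1, 0, 1, 0], [0, 1, 0, 1]])
        result = hierarchical_cluster(m)
        assert result.linkage[0][2] == pytest.approx(2.0)

    def test_complete_linkage_against_scipy_reference(self, rng):
        genes, rows, _ = two_cluster_matrix(rng, n_per_cluster=6)
        result = hierarchical_cluster(matrix_from_rows(genes, rows))
        dist = 1 - np.corrcoef(rows.astype(float))
        np.fill_diagonal(dist, 0)
        expected = hierarchy.linkage(
            dist[np.triu_indices_from(dist, k=1)], method="complete"
        )
        np.testing.assert_allclose(result.linkage, expected, atol=1e-12)

    def test_planted_two_clusters_recovered_exactly(self, rng):
        genes, rows, labels = two_cluster_matrix(rng)
        result = hierarchical_cluster(matrix_from_rows(genes, rows))
        assignment = cut_clusters(result, k=2)
        observed = [assignment[g] for g in genes]
        assert adjusted_rand_score(labels, observed) == 1.0

    def test_newick_export_contains_all_genes(self, rng):
        genes, rows, _ = two_cluster_matrix(rng, n_per_cluster=3)
        text = linkage_to_newick(hierarchical_cluster(matrix_from_rows(genes, rows)))
        assert text.endswith(";")
        for gene in genes:
            assert gene in text


class TestPairGroupSimilarity:
    def test_identical_profiles_correlate_to_one(self):
        m = matrix_from_rows(["a", "b"], [[1, 0, 1, 0], [1, 0, 1, 0]])
        summary = pair_group_similarity(m, [make_pair("a", "b")])
        assert summary.per_pair[0][3] == pytest.approx(1.0)

    def test_complementary_profiles_correlate_to_minus_one(self):
        m = matrix_from_rows(["a", "b"], [[1, 0, 1, 0], [0, 1, 0, 1]])
        summary = pair_group_similarity(m, [make_pair("a", "b")])
        assert summary.per_pair[0][3] == pytest.approx(-1.0)

    def test_missing_gene_is_skipped_and_reported(self):
        m = matrix_from_rows(["a", "b"], [[1, 0], [0, 1]])
        summary = pair_group_similarity(m, [make_pair("a", "ghost")])
        assert summary.per_pair == []
        assert summary.skipped_pairs[0][:2] == ("a", "ghost")

    def test_group_means_and_rank_test_on_generated_bundle(self, default_bundle):
        bundle, truth = default_bundle
        m, _ = drop_ubiquitous_families(build_tfbs_matrix(bundle.tfbs_rows))
        pairs = [
            make_pair(p.gene_a, p.gene_b, p.direction_a, p.direction_b)
            for p in truth.pairs
        ]
        summary = pair_group_similarity(m, pairs)
        assert summary.group_means["similar"] > summary.group_means["contrasting"]
        assert summary.mannwhitney_p < 0.05
        assert set(summary.group_submatrices) == {"similar", "contrasting"}
        for _, (genes, corr) in summary.group_submatrices.items():
            assert corr.shape == (len(genes), len(genes))


class TestFindAbsentFamilies:
    def test_family_absent_everywhere_not_returned(self):
        m = matrix_from_rows(["a", "b", "c"], [[0, 1], [0, 1], [0, 0]])
        assert find_absent_families(m, ["a"]) == []

    def test_family_absent_in_subset_present_outside_returned(self):
        m = matrix_from_rows(["a", "b", "c"], [[0, 1], [1, 1], [1, 0]])
        assert find_absent_families(m, ["a"]) == ["F00"]

    def test_subset_must_be_proper(self):
        m = matrix_from_rows(["a", "b"], [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            find_absent_families(m, ["a", "b"])
        with pytest.raises(ValueError):
            find_absent_families(m, [])

    def test_planted_eleven_families_recovered(self, default_bundle):
        bundle, truth = default_bundle
        m, _ = drop_ubiquitous_families(build_tfbs_matrix(bundle.tfbs_rows))
        found = find_absent_families(m, truth.divergent_subset)
        assert found == truth.absent_families
        assert len(found) == 11
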