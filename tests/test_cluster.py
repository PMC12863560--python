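"""PCA, Gaussian-mixture clustering with BIC selection, distinction criteria."""

import numpy as np
import pytest

import qscan
from qscan.cluster import convex_hulls_disjoint


class TestRunPCA:
    def test_reference_variance_fractions(self, table2_pca):
        np.testing.assert_allclose(table2_pca.variance_fraction[:3],
                                   [0.672, 0.259, 0.062], atol=0.002)

    def test_thirteen_variable_fractions(self, table1, table2):
        idx = [table1.subjects.index(s) for s in table2.subjects]
        cols = [f"d{d:g}" for d in table1.doses]
        t13 = qscan.VariableTable(
            table2.subjects, cols + table2.variables,
            np.column_stack([table1.responses[idx], table2.values]))
        pca = qscan.run_pca(t13)
        np.testing.assert_allclose(pca.variance_fraction[:3],
                                   [0.49, 0.39, 0.06], atol=0.015)

    def test_fractions_sum_to_one(self, table2_pca):
        assert table2_pca.variance_fraction.sum() == pytest.approx(1.0,
                                                                   abs=1e-10)

    def test_loadings_orthonormal(self, table2_pca):
        L = table2_pca.loadings
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_reconstruction(self, table2, table2_pca):
        X = table2.values
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(
            table2_pca.scores @ table2_pca.loadings.T, Z, atol=1e-8)

    def test_sign_convention(self, table2_pca):
        L = table2_pca.loadings
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_rank_one_duplicated_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        t = qscan.VariableTable([f"s{i}" for i in range(8)], ["u", "v"],
                                np.column_stack([x, 2 * x + 1]))
        pca = qscan.run_pca(t)
        assert pca.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_three_variable_analytic_eigenvalues(self):
        """Eigenvalues of an equicorrelation matrix are known in closed
        form: 1+2r and 1-r (twice)."""
        r = 0.4
        R = np.array([[1, r, r], [r, 1, r], [r, r, 1]])
        chol = np.linalg.cholesky(R)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 3)) @ chol.T
        pca = qscan.run_pca(qscan.VariableTable(
            [f"s{i}" for i in range(4000)], ["x", "y", "z"], X))
        assert pca.eigenvalues[0] == pytest.approx(1 + 2 * r, abs=0.06)
        assert pca.eigenvalues[1] == pytest.approx(1 - r, abs=0.06)

    def test_constant_column_named_in_error(self):
        t = qscan.VariableTable(["a", "b", "c"], ["x", "y"],
                                [[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="x"):
            qscan.run_pca(t)


class TestGMMCluster:
    def test_reference_table_selects_two_clusters(self, reference_clusters):
        res = reference_clusters
        assert res.k == 2
        assert sorted(res.sizes) == [5, 6]
        assert res.k == min(res.bic_by_k, key=res.bic_by_k.get)

    def test_reference_partition_membership(self, reference_clusters):
        low = set(reference_clusters.members(0))
        assert low == {"A", "D", "F", "G", "H"}

    def test_posteriors_rows_sum_to_one(self, reference_clusters):
        np.testing.assert_allclose(reference_clusters.posteriors.sum(axis=1),
                                   1.0, atol=1e-9)

    def test_labels_partition_all_subjects(self, table2, reference_clusters):
        assert set(reference_clusters.labels) == set(table2.subjects)

    def test_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, size=(20, 2))
        b = rng.normal(10.0, 1.0, size=(20, 2))
        S = np.vstack([a, b])
        res = qscan.gmm_cluster(S, restarts=5, seed=0)
        assert res.k == 2
        lab = np.array([res.labels[str(i)] for i in range(40)])
        assert len(set(lab[:20])) == 1 and len(set(lab[20:])) == 1
        assert lab[0] != lab[-1]

    def test_single_blob_selects_one_cluster(self):
        """Majority vote over 20 seeds on a single Gaussian blob (n=60)."""
        rng = np.random.default_rng(12)
        S = rng.normal(size=(60, 2))
        ks = [qscan.gmm_cluster(S, restarts=5, seed=s).k for s in range(20)]
        assert np.median(ks) == 1
        assert sum(k == 1 for k in ks) >= 14

    def test_bic_selection_stable_across_seeds(self, table2_pca):
        ks = [qscan.gmm_cluster(table2_pca, seed=s).k for s in range(10)]
        assert sum(k == 2 for k in ks) >= 8

    def test_k_candidates_validated(self, table2_pca):
        with pytest.raises(ValueError):
            qscan.gmm_cluster(table2_pca, k_candidates=range(1, 12))


class TestCheckDistinction:
    def test_reference_clusters_pass(self, table2_pca, reference_clusters):
        v = qscan.check_distinction(table2_pca, reference_clusters)
        assert v.pc1_separated and v.nonoverlapping_2d and v.nonoverlapping_3d
        assert v.distinct

    def test_mean_split_fails_pc1(self, table2, table2_pca):
        split = qscan.median_split(table2.as_mapping("mean"), "mean")
        labels = [1 if s in split.high_ids else 0 for s in table2.subjects]
        v = qscan.check_distinction(table2_pca, labels)
        assert not v.pc1_separated
        assert not v.distinct

    def test_amplitude_split_passes_pc1(self, table2, table2_pca):
        split = qscan.median_split(table2.as_mapping("amplitude"), "amplitude")
        labels = [1 if s in split.high_ids else 0 for s in table2.subjects]
        assert qscan.check_distinction(table2_pca, labels).pc1_separated

    def test_identical_point_sets_not_distinct(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        S = np.vstack([pts, pts])
        v = qscan.check_distinction(S, [0] * 6 + [1] * 6)
        assert not v.nonoverlapping_2d and not v.distinct

    def test_label_permutation_invariance(self, table2_pca, reference_clusters):
        lab = [reference_clusters.labels[s] for s in table2_pca.subjects]
        a = qscan.check_distinction(table2_pca, lab)
        b = qscan.check_distinction(table2_pca, [1 - l for l in lab])
        assert a == b

    def test_requires_two_clusters(self, table2_pca):
        with pytest.raises(ValueError):
            qscan.check_distinction(table2_pca, [0] * 11)


class TestConvexHulls:
    def test_separated_squares_disjoint(self):
        a = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        assert convex_hulls_disjoint(a, a + 5.0)

    def test_nested_sets_overlap(self):
        a = np.array([[0, 0], [4, 0], [0, 4], [4, 4]], dtype=float)
        b = np.array([[1, 1], [2, 2]], dtype=float)
        assert not convex_hulls_disjoint(a, b)

    def test_degenerate_single_points(self):
        assert convex_hulls_disjoint(np.array([[0.0, 0.0]]),
                                     np.array([[1.0, 1.0]]))
        assert not convex_hulls_disjoint(np.array([[1.0, 1.0]]),
                                         np.array([[1.0, 1.0]]))

    def test_three_dimensional_case(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.5, size=(5, 3))
        b = rng.normal(0, 0.5, size=(5, 3)) + [6, 0, 0]
        assert convex_hulls_disjoint(a, b)
        assert not convex_hulls_disjoint(a, np.vstack([a, b]))
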