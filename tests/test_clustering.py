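"""PCA, Ward-on-PCs clustering, cluster description and the DE stand-in."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from pdomics.clustering import (
    describe_clusters,
    differential_expression,
    hcpc_cluster,
    run_pca,
)
from pdomics.io import ExpressionMatrix
from pdomics.simulate import CohortConfig, simulate_pdo_cohort


def _matrix(values, metadata=None):
    g, s = values.shape
    return ExpressionMatrix(gene_ids=[f"g{i}" for i in range(g)],
                            sample_ids=[f"s{j}" for j in range(s)],
                            values=values, metadata=metadata or {})


class TestRunPca:
    def test_duplicate_samples_share_scores(self, rng):
        values = rng.normal(0, 1, size=(30, 6))
        values[:, 3] = values[:, 0]
        scores, _, _ = run_pca(_matrix(values), n_components=3)
        np.testing.assert_allclose(scores[3], scores[0], atol=1e-10)

    def test_rank_one_matrix_explained_by_first_component(self, rng):
        u = rng.normal(0, 1, size=30)
        v = rng.normal(0, 1, size=8)
        scores, evr, _ = run_pca(_matrix(np.outer(u, v)), n_components=3)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_from_all_components(self, rng):
        """Scores x loadings reproduce the per-gene-centred input (SVD identity)."""
        values = rng.normal(0, 2, size=(50, 20))
        m = _matrix(values)
        scores, _, loadings = run_pca(m, n_components=19)
        X = values.T
        centred = X - X.mean(axis=0)
        np.testing.assert_allclose(scores @ loadings, centred, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        _, _, loadings = run_pca(_matrix(rng.normal(0, 1, size=(40, 10))), 5)
        for comp in loadings:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_component_bound_enforced(self, rng):
        with pytest.raises(ValueError):
            run_pca(_matrix(rng.normal(size=(10, 5))), n_components=5)


class TestHcpcCluster:
    def test_two_separated_blobs_recovered(self, rng):
        """Two 10sigma-apart Gaussian blobs: suggested_k = 2, labels exact."""
        a = rng.normal(0, 1, size=(30, 10))
        b = rng.normal(10, 1, size=(30, 10))
        m = _matrix(np.hstack([a, b]))
        result = hcpc_cluster(m, ncp=5, descriptor_alpha=None)
        assert result.suggested_k == 2
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, result.labels) == 1.0

    def test_k_of_one_rejected(self, rng):
        m = _matrix(rng.normal(size=(10, 6)))
        with pytest.raises(ValueError):
            hcpc_cluster(m, k=1)

    def test_merge_heights_nondecreasing(self, rng):
        m = _matrix(rng.normal(size=(20, 12)))
        result = hcpc_cluster(m, descriptor_alpha=None)
        heights = result.merge_tree[:, 2]
        assert np.all(np.diff(heights) >= -1e-10)

    def test_invariant_to_sample_ordering(self, rng):
        matrix, truth = simulate_pdo_cohort(CohortConfig(
            n_genes=300, n_shared_deg=40, n_cd1_deg=30, n_cd2_deg=30, seed=5))
        base = hcpc_cluster(matrix, descriptor_alpha=None)
        perm = list(rng.permutation(matrix.sample_ids))
        shuffled = hcpc_cluster(matrix.subset_samples(perm), descriptor_alpha=None)
        lab_base = dict(zip(matrix.sample_ids, base.labels))
        lab_perm = dict(zip(perm, shuffled.labels))
        assert adjusted_rand_score([lab_base[s] for s in perm],
                                   [lab_perm[s] for s in perm]) == 1.0

    def test_three_group_cohort_recovery(self):
        """Default synthetic cohort: three clusters matching the planted groups."""
        matrix, truth = simulate_pdo_cohort(CohortConfig(seed=42))
        result = hcpc_cluster(matrix, descriptor_alpha=None)
        planted = [truth["labels"][s] for s in matrix.sample_ids]
        assert result.suggested_k == 3
        assert adjusted_rand_score(planted, result.labels) >= 0.9


class TestDescribeClusters:
    def test_constant_gene_never_a_descriptor(self, rng):
        values = rng.normal(0, 1, size=(5, 20))
        values[0] = 7.0
        m = _matrix(values)
        labels = np.array([1] * 10 + [2] * 10)
        desc = describe_clusters(m, labels)
        assert "g0" not in set(desc["variable"])

    def test_extreme_contrast_gene_described_with_direction(self, rng):
        values = rng.normal(0, 0.1, size=(5, 20))
        labels = np.array([1] * 10 + [2] * 10)
        values[2, :10] = 10.0
        values[2, 10:] = 0.0
        desc = describe_clusters(_matrix(values), labels)
        hit = desc[(desc["variable"] == "g2") & (desc["cluster"] == 1)]
        assert len(hit) == 1
        assert hit.iloc[0]["direction"] == "up"
        assert hit.iloc[0]["p"] < 0.05

    def test_chi_square_matches_contingency_formula(self):
        """2x2 table {8,2;1,9}: chi2 equals the direct sum over cells."""
        values = np.zeros((2, 20))
        labels = np.array([1] * 10 + [2] * 10)
        cats = np.array(["x"] * 8 + ["y"] * 2 + ["x"] * 1 + ["y"] * 9)
        metadata = {f"s{j}": {"clinical_subtype": cats[j]} for j in range(20)}
        m = _matrix(values, metadata=metadata)
        desc = describe_clusters(m, labels, categorical_fields=("clinical_subtype",))
        obs = np.array([[8, 2], [1, 9]])
        expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        chi2_hand = float(((obs - expected) ** 2 / expected).sum())
        row = desc[desc["variable"] == "clinical_subtype"].iloc[0]
        assert row["statistic"] == pytest.approx(chi2_hand, abs=1e-10)

    def test_singleton_cluster_skipped(self, rng):
        m = _matrix(rng.normal(size=(5, 6)))
        desc = describe_clusters(m, np.array([1, 1, 1, 1, 1, 2]))
        assert set(desc.get("cluster", [])) <= {1}

    def test_v_test_matches_direct_formula(self, rng):
        values = rng.normal(0, 1, size=(30, 16))
        labels = np.array([1] * 8 + [2] * 8)
        m = _matrix(values)
        desc = describe_clusters(m, labels, alpha=1.0)
        N, n_c = 16, 8
        for _, row in desc[desc["kind"] == "gene"].head(20).iterrows():
            i = m.gene_ids.index(row["variable"])
            mask = labels == row["cluster"]
            v_ref = (values[i, mask].mean() - values[i].mean()) / np.sqrt(
                values[i].var() / n_c * (N - n_c) / (N - 1))
            assert row["statistic"] == pytest.approx(v_ref, abs=1e-10)


class TestDifferentialExpression:
    def test_label_swap_negates_fold_changes(self, rng):
        matrix, _ = simulate_pdo_cohort(CohortConfig(
            n_genes=200, n_shared_deg=30, n_cd1_deg=20, n_cd2_deg=20, seed=2))
        a = matrix.sample_ids[:10]
        b = matrix.sample_ids[10:22]
        ab = differential_expression(matrix, a, b, lfc_min=0, fdr_max=1.0)
        ba = differential_expression(matrix, b, a, lfc_min=0, fdr_max=1.0)
        merged = ab.set_index("gene_id")["log2fc"] + ba.set_index("gene_id")["log2fc"]
        assert np.allclose(merged.to_numpy(), 0.0, atol=1e-12)

    def test_bh_adjustment_monotone(self, rng):
        matrix, _ = simulate_pdo_cohort(CohortConfig(
            n_genes=300, n_shared_deg=50, n_cd1_deg=0, n_cd2_deg=0, seed=9))
        groups = matrix.labels("group")
        cd = [s for s, g in zip(matrix.sample_ids, groups) if g == "CD"]
        healthy = [s for s, g in zip(matrix.sample_ids, groups) if g == "healthy"]
        de = differential_expression(matrix, cd, healthy, lfc_min=0, fdr_max=1.0)
        order = de.sort_values("p")
        assert (order["padj"].diff().dropna() >= -1e-12).all()
        assert (de["padj"] >= de["p"] - 1e-15).all()

    def test_planted_degs_recovered(self):
        """+2 log2 shift in 100/1000 genes, n = 10 vs 10: recall >= 0.9 at FDR 0.05."""
        cfg = CohortConfig(n_healthy=10, n_cd1=10, n_cd2=1, n_genes=1000,
                           n_shared_deg=0, n_cd1_deg=100, n_cd2_deg=0,
                           effect=2.0, sigma=0.5, seed=13)
        matrix, truth = simulate_pdo_cohort(cfg)
        cd1 = [s for s in matrix.sample_ids if s.startswith("CD1")]
        healthy = [s for s in matrix.sample_ids if s.startswith("H")]
        de = differential_expression(matrix, cd1, healthy, lfc_min=1.0, fdr_max=0.05)
        planted = set(truth["deg_cd1"])
        recall = len(planted & set(de["gene_id"])) / len(planted)
        assert recall >= 0.9

    def test_small_groups_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            differential_expression(small_matrix, small_matrix.sample_ids[:2],
                                    small_matrix.sample_ids[2:])
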