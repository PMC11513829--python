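"""Threshold-centred normalization, composite scores, ROC-AUC and Welch tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pdomics.io import ExpressionMatrix, GeneSignature
from pdomics.scoring import (
    benchmark_signature,
    compare_groups,
    composite_score,
    evaluate_auc,
    normalize_expression,
)
from pdomics.simulate import TissueConfig, simulate_tissue_cohort
from pdomics.stepminer import GeneThreshold, derive_thresholds


def _thr(gene, sthr, sd):
    return GeneThreshold(gene_id=gene, sthr=sthr, stddev=sd)


class TestNormalizeExpression:
    def test_threshold_maps_to_zero_and_three_sd_to_one(self):
        """(expr - SThr)/(3*stddev): 0 at the threshold, 1 at +3 SD."""
        m = ExpressionMatrix(gene_ids=["g"], sample_ids=["a", "b"],
                             values=[[5.0, 5.0 + 3 * 1.5]])
        out = normalize_expression(m, {"g": _thr("g", 5.0, 1.5)})
        assert out.loc["g", "a"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["g", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_on_random_matrix(self, rng):
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{j}" for j in range(10)]
        values = rng.normal(0, 3, size=(20, 10))
        m = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)
        thr = {g: _thr(g, float(rng.normal()), float(rng.uniform(0.5, 2)))
               for g in genes}
        out = normalize_expression(m, thr)
        for i, g in enumerate(genes):
            expected = (values[i] - thr[g].sthr) / (3 * thr[g].stddev)
            np.testing.assert_allclose(out.loc[g].to_numpy(), expected, atol=1e-12)

    def test_zero_stddev_gene_dropped(self):
        m = ExpressionMatrix(gene_ids=["g", "h"], sample_ids=["a", "b"],
                             values=[[1.0, 2.0], [3.0, 4.0]])
        out = normalize_expression(m, {"g": _thr("g", 1.0, 0.0),
                                       "h": _thr("h", 3.0, 1.0)})
        assert list(out.index) == ["h"]


class TestCompositeScore:
    def _normalized(self):
        m = ExpressionMatrix(gene_ids=["u1", "u2", "d1"], sample_ids=["s"],
                             values=[[0.5], [0.3], [0.2]])
        thr = {g: _thr(g, 0.0, 1 / 3) for g in m.gene_ids}  # identity normalization
        return normalize_expression(m, thr)

    def test_up_genes_sum(self):
        norm = self._normalized()
        sig = GeneSignature(name="s", up_genes=frozenset({"u1", "u2"}))
        assert composite_score(norm, sig).score[0] == pytest.approx(0.8)

    def test_down_genes_subtract(self):
        norm = self._normalized()
        sig = GeneSignature(name="s", up_genes=frozenset({"u1"}),
                            down_genes=frozenset({"d1"}))
        assert composite_score(norm, sig).score[0] == pytest.approx(0.3)

    def test_swapping_up_to_down_negates_contribution(self):
        norm = self._normalized()
        up = composite_score(norm, GeneSignature("a", frozenset({"u1", "d1"}))).score[0]
        swapped = composite_score(
            norm, GeneSignature("b", frozenset({"u1"}), frozenset({"d1"}))).score[0]
        assert up - swapped == pytest.approx(2 * 0.2)

    def test_linear_in_disjoint_signatures(self, rng):
        genes = [f"g{i}" for i in range(10)]
        m = ExpressionMatrix(gene_ids=genes, sample_ids=["x", "y"],
                             values=rng.normal(0, 1, size=(10, 2)))
        thr = {g: _thr(g, 0.0, 1.0) for g in genes}
        norm = normalize_expression(m, thr)
        sig_a = GeneSignature("a", frozenset(genes[:4]))
        sig_b = GeneSignature("b", frozenset(genes[4:7]))
        sig_ab = GeneSignature("ab", frozenset(genes[:7]))
        total = composite_score(norm, sig_ab).score
        parts = composite_score(norm, sig_a).score + composite_score(norm, sig_b).score
        np.testing.assert_allclose(total, parts, atol=1e-12)

    def test_missing_genes_recorded_and_empty_signature_fails(self):
        norm = self._normalized()
        table = composite_score(norm, GeneSignature("s", frozenset({"u1", "ghost"})))
        assert table.genes_missing == ["ghost"]
        with pytest.raises(ValueError):
            composite_score(norm, GeneSignature("s", frozenset({"ghost"})))


class TestEvaluateAuc:
    def test_perfect_separation(self):
        assert evaluate_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert evaluate_auc([2, 2, 2, 2], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auc([1, 2], [1, 1])

    def test_matches_pairwise_concordance_for_all_labelings(self, rng):
        """Every labeling of up to 8 samples agrees with the exhaustive count."""
        for n in (4, 6, 8):
            scores = rng.normal(0, 1, size=n)
            scores[rng.integers(0, n)] = scores[0]  # plant a tie
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    pos = [s for s, y in zip(scores, labels) if y]
                    neg = [s for s, y in zip(scores, labels) if not y]
                    conc = sum(1.0 if p > q else (0.5 if p == q else 0.0)
                               for p in pos for q in neg)
                    expected = conc / (len(pos) * len(neg))
                    assert evaluate_auc(scores, labels) == pytest.approx(expected,
                                                                         abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(0, 1, size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        base = evaluate_auc(scores, labels)
        assert evaluate_auc(np.exp(scores), labels) == pytest.approx(base)
        assert evaluate_auc(3 * scores - 7, labels) == pytest.approx(base)

    def test_label_flip_maps_auc_to_complement(self, rng):
        scores = rng.normal(0, 1, size=20)
        labels = np.array([0, 1] * 10)
        assert evaluate_auc(scores, 1 - labels) == pytest.approx(
            1 - evaluate_auc(scores, labels))


class TestCompareGroups:
    def test_identical_constant_groups(self):
        t, p = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_extreme_separation(self):
        _, p = compare_groups([0, 0, 0], [10, 10, 10.0001])
        assert p < 0.01

    def test_matches_welch_satterthwaite_formula(self, rng):
        """200 random pairs agree with the direct Welch formula within 1e-8."""
        for _ in range(200):
            a = rng.normal(0, rng.uniform(0.5, 3), size=int(rng.integers(3, 15)))
            b = rng.normal(rng.normal(), rng.uniform(0.5, 3),
                           size=int(rng.integers(3, 15)))
            t, p = compare_groups(a, b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se2 = va / a.size + vb / b.size
            t_ref = (a.mean() - b.mean()) / np.sqrt(se2)
            df = se2**2 / (va**2 / (a.size**2 * (a.size - 1))
                           + vb**2 / (b.size**2 * (b.size - 1)))
            p_ref = 2 * stats.t.sf(abs(t_ref), df)
            assert t == pytest.approx(t_ref, abs=1e-8)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestBenchmarkSignature:
    def test_planted_induction_recovered_only_in_active(self):
        """Signature induced only in active tissue: high active AUC, null inactive."""
        tissue, _, sig = simulate_tissue_cohort(TissueConfig(seed=7))
        table, _ = benchmark_signature(sig, tissue)
        by = table.set_index("contrast")
        assert by.loc["active_vs_control", "auc"] >= 0.9
        assert 0.4 <= by.loc["inactive_vs_control", "auc"] <= 0.6
        assert by.loc["active_vs_control", "p"] < 0.01

    def test_shuffled_activity_labels_give_null_auc(self, rng):
        """Permuting activity labels destroys the association: the mean AUC
        over shuffles sits at 0.5 (single-shuffle AUC has sd ~0.11 at n=30)."""
        tissue, _, sig = simulate_tissue_cohort(
            TissueConfig(n_control=15, n_inactive=0, n_active=15, seed=11))
        thr = derive_thresholds(tissue)
        score = composite_score(normalize_expression(tissue, thr), sig).score
        labels = np.array([tissue.metadata[s]["activity"] for s in tissue.sample_ids])
        aucs = []
        for _ in range(20):
            shuffled = rng.permutation(labels)
            aucs.append(evaluate_auc(score, shuffled == "active"))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_missing_activity_label_is_metadata_error(self):
        tissue, _, sig = simulate_tissue_cohort(TissueConfig(seed=3))
        tissue.metadata[tissue.sample_ids[0]]["activity"] = "none"
        with pytest.raises(ValueError, match="activity"):
            benchmark_signature(sig, tissue)
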