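"""Molecular-subtype discovery: PCA, Ward clustering on retained PCs, cluster
description, and a simple Welch-based differential-expression routine.

The clustering follows the hierarchical-clustering-on-principal-components
(HCPC) recipe: per-gene centring (no unit scaling), singular-value
decomposition, Ward agglomeration on Euclidean distances in the retained-PC
space, and an automatic cluster-count suggestion that maximizes the relative
loss of within-cluster inertia between successive cuts of the tree.  Cluster
description mirrors the catdes convention: a v-test for quantitative
variables (genes) and a chi-square association test for categorical
metadata, both reported at a significance threshold alpha.

The differential-expression routine is a deliberately simple stand-in for
count-based tools (it is NOT DESeq2): per-gene Welch t-tests on the
log-scale values with Benjamini-Hochberg adjustment.  Externally computed
DEG tables in the same column schema can be used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from pdomics.io import ExpressionMatrix
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    """Retained PC scores, Ward merge tree, labels and per-cluster descriptors."""

    sample_ids: list[str]
    pc_scores: np.ndarray            # samples x retained components
    explained_variance: np.ndarray   # fraction per component, nonincreasing
    merge_tree: np.ndarray           # scipy linkage matrix (node1, node2, height, size)
    labels: np.ndarray               # cluster id (1..k) per sample
    suggested_k: int
    k: int
    descriptors: pd.DataFrame | None = None

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})


def run_pca(matrix: ExpressionMatrix, n_components: int):
    """PCA of samples on per-gene-centred expression (no unit scaling).

    Samples are the observations, genes the variables.  Component signs are
    fixed by making each component's largest-magnitude gene loading positive,
    so results are reproducible across SVD implementations.

    Returns ``(pc_scores, explained_variance_fraction, loadings)`` with
    ``pc_scores`` of shape (n_samples, n_components).
    """
    n_max = min(matrix.n_genes, matrix.n_samples - 1)
    if matrix.n_samples < 3:
        raise ValueError("run_pca needs at least 3 samples")
    if not (1 <= n_components <= n_max):
        raise ValueError(f"n_components must be in [1, {n_max}], got {n_components}")
    X = matrix.values.T  # samples x genes; PCA centres each gene across samples
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_  # components x genes
    for j in range(n_components):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    return scores, pca.explained_variance_ratio_.copy(), loadings


def _within_inertia(points: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        sub = points[labels == c]
        total += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    return total


def suggest_k(points: np.ndarray, tree: np.ndarray, k_max: int | None = None) -> int:
    """Cluster count maximizing the relative within-inertia loss between cuts.

    For k in [2, min(10, n-1)] the tree is cut at k-1 and k clusters and the
    relative loss (W(k-1) - W(k)) / W(k-1) computed; the k with the largest
    loss is suggested.  This stands in for visual dendrogram inspection.
    """
    n = points.shape[0]
    k_hi = min(10, n - 1) if k_max is None else min(k_max, n - 1)
    best_k, best_gain = 2, -np.inf
    w_prev = _within_inertia(points, np.ones(n, dtype=int))
    for k in range(2, k_hi + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        w = _within_inertia(points, labels)
        gain = (w_prev - w) / w_prev if w_prev > 0 else 0.0
        if gain > best_gain:
            best_k, best_gain = k, gain
        w_prev = w
    return best_k


def hcpc_cluster(matrix: ExpressionMatrix, ncp: int = 5, k: int | None = None,
                 descriptor_alpha: float | None = 0.05) -> ClusteringResult:
    """Ward clustering of samples in the retained principal-component space.

    Parameters
    ----------
    matrix : ExpressionMatrix
    ncp : int
        Number of principal components retained before clustering (capped at
        what the data support).
    k : int, optional
        Cluster count override (must be >= 2).  When absent the count is
        suggested automatically from the inertia profile of the tree.
    descriptor_alpha : float, optional
        Significance threshold for cluster description; ``None`` skips it.
    """
    if matrix.n_samples < 3:
        raise ValueError("clustering needs at least 3 samples")
    if k is not None and not (2 <= k <= matrix.n_samples):
        raise ValueError(f"k must lie in [2, {matrix.n_samples}]")
    ncp_eff = min(ncp, matrix.n_samples - 1, matrix.n_genes)
    scores, evr, _ = run_pca(matrix, ncp_eff)
    tree = linkage(scores, method="ward")
    suggested = suggest_k(scores, tree)
    k_eff = k if k is not None else suggested
    labels = fcluster(tree, t=k_eff, criterion="maxclust")
    result = ClusteringResult(
        sample_ids=list(matrix.sample_ids),
        pc_scores=scores,
        explained_variance=evr,
        merge_tree=tree,
        labels=labels,
        suggested_k=suggested,
        k=k_eff,
    )
    if descriptor_alpha is not None:
        result.descriptors = describe_clusters(matrix, labels, alpha=descriptor_alpha)
    return result


def describe_clusters(matrix: ExpressionMatrix, labels, alpha: float = 0.05,
                      categorical_fields: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-cluster descriptors in the catdes style.

    Quantitative (gene) descriptors use the v-test: the standardized
    difference between the cluster mean and the overall mean,

        v = (mean_c - mean) / sqrt( s^2 / n_c * (N - n_c) / (N - 1) )

    with a two-sided normal p-value, reported when p < alpha.  Categorical
    metadata fields are described by a chi-square test of association
    (no continuity correction) between cluster membership and the category.
    Clusters of size 1 are skipped with a warning.  Output is sorted by
    descending |statistic| within each cluster.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("describe_clusters needs at least 2 clusters")
    N = labels.size
    rows = []

    values = matrix.values  # genes x samples
    overall_mean = values.mean(axis=1)
    # population variance (N denominator), per the v-test's finite-population form
    overall_var = values.var(axis=1)
    for c in clusters:
        mask = labels == c
        n_c = int(mask.sum())
        if n_c < 2:
            logger.warning("describe_clusters: cluster %s has a single sample; skipped", c)
            continue
        cluster_mean = values[:, mask].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(overall_var / n_c * (N - n_c) / (N - 1))
            v = np.where(se > 0, (cluster_mean - overall_mean) / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(v))
        sig = (p < alpha) & (se > 0)
        for i in np.nonzero(sig)[0]:
            rows.append({
                "cluster": c,
                "variable": matrix.gene_ids[i],
                "kind": "gene",
                "statistic": float(v[i]),
                "p": float(p[i]),
                "direction": "up" if v[i] > 0 else "down",
            })

    for field_name in categorical_fields:
        cats = matrix.labels(field_name)
        table = pd.crosstab(labels, cats)
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        if p < alpha:
            rows.append({
                "cluster": "all",
                "variable": field_name,
                "kind": "categorical",
                "statistic": float(chi2),
                "p": float(p),
                "direction": "association",
            })

    df = pd.DataFrame(rows, columns=["cluster", "variable", "kind", "statistic",
                                     "p", "direction"])
    if not df.empty:
        df = df.reindex(df["statistic"].abs().sort_values(ascending=False).index)
        df = df.sort_values("cluster", kind="stable").reset_index(drop=True)
    return df


def differential_expression(matrix: ExpressionMatrix, group_a, group_b,
                            lfc_min: float = 1.0, fdr_max: float = 0.05) -> pd.DataFrame:
    """Welch t + Benjamini-Hochberg differential expression on log-scale values.

    ``group_a``/``group_b`` are sample-id lists; log2 fold change is
    mean(a) - mean(b) on the already-log2 expression scale.  Genes pass when
    |log2FC| >= lfc_min and BH-adjusted p <= fdr_max; output is sorted by
    adjusted p.  This is a documented simple stand-in, not DESeq2.
    """
    ia = [matrix.sample_ids.index(s) for s in group_a]
    ib = [matrix.sample_ids.index(s) for s in group_b]
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("differential_expression: each group needs n >= 3")
    A = matrix.values[:, ia]
    B = matrix.values[:, ib]
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    lfc = A.mean(axis=1) - B.mean(axis=1)
    # genes constant in both groups carry no test: p = 1, t = 0
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    _, padj, _, _ = multipletests(p, method="fdr_bh")

    df = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "log2fc": lfc,
        "statistic": t,
        "p": p,
        "padj": padj,
        "direction": np.where(lfc >= 0, "up", "down"),
    })
    df = df[(df["log2fc"].abs() >= lfc_min) & (df["padj"] <= fdr_max)]
    return df.sort_values(["padj", "p", "gene_id"], kind="stable").reset_index(drop=True)


def write_clustering(result: ClusteringResult, outdir) -> None:
    """Export labels, linkage table, PC scores and descriptors as TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.labels_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False)
    pd.DataFrame(result.merge_tree,
                 columns=["node1", "node2", "height", "size"]).to_csv(
        outdir / "merge_tree.tsv", sep="\t", index=False, float_format="%.10g")
    pcs = pd.DataFrame(result.pc_scores, index=result.sample_ids,
                       columns=[f"PC{i+1}" for i in range(result.pc_scores.shape[1])])
    pcs.index.name = "sample_id"
    pcs.to_csv(outdir / "pc_scores.tsv", sep="\t", float_format="%.10g")
    if result.descriptors is not None:
        result.descriptors.to_csv(outdir / "cluster_descriptors.tsv", sep="\t",
                                  index=False, float_format="%.10g")
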