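"""Composite gene-signature scoring and group-separation statistics.

Expression is first normalized per gene by a modified Z score centred on the
StepMiner threshold, (expr - SThr) / (3 * stddev), then the normalized values
of the signature's genes are summed per sample (down-genes subtract) to give
the composite score.  Sample orderings induced by the score are evaluated by
rank-based ROC-AUC and group differences by Welch's unequal-variance t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pdomics.io import ExpressionMatrix, GeneSignature
from pdomics.stepminer import DEFAULT_DF, GeneThreshold, derive_thresholds

logger = logging.getLogger(__name__)


@dataclass
class SignatureScoreTable:
    """Per-sample composite scores for one signature."""

    signature_name: str
    sample_ids: list[str]
    score: np.ndarray
    genes_used: int
    genes_missing: list[str] = field(default_factory=list)
    genes_degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if not np.all(np.isfinite(self.score)):
            raise ValueError("non-finite composite score")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "score": self.score})

    def ordered_samples(self) -> list[str]:
        """Sample ids sorted by ascending composite score."""
        order = np.argsort(self.score, kind="stable")
        return [self.sample_ids[i] for i in order]


def normalize_expression(matrix: ExpressionMatrix,
                         thresholds: dict[str, GeneThreshold]) -> pd.DataFrame:
    """Threshold-centred modified Z score: (expr - sthr) / (3 * stddev) per gene.

    Genes with zero standard deviation cannot be normalized; they are dropped
    from the output with a logged warning (callers list them as unusable).
    """
    rows, index, dropped = [], [], []
    for i, gene in enumerate(matrix.gene_ids):
        thr = thresholds.get(gene)
        if thr is None:
            dropped.append(gene)
            continue
        if thr.stddev == 0.0 or thr.degenerate:
            dropped.append(gene)
            continue
        rows.append((matrix.values[i] - thr.sthr) / (3.0 * thr.stddev))
        index.append(gene)
    if dropped:
        logger.warning("normalize_expression: dropped %d gene(s) without usable "
                       "threshold/stddev: %s", len(dropped), dropped[:5])
    return pd.DataFrame(np.array(rows).reshape(len(index), matrix.n_samples),
                        index=index, columns=matrix.sample_ids)


def composite_score(normalized: pd.DataFrame, signature: GeneSignature,
                    down_weight: float = -1.0) -> SignatureScoreTable:
    """Sum normalized values over the signature's genes per sample.

    Up-genes add with weight +1; down-genes with ``down_weight`` (default -1,
    so they subtract).  Signature genes absent from the normalized matrix are
    recorded in ``genes_missing``; if no usable gene remains an error is
    raised.
    """
    up = sorted(signature.up_genes & set(normalized.index))
    down = sorted(signature.down_genes & set(normalized.index))
    missing = sorted(signature.genes - set(normalized.index))
    if not up and not down:
        raise ValueError(
            f"signature {signature.name!r}: none of its {len(signature)} genes "
            "are usable in this matrix"
        )
    score = np.zeros(normalized.shape[1])
    if up:
        score = score + normalized.loc[up].to_numpy().sum(axis=0)
    if down:
        score = score + down_weight * normalized.loc[down].to_numpy().sum(axis=0)
    return SignatureScoreTable(
        signature_name=signature.name,
        sample_ids=list(normalized.columns),
        score=score,
        genes_used=len(up) + len(down),
        genes_missing=missing,
    )


def evaluate_auc(scores, labels) -> float:
    """Rank-based ROC-AUC of scores against binary labels.

    Equals the fraction of (positive, negative) sample pairs in which the
    positive sample scores higher, ties counted 1/2 (the Mann-Whitney U
    formulation).  Raises if either class is empty.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be nonempty")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compare_groups(scores_a, scores_b):
    """Welch's two-sample t-test (unpaired, unequal variance), two-sided.

    Returns ``(statistic, p_value)``.  Each group needs n >= 2; two groups
    that are both constant *and* identical return (0.0, 1.0) by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_groups: each group needs at least 2 samples")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("compare_groups: both groups have zero variance "
                         "(Welch statistic undefined)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def benchmark_signature(signature: GeneSignature, tissue: ExpressionMatrix,
                        m: int = DEFAULT_DF,
                        control_labels: tuple[str, ...] = ("healthy", "control")):
    """Evaluate a signature on a tissue cohort with disease-activity labels.

    Thresholds and normalization are recomputed on the tissue matrix itself
    (cross-platform composite scores are otherwise not comparable).  For each
    contrast — active vs control and inactive vs control — the ROC-AUC of the
    composite score and Welch's two-sided p are reported.  A signature truly
    specific to disease activity scores high on the first contrast and near
    0.5 on the second.
    """
    activity = tissue.labels("activity")
    if np.any(activity == "none"):
        bad = [s for s, a in zip(tissue.sample_ids, activity) if a == "none"]
        raise ValueError(f"missing activity label for sample(s): {bad[:5]}")

    thresholds = derive_thresholds(tissue, m=m)
    normalized = normalize_expression(tissue, thresholds)
    table = composite_score(normalized, signature)

    is_control = np.isin(activity, control_labels)
    rows = []
    for contrast in ("active", "inactive"):
        mask = activity == contrast
        if mask.sum() == 0 or is_control.sum() == 0:
            raise ValueError(f"contrast {contrast} vs control: empty group")
        sel = mask | is_control
        auc = evaluate_auc(table.score[sel], mask[sel])
        t, p = compare_groups(table.score[mask], table.score[is_control])
        rows.append({
            "contrast": f"{contrast}_vs_control",
            "n_case": int(mask.sum()),
            "n_control": int(is_control.sum()),
            "auc": auc,
            "welch_t": t,
            "p": p,
        })
    return pd.DataFrame(rows), table
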