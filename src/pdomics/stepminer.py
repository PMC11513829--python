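"""One-step function fitting and expression binarization (StepMiner).

For an ordered series X_1..X_n the algorithm evaluates every split position
k (1 <= k <= n-1), fits the two segment means, and keeps the split that
minimizes the squared error.  The fit is scored by an adaptive-regression
F-statistic

    F = [ sum_i (Xhat_i - Xbar)^2 / (m - 1) ] / [ sum_i (X_i - Xhat_i)^2 / (n - m) ]

where Xhat_i are the fitted segment means, Xbar the grand mean, and m the
regression degrees of freedom (default 3: two segment means plus one
transition).  Applied to a gene's expression values sorted ascending, the
midpoint of the two segment means defines the gene's high/low threshold
(SThr) used for binarization and for threshold-centred normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pdomics.io import ExpressionMatrix

DEFAULT_DF = 3  # two segment means + one transition; configurable everywhere

# small tolerance for "sse_fit is exactly zero" in float arithmetic
_ZERO_SSE = 1e-12


@dataclass(frozen=True)
class StepFitResult:
    """Best one-step fit of an ordered series.

    ``k`` is the size of the left segment (1 <= k <= n-1); ties in squared
    error resolve to the smallest k.  ``fstat`` is ``math.inf`` when the fit
    is perfect (sse_fit = 0 with sse_null > 0) and 0 for a constant series.
    """

    n: int
    k: int
    mu_left: float
    mu_right: float
    direction: str  # "up" | "down" | "none"
    sse_fit: float
    sse_null: float
    fstat: float
    m: int

    @property
    def sthr(self) -> float:
        """Derived threshold: midpoint of the two segment means."""
        return 0.5 * (self.mu_left + self.mu_right)


@dataclass(frozen=True)
class GeneThreshold:
    """Per-gene binarization threshold with the gene's sample standard deviation."""

    gene_id: str
    sthr: float
    stddev: float
    margin: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.stddev < 0:
            raise ValueError("stddev must be nonnegative")
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")


def fit_step(series, m: int = DEFAULT_DF) -> StepFitResult:
    """Fit the best one-step function to an ordered series.

    Parameters
    ----------
    series : array-like of float, length n >= 2
        Values in their given order (sort beforehand for order-free use).
    m : int
        Degrees of freedom of the adaptive regression, 1 < m < n.

    Returns
    -------
    StepFitResult
        Split index, segment means, squared errors and F-statistic.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("fit_step needs at least 2 values")
    if not (1 < m < n):
        raise ValueError(f"degrees of freedom m={m} must satisfy 1 < m < n={n}")

    total = x.sum()
    grand_mean = total / n
    sse_null = float(np.sum((x - grand_mean) ** 2))

    # SSE(k) = sum(x^2) - k*muL^2 - (n-k)*muR^2, via prefix sums
    ks = np.arange(1, n)
    csum = np.cumsum(x)[:-1]
    mu_left = csum / ks
    mu_right = (total - csum) / (n - ks)
    ssq = float(np.sum(x**2))
    sse = ssq - ks * mu_left**2 - (n - ks) * mu_right**2
    sse = np.maximum(sse, 0.0)  # guard tiny negative rounding

    best = int(np.argmin(sse))  # argmin returns first minimum: smallest k wins ties
    k = int(ks[best])
    muL, muR = float(mu_left[best]), float(mu_right[best])
    sse_fit = float(sse[best])

    if sse_null <= _ZERO_SSE:
        # constant series: no step, F defined as 0
        return StepFitResult(
            n=n, k=k, mu_left=muL, mu_right=muR, direction="none",
            sse_fit=0.0, sse_null=0.0, fstat=0.0, m=m,
        )

    explained = sse_null - sse_fit  # = sum (Xhat - Xbar)^2
    if sse_fit <= _ZERO_SSE:
        fstat = math.inf
        sse_fit = 0.0
    else:
        fstat = (explained / (m - 1)) / (sse_fit / (n - m))
    direction = "up" if muR > muL else ("down" if muR < muL else "none")
    return StepFitResult(
        n=n, k=k, mu_left=muL, mu_right=muR, direction=direction,
        sse_fit=sse_fit, sse_null=sse_null, fstat=float(fstat), m=m,
    )


def derive_threshold(gene_values, gene_id: str = "", m: int = DEFAULT_DF,
                     margin: float = 0.0) -> GeneThreshold:
    """Derive a gene's high/low threshold from its expression values.

    Values are sorted ascending, the step fit applied, and the threshold set
    to the midpoint of the two segment means.  ``stddev`` is the sample
    standard deviation (n-1 denominator) of the *unsorted* values.  A
    zero-variance gene is flagged degenerate with sthr equal to the common
    value.
    """
    x = np.asarray(gene_values, dtype=float)
    if x.size < 3:
        raise ValueError("derive_threshold needs at least 3 samples")
    stddev = float(np.std(x, ddof=1))
    if stddev == 0.0:
        return GeneThreshold(gene_id=gene_id, sthr=float(x[0]), stddev=0.0,
                             margin=margin, degenerate=True)
    fit = fit_step(np.sort(x), m=m)
    return GeneThreshold(gene_id=gene_id, sthr=fit.sthr, stddev=stddev,
                         margin=margin, degenerate=False)


def derive_thresholds(matrix: ExpressionMatrix, m: int = DEFAULT_DF,
                      margin: float = 0.0) -> dict[str, GeneThreshold]:
    """Per-gene thresholds for every gene of an expression matrix."""
    return {
        gene: derive_threshold(matrix.values[i], gene_id=gene, m=m, margin=margin)
        for i, gene in enumerate(matrix.gene_ids)
    }


HIGH, LOW, INTERMEDIATE = 1, 0, 2


def binarize(matrix: ExpressionMatrix, thresholds: dict[str, GeneThreshold]) -> pd.DataFrame:
    """Code expression as high (1) / low (0) / intermediate (2) per gene.

    value > sthr + margin -> 1; value <= sthr - margin -> 0; otherwise 2.
    With the default margin 0 the output is strictly binary and an exact tie
    at the threshold codes low.  A gene without a threshold raises KeyError.
    """
    missing = [g for g in matrix.gene_ids if g not in thresholds]
    if missing:
        raise KeyError(f"no threshold for gene(s): {missing[:5]}")
    out = np.empty(matrix.values.shape, dtype=int)
    for i, gene in enumerate(matrix.gene_ids):
        thr = thresholds[gene]
        v = matrix.values[i]
        high = v > thr.sthr + thr.margin
        low = v <= thr.sthr - thr.margin
        out[i] = np.where(high, HIGH, np.where(low, LOW, INTERMEDIATE))
    return pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids)


def write_thresholds(thresholds: dict[str, GeneThreshold], path) -> None:
    """Export thresholds as TSV: gene_id, sthr, stddev, degenerate."""
    rows = [
        {"gene_id": t.gene_id, "sthr": t.sthr, "stddev": t.stddev,
         "degenerate": int(t.degenerate)}
        for t in thresholds.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_thresholds(path, margin: float = 0.0) -> dict[str, GeneThreshold]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.gene_id): GeneThreshold(
            gene_id=str(r.gene_id), sthr=float(r.sthr), stddev=float(r.stddev),
            margin=margin, degenerate=bool(r.degenerate),
        )
        for r in df.itertuples()
    }
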