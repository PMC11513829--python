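# Methods

## Expression scale and I/O

All analyses operate on a log2(TPM)-like scale: raw TPM is mapped to
log2(TPM) when TPM > 1 and to TPM − 1 otherwise. Both branches meet at 0
when TPM = 1, so the transform is continuous and monotone; values below
−1 cannot occur. The raw-TPM matrix is not retained — every downstream
stage consumes transformed values only. Matrices are genes-in-rows TSV;
gene sets are standard GMT; per-sample metadata is a TSV keyed by
`sample_id` whose missing fields default to `"none"` so partial cohorts
load. Genes that are identically zero are kept at load time; variance-based
exclusions happen downstream (threshold derivation flags zero-variance
genes as degenerate, normalization drops them).

## Step-function fitting and binarization

For an ordered series X₁…Xₙ (n ≥ 2), every split position k ∈ [1, n−1] is
evaluated; fitted values are the two segment means and the split minimizing
the residual sum of squares is kept, ties resolving to the smallest k for
determinism. The F-statistic divides the explained mean square
Σ(X̂ᵢ − X̄)²/(m−1) by the residual mean square Σ(Xᵢ − X̂ᵢ)²/(n−m).

* **m (degrees of freedom), default 3** — two segment means plus one
  transition. This is a package choice (the statistic's definition does not
  fix a number); it is configurable everywhere the fit is used.
* A perfect fit (zero residual with nonzero total variance) reports
  F = +∞, serialized as `inf`; a constant series reports F = 0 with no
  step direction. Residual SSEs below 10⁻¹² are treated as exact zeros to
  keep the infinity sentinel stable under float rounding.

For binarization the per-gene values are sorted ascending before fitting —
sample order is meaningless across a cohort, and sorting makes the
threshold order-free. The threshold is the midpoint of the two segment
means; the gene's sample standard deviation (n−1 denominator, computed on
the unsorted values) accompanies it. Coding: value > SThr + margin → high
(1); value ≤ SThr − margin → low (0); otherwise intermediate (2). The
margin defaults to 0, which makes the output strictly binary with exact
ties at the threshold coded low; a nonzero margin reproduces the
three-level convention used in step-fitting literature but is opt-in.

## Composite signature scores

Per gene, normalized expression is (expr − SThr)/(3·stddev) — zero at the
threshold, one at three standard deviations above it. Genes with zero
standard deviation are excluded with a warning; signature genes absent from
the matrix are recorded, not imputed. The composite score sums normalized
values over the signature's up-genes and subtracts down-genes (the down
weight, default −1, is configurable; a signature with only up-genes is just
a sum). The score is linear in disjoint signatures and each gene's
contribution negates exactly when moved between the up and down sets.

ROC-AUC uses the rank (Mann-Whitney) formulation — the fraction of
(positive, negative) pairs ranked concordantly, ties counted ½ — so it is
invariant under any strictly monotone transform of the score. Group
comparisons use Welch's unequal-variance two-sided t-test.

**Tissue benchmarking** recomputes thresholds and normalization on the
tissue dataset being scored: thresholds derived on one platform are not
transferable, and scores are only comparable within the cohort that
produced their normalization. The benchmark reports AUC and Welch p for
active-vs-control and inactive-vs-control; activity-specific biology shows
up as a high first AUC with a chance-level second.

## Subtype discovery

Samples are decomposed by PCA on per-gene-centred expression. Genes are
centred but not unit-scaled — scaling to unit variance would equalize noise
genes with the high-variance genes that carry the subtype signal, and
centring-only matches common bulk practice. Component signs are fixed by
making each component's largest-magnitude loading positive so runs are
reproducible across SVD implementations.

Ward agglomeration runs on Euclidean distances in the retained-PC space
(**ncp, default 5**, capped by the data's rank). When no cluster count is
given, the suggestion maximizes the relative loss of within-cluster inertia
(W(k−1) − W(k))/W(k−1) over k ∈ [2, min(10, n−1)] — an automated stand-in
for visual dendrogram inspection; a `k` override is always available and
k < 2 is rejected.

Cluster description follows the catdes convention. Quantitative variables
(genes) use the v-test, v = (x̄_c − x̄)/√(s²/n_c · (N − n_c)/(N − 1)) with s²
the population variance, reported two-sided against the normal when
p < alpha (default 0.05). Categorical metadata uses the chi-square test of
association without continuity correction. Both are implemented and
labelled by kind; singleton clusters are skipped with a warning.

## Differential expression stand-in

Per-gene Welch t-tests on the log-scale values with Benjamini-Hochberg
adjustment, filtered by |log2FC| ≥ lfc_min (default 1) and adjusted
p ≤ fdr_max (default 0.05). This is deliberately *not* a count-model tool
such as DESeq2 — it exists so the synthetic pipeline has a calibrated,
dependency-light DE stage; real-data users can import an externally
computed table in the same column schema. Genes constant in both groups
carry p = 1. BH is monotone, so raw-p order is preserved in adjusted p.

## Variant burden

Input is a flat TSV (sample, variant, gene, presence). **Presence mode
(default)** counts variant loci with presence > 0; allele mode sums 0/1/2
dosages — the default reflects counting mutations rather than alleles, and
the mode is recorded on the output. A minimal plain-text VCF v4.x reader
(fixed columns + GT, INFO ignored, gene annotation supplied as a side
mapping) is provided for convenience. Group tests: Mann-Whitney
(two-sided), Welch, one-way ANOVA. Two groups whose pooled observations are
all identical return p = 1 by the exact-ties convention (the asymptotic
rank-test variance is zero there).

## Synthetic cohorts

The generators plant effects directly on the log2 scale with Gaussian
noise; count-level simulation is out of scope because every analysis stage
consumes transformed values.

* **Organoid cohort (default)**: 10 healthy + 12 + 12 subtype samples,
  2,000 genes, per-gene baseline ~ Normal(5, 2), planted blocks of
  150 shared + 100 + 100 subtype-specific genes shifted by +2 log2 units,
  per-sample noise sigma = 0.7. The baseline distribution approximates the
  spread of expressed genes on a log2-TPM scale; the block sizes and effect
  give a clearly resolvable three-group structure without being trivial at
  the single-gene level (per-gene two-group separation ≈ 2.9 sigma).
* **Tissue cohort (default)**: 10 control / 10 inactive / 10 active
  samples, 500 genes, 50 induced by +2 log2 units in active samples only.
* **Variants**: Bernoulli presence per (sample, pathway gene), base rate
  0.05 against an enriched rate 0.3 in the designated group's enriched
  pathway.

Each gene's random stream is derived from `SeedSequence([seed, gene_index])`,
so outputs are bit-reproducible for a given config and adding samples or
genes leaves other genes' draws unchanged. Truth records (planted labels,
DEG blocks, induced genes, group maps) are sufficient to score ARI, recall
and test power externally.

What the generators do **not** emulate: library-size and batch effects,
count overdispersion, gene-gene correlation beyond the planted blocks,
missing data, and platform differences. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under their stated
assumptions, not robustness to real-data artifacts.

## Pipeline and determinism

`run_pipeline` validates the full config before any stage runs (broken
paths and out-of-range parameters fail fast), executes
simulate → DE → cluster/describe → thresholds → score/benchmark → burden,
and writes a manifest with the package version, the seed, a SHA-256 hash of
the config (excluding the output location) and a SHA-256 checksum of every
output file. TSV floats are serialized with the `%.10g` format so
serialized outputs are platform-stable. Stage failures abort with the stage
name; completed outputs are retained.

## Problem sizes used in the checks

The test-suite simulations use the default study conditions above;
repeated-seed checks use 20 seeds for clustering recovery and DE
calibration, 50 seeds for burden power and 100 for its null, and 1,000
random series (plus an exhaustive n ≤ 12 suite) for the step-fit oracle —
sizes at which the binomial uncertainty of each pass criterion is small
relative to its margin.

## Known limitations

* The DE routine ignores count noise models; at very low expression its
  normal-theory p-values are only approximate.
* The suggested cluster count is a heuristic over the inertia profile;
  like any such rule it can over- or under-merge when groups overlap —
  the `k` override exists for that reason.
* Composite scores are cohort-relative (thresholds and stddev are
  recomputed per dataset); absolute score values are not comparable across
  cohorts, only orderings and derived AUCs.
* The TUNEL index depends on instrument-specific integrated-density units
  and is comparable only within one imaging batch.
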