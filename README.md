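# pdomics

Transcriptomic and genomic analysis pipeline for patient-derived organoid
(PDO) cohorts in inflammatory bowel disease, built around four methods:

1. **StepMiner expression binarization.** For each gene, the expression
   values across samples are sorted and a one-step function fitted by
   evaluating every split position *k* and keeping the one that minimizes
   the squared error. The fit is scored by an adaptive-regression
   F-statistic,

   *F* = [Σᵢ (X̂ᵢ − X̄)² / (m − 1)] / [Σᵢ (Xᵢ − X̂ᵢ)² / (n − m)],

   where X̂ᵢ are the fitted segment means and *m* the regression degrees of
   freedom (default 3). The midpoint of the two segment means defines the
   gene's high/low threshold *SThr*.

2. **Composite signature scoring.** Expression is normalized per gene by a
   modified Z score centred on the StepMiner threshold,
   (expr − SThr)/(3·stddev), and the normalized values of a gene
   signature are summed per sample (down-genes subtract). Sample orderings
   induced by the score are evaluated by rank-based ROC-AUC and group
   differences by Welch's unequal-variance t-test. The key benchmark asks
   whether a disease signature is induced *exclusively in active disease*:
   active-vs-control should separate near-perfectly while
   inactive-vs-control stays at chance.

3. **Molecular-subtype discovery.** PCA of samples on per-gene-centred
   expression, Ward agglomeration on the retained principal components
   (HCPC-style), automatic cluster-count suggestion from the within-cluster
   inertia profile, and catdes-style cluster description (v-test for genes,
   chi-square for categorical metadata).

4. **Pathway variant burden.** Per-sample mutation counts restricted to
   pathway gene sets (GMT), compared across groups by Mann-Whitney,
   Welch's t or one-way ANOVA. Single-SNP risk-allele queries are expressed
   as one-gene pathways.

A seeded synthetic-cohort generator (`pdomics.simulate`) produces the study
designs these methods assume — healthy + two disease molecular subtypes
with planted DEG blocks, a tissue cohort with activity-restricted
induction, and variant tables with planted pathway enrichment — so the
entire pipeline is testable end-to-end with no external data. The arithmetic
of the wet-lab phenotype readouts (TEER normalization to Ω·cm², BrdU fold
change, TUNEL index, Ki67 percent, LYZ:MUC2 ratio) lives in
`pdomics.phenotype`.

## Worked example

```sh
pdomics run-all --seed 1 --outdir scratch/demo
```

runs every stage on the default synthetic cohort and prints the run
summary:

```
{
 "benchmark": {
  "active_vs_control": 1.0,
  "inactive_vs_control": 0.36
 },
 "burden_min_p": 0.00034016488073331186,
 "cluster_sizes": {"1": 10, "2": 12, "3": 12},
 "deg_counts": {"IDICD": 251, "S2FCD": 251},
 "suggested_k": 3
}
```

Reading: clustering on the first 5 principal components suggests k = 3 and
recovers the planted 10 healthy / 12 + 12 subtype samples exactly;
Welch+BH differential expression finds ~251 genes per subtype (250 planted
per contrast); the activity benchmark scores the induced signature at
AUC 1.0 for active-vs-control but 0.36 (chance-level) for
inactive-vs-control; and the planted pathway enrichment is detected at
p ≈ 3.4 × 10⁻⁴ by Mann-Whitney. The run directory contains every stage's
TSV outputs plus `manifest.json` with a config hash and per-file SHA-256
checksums; rerunning the same config and seed reproduces the checksums
bit-for-bit.

The numbered drivers under `analysis/` run the same stages as a narrative
sequence (`01_simulate_cohorts.py` first; later scripts read its outputs
from `results/cohorts/`). Each stage is also exposed as a CLI subcommand
(`pdomics simulate|transform|de|cluster|thresholds|score|benchmark|burden|phenotype`)
operating on plain TSV/GMT files.

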