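#!/usr/bin/env python
"""Generate the synthetic study cohorts and write them under results/.

Three datasets drive the downstream analyses:
  * an organoid cohort of 10 healthy + 12 + 12 disease-subtype samples with
    planted shared (150 genes) and subtype-specific (100 + 100) DEG blocks,
  * a tissue cohort (10 control / 10 inactive / 10 active) where 50 genes
    are induced by +2 log2 units in the active state only,
  * a variant table over four 20-gene pathways with one pathway enriched
    (rate 0.3 vs 0.05) in one subtype.
"""

import json
from pathlib import Path

from pdomics.burden import write_variant_table
from pdomics.io import write_gmt, write_matrix, write_metadata
from pdomics.simulate import (
    CohortConfig,
    TissueConfig,
    default_pathways,
    simulate_pdo_cohort,
    simulate_tissue_cohort,
    simulate_variants,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cohort, cohort_truth = simulate_pdo_cohort(CohortConfig(seed=SEED))
    write_matrix(cohort, OUT / "pdo_expression.tsv")
    write_metadata(cohort.metadata, OUT / "pdo_metadata.tsv")
    (OUT / "pdo_truth.json").write_text(json.dumps(cohort_truth, indent=1,
                                                   sort_keys=True))
    print(f"PDO cohort: {cohort.n_genes} genes x {cohort.n_samples} samples "
          f"({cohort_truth['effect']} log2 effect, sigma {cohort_truth['sigma']})")

    tissue, tissue_truth, signature = simulate_tissue_cohort(TissueConfig(seed=SEED + 1))
    write_matrix(tissue, OUT / "tissue_expression.tsv")
    write_metadata(tissue.metadata, OUT / "tissue_metadata.tsv")
    write_gmt([signature], OUT / "induced_signature.gmt")
    (OUT / "tissue_truth.json").write_text(json.dumps(tissue_truth, indent=1,
                                                      sort_keys=True))
    print(f"tissue cohort: {tissue.n_genes} genes x {tissue.n_samples} samples, "
          f"{len(tissue_truth['induced_genes'])} induced genes (active only)")

    pathways = default_pathways()
    variants, vtruth = simulate_variants(
        {"healthy": 10, "IDICD": 10}, pathways, enriched_pathway="pathway_0",
        enriched_group="IDICD", base_rate=0.05, enriched_rate=0.3, seed=SEED + 2)
    write_variant_table(variants, OUT / "variants.tsv")
    write_gmt(pathways, OUT / "pathways.gmt")
    (OUT / "variant_truth.json").write_text(json.dumps(vtruth, indent=1,
                                                       sort_keys=True))
    print(f"variants: {len(variants)} calls over {len(pathways)} pathways "
          f"(pathway_0 enriched in IDICD)")


if __name__ == "__main__":
    main()
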