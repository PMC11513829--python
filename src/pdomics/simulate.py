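"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_pdo_cohort` — an organoid cohort of healthy samples plus two
  disease molecular subtypes.  Each gene has a Normal baseline on the
  log2-expression scale; planted differentially-expressed (DEG) blocks add a
  fixed log2 shift either in both disease subtypes (shared block) or in one
  subtype only, with Gaussian per-sample noise on top.
* :func:`simulate_tissue_cohort` — a tissue cohort with healthy-control,
  inactive-disease and active-disease samples, where a chosen gene set is
  induced *only* in the active state (the benchmark design for
  activity-specific signatures).
* :func:`simulate_variants` — per-sample variant calls over pathway gene
  sets, Bernoulli at a base rate everywhere except an enriched pathway in a
  designated group.

Noise is Gaussian on the log2 scale rather than count-level negative
binomial: every downstream stage consumes transformed values, so the
generator plants effects directly on the scale the methods operate on.
Every per-gene random stream is derived deterministically from the global
seed and the gene index, so adding samples or genes leaves the draws of
other genes untouched and identical configs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pdomics.io import ExpressionMatrix, GeneSignature, PathwayGeneSet


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(gene_index)]))


@dataclass
class CohortConfig:
    """Study conditions for the synthetic organoid cohort.

    Defaults plant a shared disease block of 150 genes plus 100
    subtype-specific genes per subtype, shifted by 2 log2 units over a
    Normal(5, 2) baseline with sigma = 0.7 per-sample noise — a separation
    comparable to the strong subtype structure the pipeline is meant to
    resolve.
    """

    n_healthy: int = 10
    n_cd1: int = 12
    n_cd2: int = 12
    n_genes: int = 2000
    n_shared_deg: int = 150
    n_cd1_deg: int = 100
    n_cd2_deg: int = 100
    effect: float = 2.0
    sigma: float = 0.7
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_shared_deg + self.n_cd1_deg + self.n_cd2_deg > self.n_genes:
            raise ValueError("planted DEG blocks exceed the number of genes")
        if min(self.n_healthy, self.n_cd1, self.n_cd2) < 1:
            raise ValueError("every group needs at least one sample")


@dataclass
class TissueConfig:
    """Study conditions for the activity-benchmark tissue cohort.

    ``induced_genes`` (default: the first ``n_induced`` genes) receive
    ``induction_effect`` log2 units in active samples only.
    """

    n_control: int = 10
    n_inactive: int = 10
    n_active: int = 10
    n_genes: int = 500
    n_induced: int = 50
    induction_effect: float = 2.0
    sigma: float = 0.7
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0
    induced_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.induced_genes is None and not (0 < self.n_induced <= self.n_genes):
            raise ValueError("n_induced must be in (0, n_genes]")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"gene_{i:0{width}d}" for i in range(n)]


def simulate_pdo_cohort(config: CohortConfig = CohortConfig()):
    """Simulate the organoid cohort: healthy + two disease subtypes.

    Returns ``(matrix, truth)``.  ``truth`` records the planted group of every
    sample and the gene ids of each DEG block; it is sufficient to score
    cluster recovery (ARI) and DEG recall without touching generator
    internals.
    """
    c = config
    genes = _gene_ids(c.n_genes)
    sample_ids = (
        [f"H{i+1:02d}" for i in range(c.n_healthy)]
        + [f"CD1_{i+1:02d}" for i in range(c.n_cd1)]
        + [f"CD2_{i+1:02d}" for i in range(c.n_cd2)]
    )
    group_of = (
        ["healthy"] * c.n_healthy + ["cd1"] * c.n_cd1 + ["cd2"] * c.n_cd2
    )
    n_samples = len(sample_ids)

    shared = genes[: c.n_shared_deg]
    cd1_block = genes[c.n_shared_deg: c.n_shared_deg + c.n_cd1_deg]
    cd2_block = genes[c.n_shared_deg + c.n_cd1_deg:
                      c.n_shared_deg + c.n_cd1_deg + c.n_cd2_deg]
    shared_set, cd1_set, cd2_set = set(shared), set(cd1_block), set(cd2_block)

    is_cd1 = np.array([g == "cd1" for g in group_of])
    is_cd2 = np.array([g == "cd2" for g in group_of])

    values = np.empty((c.n_genes, n_samples))
    for i, gene in enumerate(genes):
        rng = _gene_rng(c.seed, i)
        baseline = rng.normal(c.baseline_mean, c.baseline_sd)
        mean = np.full(n_samples, baseline)
        if gene in shared_set:
            mean = mean + c.effect * (is_cd1 | is_cd2)
        elif gene in cd1_set:
            mean = mean + c.effect * is_cd1
        elif gene in cd2_set:
            mean = mean + c.effect * is_cd2
        values[i] = mean + rng.normal(0.0, c.sigma, size=n_samples)

    metadata = {}
    subtype_of = {"healthy": "none", "cd1": "IDICD", "cd2": "S2FCD"}
    for sid, grp in zip(sample_ids, group_of):
        metadata[sid] = {
            "group": "healthy" if grp == "healthy" else "CD",
            "molecular_subtype": subtype_of[grp],
        }
    matrix = ExpressionMatrix(gene_ids=genes, sample_ids=sample_ids,
                              values=values, metadata=metadata)
    truth = {
        "labels": dict(zip(sample_ids, group_of)),
        "deg_shared": shared,
        "deg_cd1": cd1_block,
        "deg_cd2": cd2_block,
        "effect": c.effect,
        "sigma": c.sigma,
        "seed": c.seed,
    }
    return matrix, truth


def simulate_tissue_cohort(config: TissueConfig = TissueConfig()):
    """Simulate the tissue benchmark cohort (control / inactive / active).

    The induced gene set is shifted by ``induction_effect`` log2 units in
    active samples only; inactive samples are statistically indistinguishable
    from controls.  Returns ``(matrix, truth)`` where truth lists the induced
    genes (also packaged as a :class:`GeneSignature`) and per-sample activity.
    """
    c = config
    genes = _gene_ids(c.n_genes)
    if c.induced_genes is not None:
        induced = sorted(set(c.induced_genes))
        unknown = set(induced) - set(genes)
        if unknown:
            raise ValueError(f"induced genes not in the cohort: {sorted(unknown)[:5]}")
    else:
        induced = genes[: c.n_induced]
    induced_set = set(induced)

    sample_ids = (
        [f"CTRL_{i+1:02d}" for i in range(c.n_control)]
        + [f"INACT_{i+1:02d}" for i in range(c.n_inactive)]
        + [f"ACT_{i+1:02d}" for i in range(c.n_active)]
    )
    activity = (
        ["healthy"] * c.n_control + ["inactive"] * c.n_inactive
        + ["active"] * c.n_active
    )
    is_active = np.array([a == "active" for a in activity])
    n_samples = len(sample_ids)

    values = np.empty((c.n_genes, n_samples))
    for i, gene in enumerate(genes):
        rng = _gene_rng(c.seed, i)
        baseline = rng.normal(c.baseline_mean, c.baseline_sd)
        mean = np.full(n_samples, baseline)
        if gene in induced_set:
            mean = mean + c.induction_effect * is_active
        values[i] = mean + rng.normal(0.0, c.sigma, size=n_samples)

    metadata = {
        sid: {"group": "healthy" if a == "healthy" else "CD", "activity": a}
        for sid, a in zip(sample_ids, activity)
    }
    matrix = ExpressionMatrix(gene_ids=genes, sample_ids=sample_ids,
                              values=values, metadata=metadata)
    truth = {
        "activity": dict(zip(sample_ids, activity)),
        "induced_genes": induced,
        "induction_effect": c.induction_effect,
        "seed": c.seed,
    }
    signature = GeneSignature(name="induced_up", up_genes=frozenset(induced))
    return matrix, truth, signature


def simulate_variants(group_sizes: dict[str, int], pathways,
                      enriched_pathway: str | None = None,
                      enriched_group: str | None = None,
                      base_rate: float = 0.05, enriched_rate: float = 0.3,
                      seed: int = 0):
    """Simulate per-sample variant presence over pathway gene sets.

    Every (sample, pathway gene) pair carries a variant with probability
    ``base_rate``, except genes of ``enriched_pathway`` in samples of
    ``enriched_group``, which use ``enriched_rate``.  Only positive calls are
    emitted (an all-zero draw yields an empty table).  Returns
    ``(variant_table, truth)`` where truth carries the sample ids, the group
    map and the planted enrichment.
    """
    if not (0 <= base_rate <= 1 and 0 <= enriched_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    pathways = list(pathways)
    by_name = {p.name: p for p in pathways}
    if enriched_pathway is not None and enriched_pathway not in by_name:
        raise ValueError(f"unknown enriched pathway {enriched_pathway!r}")
    if enriched_pathway is not None and enriched_group is not None:
        if enriched_group not in group_sizes:
            raise ValueError(f"unknown enriched group {enriched_group!r}")
        enriched_genes = by_name[enriched_pathway].genes
    else:
        enriched_genes = frozenset()

    sample_ids, group_of = [], {}
    for name in group_sizes:
        for i in range(group_sizes[name]):
            sid = f"{name}_{i+1:02d}"
            sample_ids.append(sid)
            group_of[sid] = name

    all_genes = sorted({g for p in pathways for g in p.genes})
    records = []
    for gi, gene in enumerate(all_genes):
        rng = _gene_rng(seed, gi)
        for sid in sample_ids:
            rate = (enriched_rate
                    if gene in enriched_genes and group_of[sid] == enriched_group
                    else base_rate)
            if rng.random() < rate:
                records.append({"sample_id": sid, "variant_id": f"rs_{gene}",
                                "gene_id": gene, "presence": 1})
    table = pd.DataFrame(records,
                         columns=["sample_id", "variant_id", "gene_id", "presence"])
    truth = {
        "sample_ids": sample_ids,
        "groups": {name: [s for s in sample_ids if group_of[s] == name]
                   for name in group_sizes},
        "enriched_pathway": enriched_pathway,
        "enriched_group": enriched_group,
        "base_rate": base_rate,
        "enriched_rate": enriched_rate,
        "seed": seed,
    }
    return table, truth


def default_pathways(n_pathways: int = 4, genes_per_pathway: int = 20):
    """Disjoint synthetic pathway gene sets for burden simulations."""
    pathways = []
    for p in range(n_pathways):
        genes = frozenset(
            f"pw{p}_gene_{i:02d}" for i in range(genes_per_pathway)
        )
        pathways.append(PathwayGeneSet(name=f"pathway_{p}", genes=genes,
                                       description="synthetic"))
    return pathways
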