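"""End-to-end pipeline driver with a reproducible run manifest.

A run executes, from one config mapping: synthetic-cohort simulation
(optional), differential expression, PCA + Ward subtype clustering with
cluster description, StepMiner threshold derivation, composite signature
scoring, the tissue activity benchmark, and pathway variant-burden
comparison.  Every stage writes plain-text outputs into the run directory
and the manifest records the config hash, the seed and a SHA-256 checksum
of every output, so two runs from the same config are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from pdomics import __version__
from pdomics.burden import burden_report, read_variant_table, write_variant_table
from pdomics.clustering import differential_expression, hcpc_cluster, write_clustering
from pdomics.io import read_gmt, read_matrix, write_gmt, write_matrix, write_metadata
from pdomics.scoring import benchmark_signature, composite_score, normalize_expression
from pdomics.simulate import (
    CohortConfig,
    TissueConfig,
    default_pathways,
    simulate_pdo_cohort,
    simulate_tissue_cohort,
    simulate_variants,
)
from pdomics.stepminer import derive_thresholds, write_thresholds

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG = {
    "outdir": "run",
    "seed": 0,
    "simulate": True,
    "expression": None,       # TSV path when simulate is false
    "metadata": None,
    "signature": None,        # GMT path; default: tissue truth signature
    "cohort": {},             # CohortConfig overrides
    "tissue": {},             # TissueConfig overrides
    "stepminer": {"m": 3, "margin": 0.0},
    "clustering": {"ncp": 5, "k": None, "alpha": 0.05},
    "de": {"lfc_min": 1.0, "fdr_max": 0.05},
    "burden": {"test": "mann-whitney", "mode": "presence",
               "base_rate": 0.05, "enriched_rate": 0.3,
               "n_per_group": 10},
}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(cfg: dict) -> None:
    """Fail fast, before any computation, on broken paths or ranges."""
    if not cfg["simulate"]:
        for key in ("expression",):
            if not cfg[key] or not Path(cfg[key]).exists():
                raise ValueError(f"config {key!r}: path missing or does not exist")
    if cfg["signature"] is not None and not Path(cfg["signature"]).exists():
        raise ValueError(f"signature path {cfg['signature']!r} does not exist")
    m = cfg["stepminer"]["m"]
    if not (isinstance(m, int) and m > 1):
        raise ValueError("stepminer.m must be an integer > 1")
    if cfg["stepminer"]["margin"] < 0:
        raise ValueError("stepminer.margin must be nonnegative")
    k = cfg["clustering"]["k"]
    if k is not None and k < 2:
        raise ValueError("clustering.k must be >= 2")
    if not (0 < cfg["de"]["fdr_max"] <= 1):
        raise ValueError("de.fdr_max must lie in (0, 1]")
    if cfg["burden"]["test"] not in ("mann-whitney", "welch", "anova"):
        raise ValueError(f"unknown burden test {cfg['burden']['test']!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute all stages; return the manifest (also written to the run dir).

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are left in place for debugging.
    """
    cfg = merge_config(config)
    validate_config(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    outputs: list[Path] = []
    summary: dict = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # --- simulate / load -------------------------------------------------
    name = stage("simulate")
    try:
        if cfg["simulate"]:
            cohort_cfg = CohortConfig(**{**cfg["cohort"], "seed": seed})
            matrix, cohort_truth = simulate_pdo_cohort(cohort_cfg)
            tissue_cfg = TissueConfig(**{**cfg["tissue"], "seed": seed + 1})
            tissue, tissue_truth, truth_signature = simulate_tissue_cohort(tissue_cfg)
            write_matrix(matrix, outdir / "expression.tsv")
            write_metadata(matrix.metadata, outdir / "metadata.tsv")
            write_matrix(tissue, outdir / "tissue_expression.tsv")
            write_metadata(tissue.metadata, outdir / "tissue_metadata.tsv")
            (outdir / "cohort_truth.json").write_text(
                json.dumps(cohort_truth, indent=1, sort_keys=True))
            (outdir / "tissue_truth.json").write_text(
                json.dumps(tissue_truth, indent=1, sort_keys=True))
            outputs += [outdir / f for f in (
                "expression.tsv", "metadata.tsv", "tissue_expression.tsv",
                "tissue_metadata.tsv", "cohort_truth.json", "tissue_truth.json")]
        else:
            matrix = read_matrix(cfg["expression"], metadata_path=cfg["metadata"])
            tissue = None
            truth_signature = None
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineError(name, exc) from exc

    # --- differential expression ----------------------------------------
    name = stage("de")
    try:
        groups = matrix.labels("group")
        subtypes = matrix.labels("molecular_subtype")
        healthy = [s for s, g in zip(matrix.sample_ids, groups) if g == "healthy"]
        de_tables = {}
        for subtype in sorted(set(subtypes) - {"none"}):
            case = [s for s, t in zip(matrix.sample_ids, subtypes) if t == subtype]
            if len(case) >= 3 and len(healthy) >= 3:
                de = differential_expression(matrix, case, healthy,
                                             lfc_min=cfg["de"]["lfc_min"],
                                             fdr_max=cfg["de"]["fdr_max"])
                de.to_csv(outdir / f"deg_{subtype}_vs_healthy.tsv", sep="\t",
                          index=False, float_format="%.10g")
                outputs.append(outdir / f"deg_{subtype}_vs_healthy.tsv")
                de_tables[subtype] = de
        summary["deg_counts"] = {k: int(len(v)) for k, v in de_tables.items()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # --- clustering ------------------------------------------------------
    name = stage("cluster")
    try:
        clust = hcpc_cluster(matrix, ncp=cfg["clustering"]["ncp"],
                             k=cfg["clustering"]["k"],
                             descriptor_alpha=cfg["clustering"]["alpha"])
        write_clustering(clust, outdir / "clustering")
        outputs += sorted((outdir / "clustering").glob("*.tsv"))
        summary["suggested_k"] = int(clust.suggested_k)
        summary["cluster_sizes"] = {
            int(c): int((clust.labels == c).sum()) for c in sorted(set(clust.labels))
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # --- stepminer thresholds -------------------------------------------
    name = stage("thresholds")
    try:
        thresholds = derive_thresholds(matrix, m=cfg["stepminer"]["m"],
                                       margin=cfg["stepminer"]["margin"])
        write_thresholds(thresholds, outdir / "thresholds.tsv")
        outputs.append(outdir / "thresholds.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # --- signature scoring + benchmark ----------------------------------
    name = stage("benchmark")
    try:
        if cfg["signature"] is not None:
            signature = read_gmt(cfg["signature"], as_signatures=True)[0]
        else:
            signature = truth_signature
        if signature is not None and tissue is not None:
            bench, score_table = benchmark_signature(
                signature, tissue, m=cfg["stepminer"]["m"])
            bench.to_csv(outdir / "benchmark.tsv", sep="\t", index=False,
                         float_format="%.10g")
            score_table.to_frame().to_csv(outdir / "tissue_scores.tsv", sep="\t",
                                          index=False, float_format="%.10g")
            outputs += [outdir / "benchmark.tsv", outdir / "tissue_scores.tsv"]
            summary["benchmark"] = {
                r["contrast"]: round(float(r["auc"]), 4)
                for _, r in bench.iterrows()
            }
        # composite scores on the PDO cohort with its own thresholds
        if signature is not None:
            common = signature.genes & set(matrix.gene_ids)
            if common:
                normalized = normalize_expression(matrix, thresholds)
                table = composite_score(normalized, signature)
                table.to_frame().to_csv(outdir / "cohort_scores.tsv", sep="\t",
                                        index=False, float_format="%.10g")
                outputs.append(outdir / "cohort_scores.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # --- variant burden --------------------------------------------------
    name = stage("burden")
    try:
        bcfg = cfg["burden"]
        pathways = default_pathways()
        n = int(bcfg["n_per_group"])
        variants, vtruth = simulate_variants(
            {"healthy": n, "IDICD": n}, pathways,
            enriched_pathway=pathways[0].name, enriched_group="IDICD",
            base_rate=bcfg["base_rate"], enriched_rate=bcfg["enriched_rate"],
            seed=seed + 2)
        write_variant_table(variants, outdir / "variants.tsv")
        write_gmt(pathways, outdir / "pathways.gmt")
        report = burden_report(variants, pathways, vtruth["groups"],
                               test=bcfg["test"], mode=bcfg["mode"])
        report.to_csv(outdir / "burden.tsv", sep="\t", index=False,
                      float_format="%.10g")
        outputs += [outdir / "variants.tsv", outdir / "pathways.gmt",
                    outdir / "burden.tsv"]
        summary["burden_min_p"] = float(report["p"].min())
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # --- manifest --------------------------------------------------------
    # outdir is a location, not an analysis parameter: exclude it from the hash
    cfg_canon = json.dumps({k: v for k, v in cfg.items() if k != "outdir"},
                           sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_canon.encode()).hexdigest(),
        "config": cfg,
        "summary": summary,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
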