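"""Pathway-restricted variant burden counting and group comparison.

Variant calls arrive as a flat per-sample table (sample_id, variant_id,
gene_id, presence) — presence is 0/1 in presence mode or an allele count
0/1/2 in allele mode.  Burden for a pathway is, per sample, the number of
variant records (or total alleles) falling in the pathway's genes.  Groups
are compared by Mann-Whitney, Welch's t, or one-way ANOVA.  Single-SNP
queries are expressed as one-gene pathways; no special-case code exists.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from pdomics.io import FormatError, PathwayGeneSet

VARIANT_COLUMNS = ["sample_id", "variant_id", "gene_id", "presence"]


def validate_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Check schema, uniqueness of (sample, variant) pairs and presence codes."""
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise FormatError(f"variant table missing column(s): {missing}")
    dup = variants.duplicated(subset=["sample_id", "variant_id"])
    if dup.any():
        first = variants.loc[dup, ["sample_id", "variant_id"]].iloc[0]
        raise FormatError(
            f"duplicate (sample, variant) pair: {tuple(first)}"
        )
    presence = variants["presence"].to_numpy()
    if not np.isin(presence, [0, 1, 2]).all():
        raise FormatError("presence must be coded 0/1 (presence) or 0/1/2 (alleles)")
    return variants


def read_variant_table(path) -> pd.DataFrame:
    """Read the flat TSV variant schema (sample_id, variant_id, gene_id, presence)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variant_id": str,
                                            "gene_id": str})
    return validate_variant_table(df)


def write_variant_table(variants: pd.DataFrame, path) -> None:
    validate_variant_table(variants)[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_vcf_minimal(path, gene_map: dict[str, str]) -> pd.DataFrame:
    """Minimal plain-text VCF v4.x reader: fixed columns plus GT only.

    ``gene_map`` maps variant IDs (the VCF ID column) to gene symbols; IDs
    without a mapping are skipped.  INFO and all FORMAT fields other than GT
    are ignored.  Presence is the non-reference allele count (0/1/2).
    """
    records = []
    samples: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            if len(parts) < 10 or not samples:
                raise FormatError("VCF needs #CHROM header and genotype columns")
            variant_id = parts[2]
            gene = gene_map.get(variant_id)
            if gene is None:
                continue
            fmt = parts[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise FormatError(f"variant {variant_id}: no GT in FORMAT") from None
            for sample, call in zip(samples, parts[9:]):
                gt = call.split(":")[gt_idx].replace("|", "/")
                alleles = [a for a in gt.split("/") if a not in (".", "")]
                presence = sum(1 for a in alleles if a != "0")
                records.append({"sample_id": sample, "variant_id": variant_id,
                                "gene_id": gene, "presence": presence})
    df = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    return validate_variant_table(df)


def count_pathway_mutations(variants: pd.DataFrame, pathway: PathwayGeneSet,
                            sample_ids=None, mode: str = "presence") -> pd.Series:
    """Per-sample mutation burden within one pathway's genes.

    In ``presence`` mode each variant record with presence > 0 counts once;
    in ``allele`` mode allele counts are summed.  ``sample_ids`` fixes the
    output index (samples absent from the table get 0); by default the
    table's samples are used.  A pathway with no gene represented yields
    all-zero counts with a warning.
    """
    if mode not in ("presence", "allele"):
        raise ValueError(f"unknown counting mode {mode!r}")
    validate_variant_table(variants)
    if sample_ids is None:
        sample_ids = sorted(variants["sample_id"].unique())
    in_path = variants[variants["gene_id"].isin(pathway.genes)]
    if in_path.empty and len(variants):
        warnings.warn(f"pathway {pathway.name!r}: no gene represented in the "
                      "variant table; counts are all zero", stacklevel=2)
    if mode == "presence":
        contrib = (in_path["presence"] > 0).astype(int)
    else:
        contrib = in_path["presence"]
    counts = contrib.groupby(in_path["sample_id"]).sum()
    out = counts.reindex(sample_ids, fill_value=0).astype(int)
    out.name = pathway.name
    out.attrs["mode"] = mode
    return out


def compare_burden(counts: pd.Series, groups: dict[str, list[str]],
                   test: str = "mann-whitney"):
    """Compare pathway burden across sample groups.

    ``groups`` maps group name -> sample ids.  ``test`` is one of
    ``mann-whitney`` (two groups, two-sided rank test), ``welch`` (two
    groups, unequal-variance t) or ``anova`` (one-way, >= 2 groups).
    Returns ``(statistic, p_value)``.
    """
    arrays = []
    for name, sids in groups.items():
        if len(sids) == 0:
            raise ValueError(f"group {name!r} is empty")
        arrays.append(counts.reindex(sids).to_numpy(dtype=float))
    if test == "mann-whitney":
        if len(arrays) != 2:
            raise ValueError("mann-whitney needs exactly 2 groups")
        a, b = arrays
        if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
            # all observations tied: no evidence either way
            return float(len(a) * len(b) / 2.0), 1.0
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(u), float(p)
    if test == "welch":
        if len(arrays) != 2:
            raise ValueError("welch needs exactly 2 groups")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        return float(t), float(p)
    if test == "anova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*arrays)
        if not np.isfinite(f):  # all groups constant and equal
            return 0.0, 1.0
        return float(f), float(p)
    raise ValueError(f"unknown test {test!r}; use mann-whitney, welch or anova")


def burden_report(variants: pd.DataFrame, pathways, groups: dict[str, list[str]],
                  test: str = "mann-whitney", mode: str = "presence") -> pd.DataFrame:
    """Burden comparison for a list of pathways; one row per pathway."""
    all_samples = sorted({s for sids in groups.values() for s in sids})
    rows = []
    for pw in pathways:
        counts = count_pathway_mutations(variants, pw, sample_ids=all_samples, mode=mode)
        stat, p = compare_burden(counts, groups, test=test)
        row = {"pathway": pw.name, "test": test, "mode": mode,
               "statistic": stat, "p": p}
        for name, sids in groups.items():
            row[f"mean_{name}"] = float(counts.reindex(sids).mean())
        rows.append(row)
    return pd.DataFrame(rows)
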