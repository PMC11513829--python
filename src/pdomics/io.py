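"""Expression-matrix, metadata and gene-set I/O.

Expression values live on the log2(TPM)-like scale produced by
:func:`transform_tpm`: ``log2(TPM)`` when TPM > 1, else ``TPM - 1``.  Both
branches meet at 0 when TPM = 1, so the transform is continuous and monotone
on [0, inf).  Matrices are stored genes-in-rows, samples-in-columns, as
tab-separated text with the gene identifier in the first column.

Gene sets use the standard GMT dialect: one set per line,
``name <TAB> description <TAB> gene1 <TAB> gene2 ...``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

METADATA_FIELDS = ("group", "molecular_subtype", "clinical_subtype", "activity", "response")


class FormatError(ValueError):
    """Structural problem in an input file (duplicates, malformed line)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with per-sample metadata labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Finite expression values on a log2(TPM)-like scale.
    metadata : dict
        ``sample_id -> {field: label}``; missing fields default to ``"none"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression values")
        known = set(self.sample_ids)
        for sid in self.metadata:
            if sid not in known:
                raise FormatError(f"metadata sample {sid!r} not in sample_ids")
        # normalize: every sample gets every field, defaulting to "none"
        full = {}
        for sid in self.sample_ids:
            row = dict(self.metadata.get(sid, {}))
            for f in METADATA_FIELDS:
                row.setdefault(f, "none")
            full[sid] = row
        self.metadata = full

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def labels(self, field_name: str) -> np.ndarray:
        """Per-sample label vector for one metadata field, in sample order."""
        if field_name not in METADATA_FIELDS:
            raise KeyError(f"unknown metadata field {field_name!r}")
        return np.array([self.metadata[s][field_name] for s in self.sample_ids])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            metadata={s: dict(self.metadata[s]) for s in sample_ids},
        )


@dataclass(frozen=True)
class GeneSignature:
    """Named signature of up- and down-regulated genes.

    The two sets must be disjoint and their union nonempty.
    """

    name: str
    up_genes: frozenset[str]
    down_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        if self.up_genes & self.down_genes:
            raise ValueError(f"signature {self.name!r}: up and down gene sets overlap")
        if not (self.up_genes | self.down_genes):
            raise ValueError(f"signature {self.name!r}: empty signature")

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PathwayGeneSet:
    """Named, nonempty gene set used for pathway-restricted burden counting."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"pathway {self.name!r}: empty gene set")

    def __len__(self) -> int:
        return len(self.genes)


def transform_tpm(tpm_values) -> np.ndarray:
    """Map raw TPM to the analysis scale: log2(TPM) if TPM > 1 else TPM - 1.

    Continuous and monotone nondecreasing on [0, inf); both branches give 0
    at TPM = 1.  Raises ``ValueError`` on negative input.
    """
    tpm = np.asarray(tpm_values, dtype=float)
    if np.any(tpm < 0):
        raise ValueError("TPM values must be nonnegative")
    return np.where(tpm > 1, np.log2(np.maximum(tpm, 1.0)), tpm - 1.0)


def read_matrix(path, metadata_path=None, transpose: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = gene ids, header = samples).

    Orientation is genes-in-rows; ``transpose=True`` accepts a
    samples-in-rows file and flips it on load.  Raises :class:`FormatError`
    for duplicated identifiers and ``ValueError`` naming the offending
    row/column for non-numeric cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate sample id {dup!r}")
    try:
        values = df.astype(float)
    except ValueError:
        for gene in df.index:
            for sample in df.columns:
                try:
                    float(df.at[gene, sample])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path.name}: non-numeric value {df.at[gene, sample]!r} "
                        f"at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    metadata = read_metadata(metadata_path) if metadata_path else {}
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values.to_numpy(),
        metadata=metadata,
    )


def write_matrix(matrix: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    """Write a matrix in the same TSV dialect :func:`read_matrix` accepts."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=float_format)


def read_metadata(path) -> dict[str, dict[str, str]]:
    """Read per-sample metadata TSV keyed by a ``sample_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("none")
    if "sample_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: metadata needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{Path(path).name}: duplicate sample_id in metadata")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = {
            f: row.get(f, "none") for f in METADATA_FIELDS if f in df.columns
        }
    return out


def write_metadata(metadata: Mapping[str, Mapping[str, str]], path) -> None:
    rows = [{"sample_id": sid, **labels} for sid, labels in metadata.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path, as_signatures: bool = False):
    """Parse a GMT file into :class:`PathwayGeneSet` (or :class:`GeneSignature`).

    With ``as_signatures=True`` each line becomes a signature whose genes are
    all up-genes (the GMT format carries no direction).  Malformed lines raise
    :class:`FormatError` with the 1-based line number.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{Path(path).name}:{lineno}: GMT line needs name, "
                    "description and at least one gene"
                )
            name, description = parts[0], parts[1]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{Path(path).name}:{lineno}: empty gene list for {name!r}")
            if as_signatures:
                sets.append(GeneSignature(name=name, up_genes=frozenset(genes)))
            else:
                sets.append(PathwayGeneSet(name=name, genes=frozenset(genes), description=description))
    return sets


def write_gmt(gene_sets: Iterable, path) -> None:
    """Write pathway sets or signatures as GMT (genes sorted for determinism)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            if isinstance(gs, GeneSignature):
                genes = sorted(gs.genes)
                desc = "signature"
            else:
                genes = sorted(gs.genes)
                desc = gs.description or "na"
            fh.write("\t".join([gs.name, desc, *genes]) + "\n")


def signature_from_sets(name: str, up: Iterable[str], down: Iterable[str] = ()) -> GeneSignature:
    return GeneSignature(name=name, up_genes=frozenset(up), down_genes=frozenset(down))
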