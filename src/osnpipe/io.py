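"""Readers, writers and in-memory containers for the tables the pipeline touches.

Count matrices travel as gene x sample integer tables (TSV or MatrixMarket
MTX with sidecar row/column files).  SNP definitions arrive as a minimal
VCF in which only CHROM, POS, ID, REF and ALT are consumed; the record ID
carries the overlapping gene id (``<gene>_<n>``).  All readers sort genes
canonically by id so the in-memory object is independent of row order on
disk.  Genomic positions are 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse

from .exceptions import FormatError

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("WOM", "pool", "subpop_low", "subpop_high", "cell")

#: spike-in genes are recognised by this id prefix
SPIKEIN_PREFIX = "ERCC-"


@dataclass
class CountMatrix:
    """A gene x sample matrix of non-negative integer fragment counts.

    Parameters
    ----------
    values
        DataFrame with unique gene ids as index and unique sample ids as
        columns; entries are non-negative integers.
    sample_types
        Series mapping every sample id to one of :data:`SAMPLE_TYPES`.
        Defaults to ``"cell"`` for every sample.
    """

    values: pd.DataFrame
    sample_types: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(arr != np.round(arr))[0]
                raise FormatError(
                    f"non-integer count at gene {v.index[r]!r}, sample {v.columns[c]!r}"
                )
            v = v.round().astype(np.int64)
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        v = v.sort_index().astype(np.int64)
        v.index = v.index.rename("gene")
        v.columns = v.columns.rename(None)
        self.values = v
        if self.sample_types is None:
            self.sample_types = pd.Series("cell", index=self.values.columns)
        self.sample_types = self.sample_types.reindex(self.values.columns)
        if self.sample_types.isna().any():
            missing = self.sample_types.index[self.sample_types.isna()].tolist()
            raise FormatError(f"sample metadata missing for: {missing[:5]}")
        bad = set(self.sample_types) - set(SAMPLE_TYPES)
        if bad:
            raise FormatError(f"unknown sample types: {sorted(bad)}")

    # -- convenience -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def spikein_mask(self) -> pd.Series:
        """Boolean per-gene mask for ERCC spike-in controls."""
        return pd.Series(
            self.values.index.str.startswith(SPIKEIN_PREFIX), index=self.values.index
        )

    def drop_spikeins(self) -> "CountMatrix":
        return CountMatrix(self.values.loc[~self.spikein_mask], self.sample_types)


# ---------------------------------------------------------------------------
# count matrix IO
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    counts.values.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path: str | Path, sample_types: pd.Series | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix(df, sample_types)


def write_counts_mtx(counts: CountMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rows.txt`` / ``<prefix>.cols.txt``."""
    prefix = Path(prefix)
    sparse = scipy.sparse.coo_matrix(counts.values.to_numpy())
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sparse, field="integer")
    prefix.with_suffix(".rows.txt").write_text("\n".join(counts.genes) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(counts.samples) + "\n")


def read_counts_mtx(prefix: str | Path, sample_types: pd.Series | None = None) -> CountMatrix:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix.with_suffix(".mtx")))
    genes = prefix.with_suffix(".rows.txt").read_text().splitlines()
    samples = prefix.with_suffix(".cols.txt").read_text().splitlines()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    df = pd.DataFrame(dense, index=genes, columns=samples)
    return CountMatrix(df, sample_types)


def read_counts(path: str | Path, format: str = "tsv", **kw) -> CountMatrix:
    """Dispatching reader; ``format`` is ``"tsv"`` or ``"mtx"``."""
    if format == "tsv":
        return read_counts_tsv(path, **kw)
    if format == "mtx":
        return read_counts_mtx(path, **kw)
    raise FormatError(f"unknown count-matrix format {format!r}")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["gene", "symbol", "category", "status", "or_class", "length"]
CATEGORIES = {"OR", "TAAR", "marker", "other"}
STATUSES = {"intact", "pseudogene"}


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort a gene annotation table.

    Columns: gene, symbol, category (OR|TAAR|marker|other), status
    (intact|pseudogene), or_class (I|II or missing), length (bp > 0).
    """
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    if ann["gene"].duplicated().any():
        raise FormatError("duplicate gene ids in annotation")
    bad = set(ann["category"]) - CATEGORIES
    if bad:
        raise FormatError(f"unknown categories: {sorted(bad)}")
    bad = set(ann["status"]) - STATUSES
    if bad:
        raise FormatError(f"unknown statuses: {sorted(bad)}")
    if (ann["length"] <= 0).any():
        g = ann.loc[ann["length"] <= 0, "gene"].iloc[0]
        raise FormatError(f"non-positive transcript length for gene {g!r}")
    has_class = ann["or_class"].notna() & (ann["or_class"].astype(str) != ".")
    if (has_class & (ann["category"] != "OR")).any():
        g = ann.loc[has_class & (ann["category"] != "OR"), "gene"].iloc[0]
        raise FormatError(f"or_class set for non-OR gene {g!r}")
    return ann.sort_values("gene").reset_index(drop=True)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False, na_rep=".")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", na_values=["."], dtype={"gene": str})
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# SNP table (minimal VCF)
# ---------------------------------------------------------------------------

SNP_COLUMNS = ["gene", "chrom", "pos", "strain_a_base", "strain_b_base"]
_BASES = {"A", "C", "G", "T"}


def read_snp_vcf(path: str | Path) -> pd.DataFrame:
    """Read biallelic SNPs from a VCF into a SnpTable DataFrame.

    REF is the strain-A base, ALT the strain-B base.  The record ID field
    names the overlapping gene as ``<gene>_<n>``.  Multi-allelic records
    and indels are skipped (count logged); REF == ALT is an error.
    """
    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                skipped += 1
                continue
            if ref == alt:
                raise FormatError(f"REF == ALT ({ref}) in record {i + 1} of {path}")
            ident = rec.id or ""
            gene = ident.rsplit("_", 1)[0] if "_" in ident else ident
            if not gene:
                raise FormatError(f"record {i + 1} of {path} lacks a gene-bearing ID")
            rows.append((gene, rec.chrom, rec.pos, ref, alt))
    if skipped:
        logger.info("read_snp_vcf: skipped %d non-biallelic-SNP records", skipped)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    if len(snps) and snps.duplicated(["gene", "pos"]).any():
        raise FormatError("duplicate SNP position within a gene")
    return snps.sort_values(["gene", "pos"]).reset_index(drop=True)


def write_snp_vcf(snps: pd.DataFrame, path: str | Path) -> None:
    """Write a SnpTable as a minimal 8-column VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    counter: dict[str, int] = {}
    for _, row in snps.sort_values(["gene", "pos"]).iterrows():
        n = counter.get(row["gene"], 0) + 1
        counter[row["gene"]] = n
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{row['gene']}_{n}\t"
            f"{row['strain_a_base']}\t{row['strain_b_base']}\t.\t.\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# simple TSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])
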