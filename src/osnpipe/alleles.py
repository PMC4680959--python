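"""Allele-specific expression from strain-discriminating SNP read counts.

For a gene with SNPs distinguishing the two parental strains, reads
supporting each allele are summed across SNPs; the majority-allele
fraction p = max(sum A, sum B) / (sum A + sum B) quantifies allelic
purity.  Reads matching neither strain base (sequencing error) are
excluded from the denominator but reported.  A strain is called when the
informative read total reaches ``min_reads`` and p reaches
``call_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

ALLELE_COLUMNS = ["cell", "gene", "snp_id", "a_count", "b_count", "other_count"]


@dataclass
class AllelicCall:
    """Per (cell, gene) allelic summary."""

    cell: str
    gene: str
    n_informative: int
    majority_fraction: float  # p in [0.5, 1]
    strain: str  # "A" | "B" | "ambiguous" | "insufficient"
    other_fraction: float
    per_snp: pd.DataFrame

    @property
    def percent(self) -> float:
        """Majority fraction as a percentage, reported to 2 decimals."""
        return round(100.0 * self.majority_fraction, 2)


def validate_allele_counts(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(ALLELE_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigurationError(f"allele count table missing columns: {sorted(missing)}")
    if (table[["a_count", "b_count", "other_count"]] < 0).to_numpy().any():
        raise ConfigurationError("allele counts must be non-negative")
    return table


def allelic_purity(
    table: pd.DataFrame,
    gene: str,
    cell: str,
    min_reads: int = 20,
    call_threshold: float = 0.95,
) -> AllelicCall:
    """Allelic purity and strain call for one (cell, gene).

    Raises if the gene has no SNP rows for this cell.  With n informative
    reads (A + B summed over SNPs), p = max(sum A, sum B)/n; the call is
    the majority strain when n >= min_reads and p >= call_threshold,
    "insufficient" when n < min_reads, else "ambiguous".
    """
    validate_allele_counts(table)
    rows = table[(table["gene"] == gene) & (table["cell"] == cell)]
    if rows.empty:
        raise ConfigurationError(f"no informative SNPs for gene {gene!r} in cell {cell!r}")
    a, b = int(rows["a_count"].sum()), int(rows["b_count"].sum())
    other = int(rows["other_count"].sum())
    n = a + b
    if n == 0:
        strain, p = "insufficient", np.nan
    else:
        p = max(a, b) / n
        if n < min_reads:
            strain = "insufficient"
        elif p >= call_threshold:
            strain = "A" if a >= b else "B"
        else:
            strain = "ambiguous"
    per_snp = rows.assign(
        a_fraction=lambda d: d["a_count"] / (d["a_count"] + d["b_count"]).replace(0, np.nan)
    )[["snp_id", "a_count", "b_count", "other_count", "a_fraction"]].reset_index(drop=True)
    return AllelicCall(
        cell=cell,
        gene=gene,
        n_informative=n,
        majority_fraction=p,
        strain=strain,
        other_fraction=other / (n + other) if (n + other) else np.nan,
        per_snp=per_snp,
    )


def call_alleles(
    table: pd.DataFrame,
    receptor_calls: pd.DataFrame,
    min_reads: int = 20,
    call_threshold: float = 0.95,
) -> pd.DataFrame:
    """Allelic call for every cell with a single abundant intact OR.

    Cells whose abundant OR has no SNP rows are reported with strain
    ``no_informative_snps``.
    """
    validate_allele_counts(table)
    snp_genes = set(table["gene"].unique())
    rows = []
    for cell, rc in receptor_calls.iterrows():
        genes = [g for g in str(rc["abundant_intact"]).split(",") if g]
        if len(genes) != 1:
            continue
        gene = genes[0]
        if gene not in snp_genes or table[
            (table["gene"] == gene) & (table["cell"] == cell)
        ].empty:
            rows.append(
                {
                    "cell": cell,
                    "gene": gene,
                    "n_informative": 0,
                    "majority_fraction": np.nan,
                    "percent": np.nan,
                    "strain": "no_informative_snps",
                }
            )
            continue
        call = allelic_purity(table, gene, cell, min_reads, call_threshold)
        rows.append(
            {
                "cell": cell,
                "gene": gene,
                "n_informative": call.n_informative,
                "majority_fraction": call.majority_fraction,
                "percent": call.percent,
                "strain": call.strain,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell", "gene", "n_informative", "majority_fraction", "percent", "strain"],
    ).set_index("cell")


def strain_summary(calls: pd.DataFrame) -> dict:
    """Partition cells into {strain_a, strain_b, ambiguous, no_informative_snps}.

    Calls of "insufficient" depth are folded into the ambiguous bucket.
    """
    counts = calls["strain"].value_counts().to_dict()
    return {
        "strain_a": counts.get("A", 0),
        "strain_b": counts.get("B", 0),
        "ambiguous": counts.get("ambiguous", 0) + counts.get("insufficient", 0),
        "no_informative_snps": counts.get("no_informative_snps", 0),
    }
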