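"""Hierarchical single-cell quality control.

Criteria are evaluated in a fixed order; a cell passes only if it meets
every criterion, and each failing cell is attributed to the *first*
criterion it violates, so the per-criterion attributions partition the
failures.  The default thresholds are representative single-cell RNA-seq
cutoffs and are fully configurable — the hierarchy, not the particular
numbers, is the structural contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ConfigurationError

#: metrics a QCMetrics table must provide (fractions in [0, 1])
QC_METRICS = (
    "total_fragments",
    "mapped_fraction",
    "genes_detected",
    "ercc_fraction",
    "top_gene_fraction",
)


@dataclass(frozen=True)
class Criterion:
    """One ordered QC rule: metric `op` cutoff, where op is ">=" or "<=". """

    name: str
    metric: str
    op: str
    cutoff: float

    def passes(self, value: float) -> bool:
        if self.op == ">=":
            return value >= self.cutoff
        if self.op == "<=":
            return value <= self.cutoff
        raise ConfigurationError(f"criterion {self.name!r}: unknown comparator {self.op!r}")


DEFAULT_CRITERIA: tuple[Criterion, ...] = (
    Criterion("min_total_fragments", "total_fragments", ">=", 500_000),
    Criterion("min_mapped_fraction", "mapped_fraction", ">=", 0.5),
    Criterion("min_genes_detected", "genes_detected", ">=", 2_000),
    Criterion("max_ercc_fraction", "ercc_fraction", "<=", 0.2),
    Criterion("max_top_gene_fraction", "top_gene_fraction", "<=", 0.25),
)


def validate_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    missing = set(QC_METRICS) - set(metrics.columns)
    if missing:
        raise ConfigurationError(f"QC metrics table missing columns: {sorted(missing)}")
    for col in ("mapped_fraction", "ercc_fraction", "top_gene_fraction"):
        if ((metrics[col] < 0) | (metrics[col] > 1)).any():
            raise ConfigurationError(f"QC metric {col!r} outside [0, 1]")
    if (metrics[["total_fragments", "genes_detected"]] < 0).to_numpy().any():
        raise ConfigurationError("QC counts must be non-negative")
    return metrics


def qc_filter(
    metrics: pd.DataFrame, criteria: Sequence[Criterion] = DEFAULT_CRITERIA
) -> pd.DataFrame:
    """Apply ordered QC criteria; return per-cell decisions.

    ``metrics`` is indexed by cell id with the :data:`QC_METRICS` columns.
    The result has columns ``passed`` (bool), ``first_failed`` (criterion
    name or missing) and ``all_failed`` (comma-joined names).
    """
    validate_metrics(metrics)
    for crit in criteria:
        if crit.metric not in metrics.columns:
            raise ConfigurationError(
                f"criterion {crit.name!r} references unknown metric {crit.metric!r}"
            )
    rows = []
    for cell, row in metrics.iterrows():
        failed = [c.name for c in criteria if not c.passes(row[c.metric])]
        rows.append(
            {
                "cell": cell,
                "passed": not failed,
                "first_failed": failed[0] if failed else None,
                "all_failed": ",".join(failed) if failed else None,
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def qc_summary(decisions: pd.DataFrame) -> dict:
    """Pass/fail counts and the first-failure attribution per criterion."""
    attribution = decisions.loc[~decisions["passed"], "first_failed"].value_counts()
    return {
        "n_pass": int(decisions["passed"].sum()),
        "n_fail": int((~decisions["passed"]).sum()),
        "attribution": attribution.to_dict(),
    }
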