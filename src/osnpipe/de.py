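"""Negative-binomial differential expression and coexpression signatures.

The DE engine is a two-group NB Wald test: per gene, a method-of-moments
dispersion is estimated from the pooled within-group variance of
normalized counts, the log2 fold change of group means is tested against
zero with a delta-method standard error, and Benjamini-Hochberg step-up
adjusts for multiple testing.  This preserves the statistical contract
(type-I error, FDR control) of a standard NB Wald analysis without
cross-gene dispersion shrinkage; genes below a mean-count floor get a
missing adjusted p-value.

The module also hosts the CV-based variable-gene screen, the
unique-coexpression signature of a cell pair, and the exhaustive
pairwise scan used to discover minority cell types.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .io import CountMatrix
from .normalize import normalize, size_factors

DE_COLUMNS = ["gene", "baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing values pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass
class DEConfig:
    """DE engine controls."""

    min_base_mean: float = 1.0  # below this, padj is set missing
    dispersion_floor: float = 1e-8
    pseudocount: float = 0.5  # stabilises fold changes at zero means

    def __post_init__(self) -> None:
        if self.min_base_mean < 0 or self.dispersion_floor <= 0 or self.pseudocount <= 0:
            raise ConfigurationError("invalid DEConfig value")


class NegativeBinomialDE:
    """Two-group NB Wald differential-expression model.

    Parameters
    ----------
    counts
        Raw counts (CountMatrix or gene x sample DataFrame).
    group_a, group_b
        Disjoint sample-id lists, each of size >= 2.  The reported fold
        change is group A over group B.
    factors
        Optional precomputed size factors covering both groups; computed
        by median-of-ratios on the combined groups if omitted.
    """

    def __init__(self, counts, group_a, group_b, factors: pd.Series | None = None):
        values = counts.values if isinstance(counts, CountMatrix) else counts
        group_a, group_b = list(group_a), list(group_b)
        if set(group_a) & set(group_b):
            raise ConfigurationError("groups overlap")
        if len(group_a) < 2 or len(group_b) < 2:
            raise ConfigurationError("each group needs at least 2 samples")
        missing = (set(group_a) | set(group_b)) - set(values.columns)
        if missing:
            raise ConfigurationError(f"unknown samples: {sorted(missing)}")
        self.counts = values[group_a + group_b]
        self.group_a, self.group_b = group_a, group_b
        if factors is None:
            factors = size_factors(self.counts, exclude_spikeins=False)
        self.factors = factors.reindex(self.counts.columns)

    def fit(self, config: DEConfig | None = None) -> "DEResults":
        config = config or DEConfig()
        x = normalize(self.counts, self.factors)
        a = x[self.group_a].to_numpy()
        b = x[self.group_b].to_numpy()
        na, nb = a.shape[1], b.shape[1]
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        base_mean = x.to_numpy().mean(axis=1)

        # method-of-moments dispersion from pooled within-group variance:
        # Var(c/s) = mu/s + alpha*mu^2, averaged over samples
        ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
        ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
        var_w = (ssa + ssb) / max(na + nb - 2, 1)
        xi = float(np.mean(1.0 / self.factors.to_numpy()))
        mu = np.maximum(base_mean, config.pseudocount)
        alpha = np.maximum((var_w - mu * xi) / mu**2, config.dispersion_floor)

        eps = config.pseudocount
        lfc = np.log2((ma + eps) / (mb + eps))
        inv_sa = float(np.mean(1.0 / self.factors[self.group_a].to_numpy()))
        inv_sb = float(np.mean(1.0 / self.factors[self.group_b].to_numpy()))
        var_ma = (ma * inv_sa + alpha * ma**2) / na
        var_mb = (mb * inv_sb + alpha * mb**2) / nb
        se = np.sqrt(var_ma / (ma + eps) ** 2 + var_mb / (mb + eps) ** 2) / np.log(2)
        se = np.maximum(se, 1e-12)
        stat = lfc / se
        pvalue = 2.0 * scipy.stats.norm.sf(np.abs(stat))
        padj = bh_adjust(np.where(base_mean >= config.min_base_mean, pvalue, np.nan))

        frame = pd.DataFrame(
            {
                "gene": self.counts.index,
                "baseMean": base_mean,
                "log2FoldChange": lfc,
                "lfcSE": se,
                "stat": stat,
                "pvalue": pvalue,
                "padj": padj,
            }
        )
        return DEResults(model=self, frame=frame, config=config)


@dataclass
class DEResults:
    """DE estimates per gene with the standard result columns."""

    model: NegativeBinomialDE
    frame: pd.DataFrame
    config: DEConfig = field(default_factory=DEConfig)

    def classify(
        self, fc_up: float = 3.0, fc_down: float = 1.0 / 3.0, fdr: float = 0.05
    ) -> tuple[set, set]:
        """Significant up/down gene sets at linear fold-change thresholds."""
        f = self.frame
        sig = f["padj"] < fdr
        fc = 2.0 ** f["log2FoldChange"]
        up = set(f.loc[sig & (fc > fc_up), "gene"])
        down = set(f.loc[sig & (fc < fc_down), "gene"])
        return up, down

    def significant(self, fdr: float = 0.05) -> set:
        f = self.frame
        return set(f.loc[f["padj"] < fdr, "gene"])

    def summary(self, fdr: float = 0.05) -> str:
        f = self.frame
        n_sig = int((f["padj"] < fdr).sum())
        return "\n".join(
            [
                "Two-group negative-binomial Wald test",
                f"  genes tested:     {len(f)} ({int(f['padj'].isna().sum())} below mean floor)",
                f"  group sizes:      {len(self.model.group_a)} vs {len(self.model.group_b)}",
                f"  significant (FDR<{fdr:g}): {n_sig}",
            ]
        )


def de_test(
    counts,
    group_a,
    group_b,
    factors: pd.Series | None = None,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Functional wrapper returning the DE result frame."""
    return NegativeBinomialDE(counts, group_a, group_b, factors).fit(config).frame


def de_classify(frame: pd.DataFrame, fc_up=3.0, fc_down=1.0 / 3.0, fdr=0.05):
    """Up/down gene sets from a DE result frame (linear-scale thresholds)."""
    sig = frame["padj"] < fdr
    fc = 2.0 ** frame["log2FoldChange"]
    up = set(frame.loc[sig & (fc > fc_up), "gene"])
    down = set(frame.loc[sig & (fc < fc_down), "gene"])
    return up, down


# ---------------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------------

def cv_variable_genes(
    normalized: pd.DataFrame,
    min_max_count: float = 1000.0,
    cv_cutoff: float = 4.0,
) -> pd.DataFrame:
    """CV screen for heterogeneously expressed genes across single cells.

    Eligibility: maximum normalized count across cells >= min_max_count.
    CV = sample (n-1) standard deviation / mean; selected iff CV >
    cv_cutoff.  Each selected gene is attributed to the cell where it is
    maximal.
    """
    if normalized.shape[1] < 2:
        raise ConfigurationError("cv_variable_genes requires at least 2 cells")
    arr = normalized.to_numpy(dtype=float)
    eligible = arr.max(axis=1) >= min_max_count
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    out = pd.DataFrame(
        {
            "gene": normalized.index,
            "mean": mean,
            "sd": sd,
            "cv": cv,
            "eligible": eligible,
            "selected": eligible & (cv > cv_cutoff),
            "top_cell": normalized.columns[arr.argmax(axis=1)],
        }
    ).set_index("gene")
    return out


# ---------------------------------------------------------------------------
# unique coexpression and the pairwise scan
# ---------------------------------------------------------------------------

def unique_coexpression_signature(
    normalized: pd.DataFrame,
    pair: tuple,
    de_genes,
    high_cutoff: float = 100.0,
    low_cutoff: float = 10.0,
) -> set:
    """Genes from ``de_genes`` highly expressed only in the pair.

    A gene qualifies iff its normalized counts are >= high_cutoff in both
    pair cells and < low_cutoff in every other cell.
    """
    if high_cutoff <= low_cutoff or low_cutoff < 0:
        raise ConfigurationError("need high_cutoff > low_cutoff >= 0")
    pair = list(pair)
    rest = [c for c in normalized.columns if c not in pair]
    if len(set(pair)) != 2 or not set(pair) <= set(normalized.columns):
        raise ConfigurationError("pair must be two distinct cells of the matrix")
    genes = [g for g in de_genes if g in normalized.index]
    if not genes:
        return set()
    sub = normalized.loc[genes]
    in_pair = (sub[pair] >= high_cutoff).all(axis=1)
    out_rest = (sub[rest] < low_cutoff).all(axis=1) if rest else True
    return set(sub.index[in_pair & out_rest])


@dataclass
class PairScanConfig:
    """Pairwise unique-coexpression scan controls."""

    fdr: float = 0.05
    high_cutoff: float = 100.0
    low_cutoff: float = 10.0
    flag_ratio: float = 2.0
    de: DEConfig = field(default_factory=DEConfig)


@dataclass
class PairSharingResult:
    """Ranked unique-coexpression counts over all unordered cell pairs."""

    frame: pd.DataFrame  # columns: cell1, cell2, n_shared; sorted descending
    top_pair: tuple
    ratio_top_to_second: float
    distinct_cell_type: bool

    @property
    def n_pairs(self) -> int:
        return len(self.frame)


def pairwise_sharing_scan(
    counts,
    factors: pd.Series | None = None,
    config: PairScanConfig | None = None,
) -> PairSharingResult:
    """Evaluate every unordered cell pair for uniquely coexpressed genes.

    For each of the C(n, 2) pairs: test the pair against the remaining
    cells with the NB Wald engine, then count significant genes highly
    expressed only in the pair.  The top pair is flagged as a candidate
    distinct cell type when its count exceeds ``flag_ratio`` times the
    second-best count.
    """
    config = config or PairScanConfig()
    values = counts.values if isinstance(counts, CountMatrix) else counts
    cells = list(values.columns)
    if len(cells) < 4:
        raise ConfigurationError(
            "pairwise scan requires at least 4 cells (a pair and a rest group of >= 2)"
        )
    if factors is None:
        factors = size_factors(values, exclude_spikeins=False, min_mean=1.0)
    normalized = normalize(values, factors)
    rows = []
    for c1, c2 in itertools.combinations(cells, 2):
        rest = [c for c in cells if c not in (c1, c2)]
        frame = de_test(values, [c1, c2], rest, factors=factors, config=config.de)
        sig = set(frame.loc[frame["padj"] < config.fdr, "gene"])
        shared = unique_coexpression_signature(
            normalized, (c1, c2), sig, config.high_cutoff, config.low_cutoff
        )
        rows.append({"cell1": c1, "cell2": c2, "n_shared": len(shared)})
    frame = (
        pd.DataFrame(rows)
        .sort_values(["n_shared", "cell1", "cell2"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    top = frame.iloc[0]
    second = frame["n_shared"].iloc[1] if len(frame) > 1 else 0
    ratio = float(top["n_shared"] / second) if second > 0 else np.inf
    return PairSharingResult(
        frame=frame,
        top_pair=(top["cell1"], top["cell2"]),
        ratio_top_to_second=ratio,
        distinct_cell_type=bool(ratio > config.flag_ratio and top["n_shared"] > 0),
    )
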