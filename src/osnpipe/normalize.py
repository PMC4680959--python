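"""Median-of-ratios size factors and count normalization.

The size factor for sample *j* is the median, over genes expressed in
every sample, of the ratio of that gene's count in *j* to its geometric
mean across samples.  Normalized counts are raw counts divided by the
sample's factor.  For single cells, spike-ins are excluded and the gene
set may additionally be restricted to genes above a mean-count floor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import CountMatrix

logger = logging.getLogger(__name__)


def size_factors(
    counts: CountMatrix | pd.DataFrame,
    exclude_spikeins: bool = True,
    min_mean: float = 0.0,
) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Genes with a zero count in any sample are excluded from the median
    (strict rule, no pseudo-reference); ``min_mean`` optionally restricts
    the reference gene set further to genes whose mean raw count reaches
    the floor, which stabilises factors for sparse single cells.
    """
    if isinstance(counts, CountMatrix):
        if exclude_spikeins:
            counts = counts.drop_spikeins()
        values = counts.values
    else:
        values = counts
        if exclude_spikeins:
            spike = values.index.map(lambda g: str(g).startswith("ERCC-"))
            values = values.loc[~np.asarray(spike, dtype=bool)]
    if values.shape[1] < 2:
        raise ConfigurationError("size_factors requires at least 2 samples")
    arr = values.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    if min_mean > 0:
        eligible &= arr.mean(axis=1) >= min_mean
    if not eligible.any():
        raise ConfigurationError(
            "no gene has nonzero counts in every sample; "
            "pseudo-reference fallback is disabled — lower min_mean or pre-filter"
        )
    ref = arr[eligible]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=values.columns, name="size_factor")


def normalize(
    counts: CountMatrix | pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    values = counts.values if isinstance(counts, CountMatrix) else counts
    if set(factors.index) != set(values.columns):
        raise ConfigurationError("size factors do not match the sample set")
    if not np.isfinite(factors).all() or (factors <= 0).any():
        raise ConfigurationError("size factors must be finite and positive")
    return values / factors.reindex(values.columns)


def log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """Display transform: log10(normalized counts + 1)."""
    return np.log10(normalized + 1.0)


def sample_similarity(normalized: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Sample x sample rank-correlation matrix (Spearman, average ranks).

    A constant sample yields undefined correlations, reported as missing.
    """
    if normalized.shape[1] < 2:
        raise ConfigurationError("sample_similarity requires at least 2 samples")
    if method != "spearman":
        raise ConfigurationError(f"unsupported similarity method {method!r}")
    arr = normalized.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "sample_similarity: %d constant sample(s); correlations set to missing",
            int(constant.sum()),
        )
    out = normalized.corr(method="spearman")  # average ranks, NaN for constants
    np.fill_diagonal(out.values, 1.0)
    return out
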