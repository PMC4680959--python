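"""Per-cell receptor classification: the monogenicity engine.

An OR (or TAAR) *expression event* is a (cell, gene) pair with at least
one mapped fragment.  Events whose fragments cover less than one third
of the gene are discarded as likely mismapping or non-specific
transcription.  The retained events, pooled over all cells, are
deconvolved into a low- and a high-abundance Gaussian class on the log10
scale (:mod:`osnpipe.mixture`); a single global intersection threshold
tau then labels an OR "abundant" in a cell iff its normalized counts are
at or above tau.  A cell with exactly one abundant intact OR is
monogenic; with none of any status, receptorless; otherwise
coexpressing.  Abundant pseudogenes flag pseudogene coexpression but do
not break monogenicity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError
from .mixture import AbundanceMixtureResults, EMConfig, fit_mixture

logger = logging.getLogger(__name__)

#: minimum covered fraction of the gene length for a credible event
COVERAGE_MIN_FRACTION = 1.0 / 3.0

EVENT_COLUMNS = ["cell", "gene", "normalized_counts", "coverage"]


def or_expression_events(
    normalized: pd.DataFrame,
    coverage: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Build the event table for receptor-category genes.

    ``coverage`` holds per-(cell, gene) covered fractions for genes with
    mapped fragments.  Only OR and TAAR category genes with normalized
    counts > 0 become events; a receptor event without a coverage record
    is an error.
    """
    receptor_genes = annotation.loc[
        annotation["category"].isin(["OR", "TAAR"]), "gene"
    ]
    sub = normalized.loc[normalized.index.intersection(receptor_genes)]
    stacked = sub.stack()
    stacked = stacked[stacked > 0]
    events = stacked.rename("normalized_counts").reset_index()
    events.columns = ["gene", "cell", "normalized_counts"]
    cov = coverage.set_index(["cell", "gene"])["coverage"]
    key = pd.MultiIndex.from_frame(events[["cell", "gene"]])
    events["coverage"] = cov.reindex(key).to_numpy()
    if events["coverage"].isna().any():
        bad = events.loc[events["coverage"].isna()].iloc[0]
        raise FormatError(
            f"no coverage fraction for event cell={bad['cell']!r} gene={bad['gene']!r}"
        )
    return events[EVENT_COLUMNS].sort_values(["cell", "gene"]).reset_index(drop=True)


def coverage_filter(events: pd.DataFrame) -> pd.DataFrame:
    """Drop events covering less than one third of the gene length."""
    if events["coverage"].isna().any():
        bad = events.loc[events["coverage"].isna()].iloc[0]
        raise FormatError(
            f"missing coverage fraction for event cell={bad['cell']!r} gene={bad['gene']!r}"
        )
    if ((events["coverage"] < 0) | (events["coverage"] > 1)).any():
        raise FormatError("coverage fractions must lie in [0, 1]")
    keep = events["coverage"] >= COVERAGE_MIN_FRACTION
    logger.info(
        "coverage_filter: removed %d of %d events (<1/3 covered)",
        int((~keep).sum()),
        len(events),
    )
    return events.loc[keep].reset_index(drop=True)


def classify_cells(
    events: pd.DataFrame,
    tau: float,
    annotation: pd.DataFrame,
    cells: list | None = None,
) -> pd.DataFrame:
    """Classify each cell by its abundant receptors relative to tau.

    "Abundant" means normalized counts >= tau (at-or-above).  Returns one
    row per cell: class (monogenic | coexpressing | receptorless), the
    abundant intact / pseudogene OR lists, background OR count, the
    pseudogene-coexpression flag, and the dominance ratio (top abundant
    intact OR over the next intact OR of any abundance; infinite when
    there is no second intact OR event).
    """
    if tau <= 0:
        raise ConfigurationError("tau must be > 0")
    status = annotation.set_index("gene")["status"]
    cells = list(cells) if cells is not None else sorted(events["cell"].unique())
    rows = []
    grouped = dict(tuple(events.groupby("cell")))
    for cell in cells:
        ev = grouped.get(cell)
        if ev is None or ev.empty:
            rows.append(
                {
                    "cell": cell,
                    "class": "receptorless",
                    "abundant_intact": "",
                    "abundant_pseudo": "",
                    "n_abundant": 0,
                    "n_background": 0,
                    "pseudogene_coexpression": False,
                    "dominance_ratio": np.nan,
                }
            )
            continue
        ev = ev.sort_values("normalized_counts", ascending=False)
        ev_status = status.reindex(ev["gene"]).to_numpy()
        abundant = ev["normalized_counts"].to_numpy() >= tau
        intact = ev_status == "intact"
        ab_intact = ev.loc[abundant & intact, "gene"].tolist()
        ab_pseudo = ev.loc[abundant & ~intact, "gene"].tolist()
        n_abundant = len(ab_intact) + len(ab_pseudo)
        if n_abundant == 0:
            cls = "receptorless"
        elif len(ab_intact) == 1:
            cls = "monogenic"
        else:
            cls = "coexpressing"
        intact_counts = ev.loc[intact, "normalized_counts"].to_numpy()
        if len(ab_intact) >= 1 and intact_counts.size >= 2:
            dominance = float(intact_counts[0] / intact_counts[1])
        elif len(ab_intact) >= 1:
            dominance = np.inf
        else:
            dominance = np.nan
        rows.append(
            {
                "cell": cell,
                "class": cls,
                "abundant_intact": ",".join(ab_intact),
                "abundant_pseudo": ",".join(ab_pseudo),
                "n_abundant": n_abundant,
                "n_background": int((~abundant).sum()),
                "pseudogene_coexpression": bool(ab_pseudo),
                "dominance_ratio": dominance,
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def call_receptors(
    normalized: pd.DataFrame,
    coverage: pd.DataFrame,
    annotation: pd.DataFrame,
    em_config: EMConfig | None = None,
) -> tuple[pd.DataFrame, AbundanceMixtureResults]:
    """Full receptor-calling pipeline for one cohort.

    Builds events, applies the coverage filter, fits the pooled mixture
    on log10 counts, derives tau, and classifies every cell (cells with
    no retained events are receptorless).  Returns (calls, mixture fit).
    """
    events = or_expression_events(normalized, coverage, annotation)
    retained = coverage_filter(events)
    fit = fit_mixture(np.log10(retained["normalized_counts"]), em_config)
    tau = fit.intersection()
    calls = classify_cells(retained, tau, annotation, cells=list(normalized.columns))
    return calls, fit
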