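import numpy as np
import pandas as pd
import pytest

from osnpipe.exceptions import ConfigurationError, FormatError
from osnpipe.receptors import (
    classify_cells,
    coverage_filter,
    or_expression_events,
)

ANN = pd.DataFrame(
    {
        "gene": ["OrA", "OrB", "OrC", "OrPs", "Omp"],
        "symbol": ["OrA", "OrB", "OrC", "OrPs", "Omp"],
        "category": ["OR", "OR", "OR", "OR", "marker"],
        "status": ["intact", "intact", "intact", "pseudogene", "intact"],
        "or_class": ["II", "II", "II", "II", None],
        "length": [1000, 1000, 1000, 1000, 2000],
    }
)


def events_frame(rows):
    return pd.DataFrame(rows, columns=["cell", "gene", "normalized_counts", "coverage"])


@pytest.mark.parametrize(
    "coverage,kept",
    [(0.30, False), (0.34, True), (1.0, True), (0.0, False), (1 / 3, True)],
)
def test_coverage_filter_one_third_rule(coverage, kept):
    ev = events_frame([("c1", "OrA", 100.0, coverage)])
    out = coverage_filter(ev)
    assert (len(out) == 1) == kept


def test_missing_coverage_names_event():
    ev = events_frame([("c1", "OrA", 100.0, np.nan)])
    with pytest.raises(FormatError, match="OrA"):
        coverage_filter(ev)


def test_event_table_excludes_zero_counts_and_non_receptors():
    norm = pd.DataFrame(
        {"c1": [500.0, 0.0, 9.0, 100.0]},
        index=["OrA", "OrB", "OrC", "Omp"],
    )
    cov = pd.DataFrame(
        {"cell": ["c1", "c1"], "gene": ["OrA", "OrC"], "coverage": [0.9, 0.2]}
    )
    ev = or_expression_events(norm, cov, ANN)
    assert set(ev["gene"]) == {"OrA", "OrC"}  # no zero-count OrB, no marker


def test_monogenic_call_with_high_dominance():
    rows = [("c1", "OrA", 36_000.0, 0.95)]
    rows += [("c1", f"OrB", 16.0, 0.5)]
    ev = events_frame(rows)
    calls = classify_cells(ev, tau=855.0, annotation=ANN)
    assert calls.loc["c1", "class"] == "monogenic"
    assert calls.loc["c1", "dominance_ratio"] > 1000


def test_pseudogene_exactly_at_threshold_is_abundant_but_not_breaking():
    """An abundant pseudogene at exactly tau sets the coexpression flag
    while the cell stays monogenic (at-or-above counts as abundant)."""
    ev = events_frame(
        [("c1", "OrA", 30_000.0, 0.95), ("c1", "OrPs", 855.0, 0.8)]
    )
    calls = classify_cells(ev, tau=855.0, annotation=ANN)
    assert calls.loc["c1", "class"] == "monogenic"
    assert calls.loc["c1", "pseudogene_coexpression"]
    assert calls.loc["c1", "n_abundant"] == 2


def test_two_abundant_intact_is_coexpressing():
    ev = events_frame([("c1", "OrA", 30_000.0, 0.95), ("c1", "OrB", 5000.0, 0.9)])
    assert classify_cells(ev, 855.0, ANN).loc["c1", "class"] == "coexpressing"


def test_no_or_above_tau_is_receptorless():
    ev = events_frame([("c1", "OrA", 100.0, 0.9)])
    calls = classify_cells(ev, 855.0, ANN)
    assert calls.loc["c1", "class"] == "receptorless"
    assert calls.loc["c1", "n_background"] == 1


def test_cell_without_events_is_receptorless():
    ev = events_frame([("c1", "OrA", 5000.0, 0.9)])
    calls = classify_cells(ev, 855.0, ANN, cells=["c1", "c2"])
    assert calls.loc["c2", "class"] == "receptorless"


def test_nonpositive_tau_rejected():
    with pytest.raises(ConfigurationError, match="tau"):
        classify_cells(events_frame([]), 0.0, ANN)


def test_raising_tau_never_increases_abundant_counts(rng):
    """Threshold consistency over random event tables."""
    rows = [
        (f"c{rng.integers(5)}", f"Or{g}", float(10 ** rng.uniform(0, 5)), 0.9)
        for g in range(40)
    ]
    ann = pd.DataFrame(
        {
            "gene": [f"Or{g}" for g in range(40)],
            "symbol": [f"Or{g}" for g in range(40)],
            "category": "OR",
            "status": "intact",
            "or_class": "II",
            "length": 1000,
        }
    )
    ev = events_frame(rows)
    taus = [10.0, 100.0, 1000.0, 10_000.0]
    per_tau = [classify_cells(ev, t, ann)["n_abundant"] for t in taus]
    for lo, hi in zip(per_tau, per_tau[1:]):
        assert (hi.reindex(lo.index).fillna(0) <= lo).all()


def test_cohort21_classification_recovers_truth(cohort21, cohort21_calls):
    """Full-pipeline recovery of the generator's per-cell classes."""
    calls, fit = cohort21_calls
    truth = cohort21.truth.cells.set_index("cell")
    expected = truth["true_class"].map(
        {"canonical": "monogenic", "typeB": "receptorless"}
    )
    assert (calls["class"] == expected.reindex(calls.index)).all()
    # each monogenic cell names its true abundant OR
    mono = calls[calls["class"] == "monogenic"]
    assert (mono["abundant_intact"] == truth.loc[mono.index, "true_or"]).all()
    assert fit.converged
    assert fit.separation > 2
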