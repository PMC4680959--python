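import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import osnpipe as op
from osnpipe.de import (
    DEConfig,
    NegativeBinomialDE,
    PairScanConfig,
    bh_adjust,
    cv_variable_genes,
    de_classify,
    de_test,
    pairwise_sharing_scan,
    unique_coexpression_signature,
)
from osnpipe.exceptions import ConfigurationError


def nb_counts(rng, means, n, alpha=0.1):
    lam = rng.gamma(1 / alpha, alpha * np.asarray(means)[:, None] * np.ones(n))
    return rng.poisson(lam)


# -- BH ----------------------------------------------------------------------

def test_bh_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert bh_adjust([0.3])[0] == 0.3


def test_bh_permutation_invariance_and_dominance(rng):
    p = rng.random(50)
    perm = rng.permutation(50)
    adj = bh_adjust(p)
    assert np.allclose(adj[perm], bh_adjust(p[perm]))
    assert (adj >= p).all()
    assert (adj <= 1).all()


def test_bh_missing_passthrough_and_range_check():
    out = bh_adjust([0.01, np.nan, 0.02])
    assert np.isnan(out[1]) and not np.isnan(out[0])
    with pytest.raises(ConfigurationError, match="0, 1"):
        bh_adjust([1.5])


# -- NB Wald DE --------------------------------------------------------------

def test_identical_groups_give_zero_fold_change(rng):
    base = nb_counts(rng, np.full(100, 50.0), 3)
    counts = pd.DataFrame(
        np.hstack([base, base]),
        index=[f"g{i}" for i in range(100)],
        columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
    )
    frame = de_test(counts, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)])
    assert np.allclose(frame["log2FoldChange"], 0.0)


def test_null_type_one_error_calibrated():
    """10 vs 10, NB(mean 100, dispersion 0.1), 2,000 genes: the fraction
    of p < 0.05 lies in [0.03, 0.07] and p-values are near-uniform."""
    rng = np.random.default_rng(123)
    counts = pd.DataFrame(
        nb_counts(rng, np.full(2000, 100.0), 20),
        index=[f"g{i}" for i in range(2000)],
        columns=[f"s{i}" for i in range(20)],
    )
    frame = de_test(counts, [f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)])
    frac = (frame["pvalue"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07
    assert scipy.stats.kstest(frame["pvalue"], "uniform").statistic < 0.05


def test_power_detects_spiked_eightfold_genes():
    """100 genes with a true 8-fold change at mean 500, 6 vs 6: at least
    90 are recovered at padj < 0.05."""
    rng = np.random.default_rng(7)
    means_a = np.full(2000, 500.0)
    means_a[:100] *= 8
    counts = pd.DataFrame(
        np.hstack([nb_counts(rng, means_a, 6), nb_counts(rng, np.full(2000, 500.0), 6)]),
        index=[f"g{i}" for i in range(2000)],
        columns=[f"s{i}" for i in range(12)],
    )
    frame = de_test(counts, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)])
    spiked = frame.iloc[:100]
    assert (spiked["padj"] < 0.05).sum() >= 90
    up, _ = de_classify(frame, fc_up=3)
    assert len(up & set(spiked["gene"])) >= 90


def test_low_mean_genes_get_missing_padj(rng):
    counts = pd.DataFrame(
        np.vstack([nb_counts(rng, [100.0], 8), np.zeros((1, 8), dtype=int)]),
        index=["hi", "lo"],
        columns=[f"s{i}" for i in range(8)],
    )
    counts.loc["lo", "s0"] = 1  # baseMean well below 1
    frame = de_test(counts, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]).set_index("gene")
    assert np.isnan(frame.loc["lo", "padj"])
    assert not np.isnan(frame.loc["lo", "pvalue"])


def test_group_contract_errors(small_counts):
    with pytest.raises(ConfigurationError, match="overlap"):
        NegativeBinomialDE(small_counts, ["s1"], ["s1"])
    with pytest.raises(ConfigurationError, match="at least 2"):
        NegativeBinomialDE(small_counts, ["s1"], ["s2"])


def test_de_classify_thresholds():
    frame = pd.DataFrame(
        {
            "gene": ["up4", "mid2", "down"],
            "log2FoldChange": [2.0, 1.0, -2.0],
            "padj": [0.01, 0.01, 0.01],
        }
    )
    up, down = de_classify(frame)
    assert up == {"up4"}      # FC 4 > 3
    assert "mid2" not in up   # FC 2 below the cutoff
    assert down == {"down"}   # FC 0.25 < 1/3


# -- CV variable genes -------------------------------------------------------

def test_cv_constant_gene_not_selected():
    norm = pd.DataFrame({f"c{i}": [2000.0] for i in range(5)}, index=["g"])
    out = cv_variable_genes(norm)
    assert out.loc["g", "cv"] == 0.0
    assert not out.loc["g", "selected"]


def test_cv_hand_computed_example():
    """(1000, 0 x 20) over 21 cells: mean 47.62, sample SD 218.2, CV 4.58."""
    vals = [1000.0] + [0.0] * 20
    norm = pd.DataFrame([vals], index=["g"], columns=[f"c{i}" for i in range(21)])
    out = cv_variable_genes(norm)
    assert np.isclose(out.loc["g", "mean"], 47.619, atol=1e-3)
    assert np.isclose(out.loc["g", "sd"], 218.218, atol=1e-2)
    assert np.isclose(out.loc["g", "cv"], 4.5826, atol=1e-3)
    assert out.loc["g", "selected"]
    assert out.loc["g", "top_cell"] == "c0"


def test_cv_eligibility_gate():
    norm = pd.DataFrame([[999.0] + [0.0] * 20], index=["g"],
                        columns=[f"c{i}" for i in range(21)])
    assert not cv_variable_genes(norm).loc["g", "eligible"]


@settings(derandomize=True, max_examples=25, deadline=None)
@given(k=st.floats(1.0, 50.0), seed=st.integers(0, 1000))
def test_cv_scale_free_modulo_gate(k, seed):
    rng = np.random.default_rng(seed)
    norm = pd.DataFrame(rng.gamma(2, 400, size=(20, 6)),
                        columns=[f"c{i}" for i in range(6)])
    a = cv_variable_genes(norm, min_max_count=0)
    b = cv_variable_genes(norm * k, min_max_count=0)
    assert np.allclose(a["cv"], b["cv"])


# -- unique coexpression and pair scan ---------------------------------------

def test_unique_coexpression_enumeration_oracle():
    cells = [f"c{i}" for i in range(5)]
    norm = pd.DataFrame(0.0, index=[f"g{i}" for i in range(4)], columns=cells)
    norm.loc[["g0", "g1", "g2"], ["c0", "c1"]] = 500.0
    norm.loc["g3", ["c0", "c1", "c2"]] = 500.0  # leaks into a third cell
    sig = unique_coexpression_signature(norm, ("c0", "c1"), list(norm.index),
                                        high_cutoff=100, low_cutoff=10)
    assert sig == {"g0", "g1", "g2"}


def test_unique_coexpression_empty_de_genes():
    norm = pd.DataFrame(np.ones((3, 4)), columns=[f"c{i}" for i in range(4)])
    assert unique_coexpression_signature(norm, ("c0", "c1"), []) == set()


def test_pair_scan_counts_all_pairs_and_flags_planted_pair(rng):
    """6 cells, 2 with a private signature: C(6,2)=15 pairs, the planted
    pair on top with ratio above the flag threshold."""
    cells = [f"c{i}" for i in range(6)]
    counts = pd.DataFrame(
        nb_counts(rng, np.full(300, 50.0), 6, alpha=0.05),
        index=[f"g{i}" for i in range(300)], columns=cells,
    )
    counts.iloc[:12, :] = rng.poisson(5, size=(12, 6))
    counts.iloc[:12, 4:] = rng.poisson(800, size=(12, 2))  # c4+c5 signature
    result = pairwise_sharing_scan(counts)
    assert result.n_pairs == 15
    assert set(result.top_pair) == {"c4", "c5"}
    assert result.distinct_cell_type


def test_pair_scan_too_few_cells_is_error(small_counts):
    with pytest.raises(ConfigurationError, match="at least 4"):
        pairwise_sharing_scan(small_counts)


def test_cohort21_scan_finds_type_b_pair(cohort21, cohort21_normalized):
    """On the 21-cell cohort the scan evaluates 210 pairs and the two
    type-B cells share over twice as many unique genes as any other pair."""
    factors, _ = cohort21_normalized
    result = pairwise_sharing_scan(cohort21.counts.drop_spikeins().values,
                                   factors=factors)
    assert result.n_pairs == 210
    typeb = set(cohort21.truth.cells.query("true_class == 'typeB'")["cell"])
    assert set(result.top_pair) == typeb
    assert result.ratio_top_to_second > 2
    assert result.distinct_cell_type
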