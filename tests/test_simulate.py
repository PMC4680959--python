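import numpy as np
import pandas as pd
import pytest

import osnpipe as op
from osnpipe.exceptions import ConfigurationError
from osnpipe.simulate import (
    SimConfig,
    _cc_profile,
    cellcycle_gene_ids,
    generate_cohort,
    generate_reference_cellcycle,
    preset_config,
)


def test_cohort21_truth_has_19_canonical_cells(cohort21):
    classes = cohort21.truth.cells["true_class"].value_counts()
    assert classes["canonical"] == 19
    assert classes["typeB"] == 2


def test_determinism_byte_identical():
    a = generate_cohort(preset_config("cohort21", seed=3))
    b = generate_cohort(preset_config("cohort21", seed=3))
    pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
    pd.testing.assert_frame_equal(a.coverage, b.coverage)
    pd.testing.assert_frame_equal(a.allele_counts, b.allele_counts)
    pd.testing.assert_frame_equal(a.qc_metrics, b.qc_metrics)


def test_empty_cohort_degenerate_size():
    c = generate_cohort(SimConfig(n_cells=0, n_canonical=0, n_typeB=0))
    assert c.counts.values.shape[1] == 0
    assert len(c.truth.cells) == 0
    assert len(c.qc_metrics) == 0


@pytest.mark.parametrize(
    "kw,fieldname",
    [
        (dict(n_cells=5, n_canonical=4, n_typeB=2), "n_canonical"),
        (dict(allelic_purity=0.4), "allelic_purity"),
        (dict(high_mean_counts=-1.0), "high_mean_counts"),
        (dict(background_or_range=(10, 5)), "background_or_range"),
        (dict(qc_fail_profile=(("nonsense", 1.0),)), "nonsense"),
    ],
)
def test_invalid_config_names_field(kw, fieldname):
    with pytest.raises(ConfigurationError, match=fieldname):
        SimConfig(**kw)


def test_abundant_or_mean_recovers_configured_level():
    """Monte-Carlo: the sample mean of abundant-OR normalized counts sits
    within 3 standard errors of the configured high mean."""
    cfg = SimConfig(seed=7, n_cells=50, n_canonical=50, n_typeB=0)
    c = generate_cohort(cfg)
    factors = op.size_factors(c.counts, min_mean=1.0)
    norm = op.normalize(c.counts.drop_spikeins(), factors)
    truth = c.truth.cells
    vals = np.array(
        [norm.loc[r["true_or"], r["cell"]] for _, r in truth.iterrows()]
    )
    # independent recomputation of the sample mean
    assert np.isclose(vals.mean(), sum(vals) / len(vals))
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - cfg.high_mean_counts) < 3 * se


def test_abundant_or_dominates_by_three_orders(cohort21, cohort21_normalized):
    """In expectation the abundant OR exceeds the next OR by >= 3 orders
    of magnitude; per-cell raw counts dominate by large margins."""
    _, norm = cohort21_normalized
    ors = cohort21.annotation.loc[cohort21.annotation["category"] == "OR", "gene"]
    sub = norm.loc[norm.index.intersection(ors)]
    truth = cohort21.truth.cells.query("true_class == 'canonical'")
    ratios = []
    for _, r in truth.iterrows():
        col = sub[r["cell"]].sort_values(ascending=False)
        assert col.index[0] == r["true_or"]
        ratios.append(col.iloc[0] / max(col.iloc[1], 1e-9))
    assert np.median(ratios) > 100  # per-draw; 1000x in expectation


def test_background_or_count_in_configured_range(cohort21):
    truth = cohort21.truth.cells.set_index("cell")
    ors = set(cohort21.annotation.loc[cohort21.annotation["category"] == "OR", "gene"])
    counts = cohort21.counts.values
    for cell, row in truth.iterrows():
        expressed = set(counts.index[counts[cell] > 0]) & ors - {row["true_or"]}
        # NB sampling can zero out a background OR but never adds one
        assert len(expressed) <= 28


def test_coverage_structure(cohort21):
    cov = cohort21.coverage.merge(
        cohort21.truth.cells[["cell", "true_or"]], on="cell"
    )
    abundant = cov[cov["gene"] == cov["true_or"]]
    background = cov[cov["gene"] != cov["true_or"]]
    assert (abundant["coverage"] > 2 / 3).all()
    frac_low = (background["coverage"] < 1 / 3).mean()
    assert 0.75 < frac_low < 0.95  # configured 0.86


def test_allele_counts_conserve_informative_reads(cohort21):
    """Summed A+B reads equal the simulated informative total derived
    from the abundant OR's raw count."""
    ac = cohort21.allele_counts
    counts = cohort21.counts.values
    cfg = cohort21.config
    for (cell, gene), grp in ac.groupby(["cell", "gene"]):
        total = int(round(cfg.allele_reads_per_count * counts.loc[gene, cell]))
        assert (grp["a_count"] + grp["b_count"]).sum() == total


def test_typeb_cells_express_signature_not_receptors(cohort21):
    counts = cohort21.counts.values
    typeb = cohort21.truth.cells.query("true_class == 'typeB'")["cell"]
    sig = cohort21.truth.signature_genes
    canonical = cohort21.truth.cells.query("true_class == 'canonical'")["cell"]
    assert (counts.loc[sig, typeb] > 50).to_numpy().mean() > 0.95
    assert (counts.loc[sig, canonical] == 0).to_numpy().mean() > 0.95
    for marker in ("Trpc2", "Gucy1b2", "Sln", "Emx1", "Sncg"):
        assert (counts.loc[marker, typeb] > 50).all()


# -- cell-cycle reference ----------------------------------------------------

def test_reference_shape_and_labels():
    cfg = preset_config("cohort21", seed=1)
    ref, labels = generate_reference_cellcycle(cfg)
    assert ref.shape == (cfg.n_cellcycle_genes, 2 * cfg.n_ref_per_label)
    assert set(labels) == {"G1", "S/G2-M"}


def test_reference_group_means_differ_by_configured_effect():
    """Cycling genes differ between label groups by ~10**effect; verified
    by direct group-mean comparison."""
    cfg = preset_config("cohort21", seed=1)
    ref, labels = generate_reference_cellcycle(cfg)
    _, cycling = _cc_profile(cfg)
    g1 = ref.loc[:, labels == "G1"].mean(axis=1).to_numpy()
    s = ref.loc[:, labels == "S/G2-M"].mean(axis=1).to_numpy()
    ratio = (s[cycling] + 1) / (g1[cycling] + 1)
    assert (ratio > 10 ** (cfg.cc_effect / 2)).mean() >= 0.9


def test_reference_too_few_samples_per_label_is_error():
    cfg = preset_config("cohort21", seed=1, n_ref_per_label=1)
    with pytest.raises(ConfigurationError, match="n_ref_per_label"):
        generate_reference_cellcycle(cfg)


def test_cohort_cells_share_reference_g1_profile(cohort21, cohort21_normalized):
    """Cohort cell-cycle expression matches the reference G1 profile, not
    the shifted S/G2-M profile."""
    cfg = cohort21.config
    base, cycling = _cc_profile(cfg)
    _, norm = cohort21_normalized
    cc = norm.loc[cellcycle_gene_ids(cfg)].mean(axis=1).to_numpy()
    log_ratio = np.log10(cc[cycling] + 1) - (base[cycling])
    assert abs(np.median(log_ratio)) < 0.2  # matches G1, not base + effect
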