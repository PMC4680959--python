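"""Synthetic single-OSN cohort generator.

Generates count matrices, coverage fractions, SNP allele counts, QC
metrics and ground-truth labels with the statistical structure of a
mature-OSN single-cell RNA-seq experiment, so every downstream stage of
the pipeline is testable without sequencing data:

* canonical cells carry one abundant intact OR (mean ~36,162 normalized
  counts) plus 11-28 background ORs at ~16 counts, three or more orders
  of magnitude lower in expectation;
* two receptorless "type B" cells express a 55-gene signature (headed by
  Trpc2, Gucy1b2, Sln, Emx1, Sncg) and only background-level ORs;
* background OR events are mostly (86%) covered over less than one third
  of the gene length, abundant ORs near fully;
* allele counts at the abundant OR's SNPs split (purity, 1 - purity);
* baseline expression is calibrated so the expected number of detected
  genes per cell matches the configured target (~4,717);
* QC-failing cells are injected per criterion in a fixed order so the
  hierarchical filter attributes each to exactly one first violation.

Counts are negative binomial per gene per cell (cell-class mean profile
times a library-size factor, shared dispersion); at dispersion -> 0 the
draws become Poisson and, for noise-free checks, deterministic structure
dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from . import io as osn_io
from .alleles import ALLELE_COLUMNS
from .exceptions import ConfigurationError
from .qc import DEFAULT_CRITERIA

SIGNATURE_HEAD = ["Trpc2", "Gucy1b2", "Sln", "Emx1", "Sncg"]

#: mature-OSN marker profile (gene -> mean normalized counts)
MARKER_MEANS = {
    "Omp": 30000.0,
    "Gnal": 8000.0,
    "Gnb1": 40000.0,
    "Cnga2": 2500.0,
    "Cnga4": 1500.0,
    "Ano2": 2000.0,
    "Adcy3": 2200.0,
    "Stoml3": 45000.0,
    "Malat1": 50000.0,
    "Calm1": 38000.0,
}
#: markers of the canonical transduction cascade absent from type-B cells
TYPEB_ABSENT_MARKERS = ("Adcy3", "Cnga4")

_CRITERION_NAMES = tuple(c.name for c in DEFAULT_CRITERIA)


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 1
    n_cells: int = 21
    n_canonical: int = 19
    n_typeB: int = 2
    n_intact_or: int = 1099
    n_pseudo_or: int = 151
    n_taar: int = 15
    high_mean_counts: float = 36162.46
    high_cv: float = 0.77
    low_mean_counts: float = 15.99
    low_cv: float = 1.0
    background_or_range: tuple = (11, 28)
    genes_detected_mean: float = 4717.0
    signature_size: int = 55
    signature_mean_counts: float = 500.0
    allelic_purity: float = 0.998
    snps_per_or: int = 15
    snp_gene_fraction: float = 0.5
    allele_reads_per_count: float = 1.5
    sequencing_error: float = 0.001
    qc_fail_profile: tuple = (
        ("min_total_fragments", 0.30),
        ("min_mapped_fraction", 0.25),
        ("min_genes_detected", 0.20),
        ("max_ercc_fraction", 0.15),
        ("max_top_gene_fraction", 0.10),
    )
    nb_dispersion: float = 0.1
    library_size_lognormal: tuple = (0.0, 0.3)
    n_other_genes: int = 6000
    n_housekeeping: int = 200
    housekeeping_mean_counts: float = 2000.0
    n_cellcycle_genes: int = 971
    cc_effect: float = 1.0  # log10 shift of cycling genes in S/G2-M
    n_ref_per_label: int = 5
    n_ercc: int = 92
    ercc_fraction: float = 0.05
    or_class1_fraction: float = 0.1
    background_subthird_fraction: float = 0.86

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if self.n_canonical < 0 or self.n_typeB < 0:
            raise ConfigurationError("n_canonical and n_typeB must be >= 0")
        if self.n_canonical + self.n_typeB > self.n_cells:
            raise ConfigurationError("n_canonical + n_typeB exceeds n_cells")
        for name in (
            "high_mean_counts",
            "low_mean_counts",
            "genes_detected_mean",
            "signature_mean_counts",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0.5 < self.allelic_purity <= 1.0):
            raise ConfigurationError("allelic_purity must lie in (0.5, 1]")
        lo, hi = self.background_or_range
        if lo > hi or lo < 0:
            raise ConfigurationError("background_or_range must satisfy 0 <= low <= high")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.n_intact_or < self.n_canonical:
            raise ConfigurationError("n_intact_or must cover n_canonical distinct ORs")
        total = sum(f for _, f in self.qc_fail_profile)
        if self.qc_fail_profile and not np.isclose(total, 1.0):
            raise ConfigurationError("qc_fail_profile fractions must sum to 1")
        for name, _ in self.qc_fail_profile:
            if name not in _CRITERION_NAMES:
                raise ConfigurationError(f"qc_fail_profile: unknown criterion {name!r}")


#: presets mirroring the emulated cohort: 21 high-quality cells, and the
#: full 58-cell capture of which 37 fail hierarchical QC
PRESETS = {
    "cohort21": dict(n_cells=21, n_canonical=19, n_typeB=2),
    "cohort58": dict(n_cells=58, n_canonical=19, n_typeB=2),
}


def preset_config(name: str, seed: int = 1, **overrides) -> SimConfig:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


@dataclass
class CohortTruth:
    """Ground-truth labels for one simulated cohort."""

    cells: pd.DataFrame  # cell, true_class, true_or, true_allele, true_stage, qc_fail_criterion
    signature_genes: list


@dataclass
class Cohort:
    """Everything one simulated cohort comprises."""

    counts: osn_io.CountMatrix
    annotation: pd.DataFrame
    coverage: pd.DataFrame  # cell, gene, coverage
    allele_counts: pd.DataFrame  # cell, gene, snp_id, a_count, b_count, other_count
    qc_metrics: pd.DataFrame  # indexed by cell
    snps: pd.DataFrame  # SnpTable
    truth: CohortTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _detection_prob(mean: np.ndarray, alpha: float) -> np.ndarray:
    """P(NB(mean, alpha) > 0); Poisson limit when alpha ~ 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return 1.0 - np.exp(-mean)
    return 1.0 - (1.0 + alpha * mean) ** (-1.0 / alpha)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson negative binomial draw, elementwise over ``mean``."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / alpha, alpha * mean)
    return rng.poisson(lam)


def _lognormal_jitter(rng: np.random.Generator, size, cv: float) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(-s2 / 2.0, np.sqrt(s2), size)


def _cc_profile(config: SimConfig):
    """Shared cell-cycle base profile (log10 means) and cycling-gene mask.

    Derived from a dedicated sub-seed so the cohort and the labelled
    reference agree on the G1 profile.
    """
    rng = np.random.default_rng([config.seed % (2**31), 7])
    base = rng.uniform(0.5, 2.5, config.n_cellcycle_genes)
    cycling = np.zeros(config.n_cellcycle_genes, dtype=bool)
    cycling[rng.permutation(config.n_cellcycle_genes)[: config.n_cellcycle_genes // 2]] = True
    return base, cycling


def cellcycle_gene_ids(config: SimConfig) -> list:
    return [f"Ccg{i + 1:04d}" for i in range(config.n_cellcycle_genes)]


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------

def _build_annotation(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(config.n_intact_or):
        rows.append((f"OrI{i + 1:04d}", "OR", "intact"))
    for i in range(config.n_pseudo_or):
        rows.append((f"OrP{i + 1:04d}", "OR", "pseudogene"))
    for i in range(config.n_taar):
        rows.append((f"Taar{i + 1:02d}", "TAAR", "intact"))
    for g in MARKER_MEANS:
        rows.append((g, "marker", "intact"))
    n_extra = max(config.signature_size - len(SIGNATURE_HEAD), 0)
    for g in SIGNATURE_HEAD[: config.signature_size]:
        rows.append((g, "other", "intact"))
    for i in range(n_extra):
        rows.append((f"Sig{i + 1:03d}", "other", "intact"))
    for g in cellcycle_gene_ids(config):
        rows.append((g, "other", "intact"))
    for i in range(config.n_housekeeping):
        rows.append((f"Hk{i + 1:04d}", "other", "intact"))
    for i in range(config.n_other_genes):
        rows.append((f"Gx{i + 1:05d}", "other", "intact"))
    for i in range(config.n_ercc):
        rows.append((f"ERCC-{i + 1:05d}", "other", "intact"))
    ann = pd.DataFrame(rows, columns=["gene", "category", "status"])
    ann["symbol"] = ann["gene"]
    is_or = ann["category"] == "OR"
    lengths = np.where(
        is_or,
        rng.integers(950, 1150, len(ann)),
        np.round(rng.lognormal(np.log(2000), 0.5, len(ann))).astype(int),
    )
    ann["length"] = np.maximum(lengths, 200)
    or_class = np.where(
        rng.random(len(ann)) < config.or_class1_fraction, "I", "II"
    )
    ann["or_class"] = np.where(is_or, or_class, None)
    return osn_io.validate_annotation(ann[osn_io.ANNOTATION_COLUMNS])


def signature_gene_ids(config: SimConfig) -> list:
    head = SIGNATURE_HEAD[: config.signature_size]
    extra = [f"Sig{i + 1:03d}" for i in range(max(config.signature_size - len(head), 0))]
    return head + extra


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> Cohort:
    """Generate one cohort under ``config``; byte-identical given the seed."""
    rng = np.random.default_rng(config.seed % (2**31))
    annotation = _build_annotation(config, rng)
    genes = annotation["gene"].tolist()
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    intact_ors = annotation.loc[
        (annotation["category"] == "OR") & (annotation["status"] == "intact"), "gene"
    ].tolist()
    all_ors = annotation.loc[annotation["category"] == "OR", "gene"].tolist()
    sig_genes = signature_gene_ids(config)
    cc_genes = cellcycle_gene_ids(config)
    other_genes = [g for g in genes if g.startswith("Gx")]
    hk_genes = [g for g in genes if g.startswith("Hk")]
    ercc_genes = [g for g in genes if g.startswith("ERCC-")]

    alpha = config.nb_dispersion
    cc_base, _ = _cc_profile(config)
    cc_means = 10.0**cc_base

    # baseline means for genes shared by every cell class
    other_raw = rng.lognormal(np.log(20.0), 1.8, len(other_genes))
    hk_means = config.housekeeping_mean_counts * rng.lognormal(
        -0.125, 0.5, len(hk_genes)
    )
    fixed_detect = (
        len(MARKER_MEANS)
        + len(hk_genes)
        + _detection_prob(cc_means, alpha).sum()
        + 1.0  # the abundant OR
        + np.mean(config.background_or_range) * _detection_prob(config.low_mean_counts, alpha)
    )
    target_other = max(config.genes_detected_mean - fixed_detect, 1.0)
    if target_other >= len(other_genes):
        raise ConfigurationError(
            "genes_detected_mean unreachable: raise n_other_genes"
        )

    def detected(scale: float) -> float:
        return _detection_prob(scale * other_raw, alpha).sum() - target_other

    scale = scipy.optimize.brentq(detected, 1e-6, 1e6)
    other_means = scale * other_raw

    # per-gene signature means, shared by both type-B cells
    sig_means = config.signature_mean_counts * _lognormal_jitter(
        rng, len(sig_genes), 0.5
    )

    # cell classes in a fixed order: canonical, type B, QC failures
    n_fail = config.n_cells - config.n_canonical - config.n_typeB
    cell_ids = [f"OSN{i + 101}" for i in range(config.n_cells)]
    classes = (
        ["canonical"] * config.n_canonical
        + ["typeB"] * config.n_typeB
        + ["qc_fail"] * n_fail
    )
    fail_criteria = _allocate_failures(config, n_fail)

    # mean matrix on the normalized-count scale
    M = np.zeros((n_genes, config.n_cells))
    idx_other = [gene_index[g] for g in other_genes]
    idx_hk = [gene_index[g] for g in hk_genes]
    idx_cc = [gene_index[g] for g in cc_genes]
    idx_marker = [gene_index[g] for g in MARKER_MEANS]
    idx_sig = [gene_index[g] for g in sig_genes]
    idx_ercc = [gene_index[g] for g in ercc_genes]
    marker_vals = np.array(list(MARKER_MEANS.values()))
    for j in range(config.n_cells):
        M[idx_other, j] = other_means
        M[idx_hk, j] = hk_means
        M[idx_cc, j] = cc_means
        M[idx_marker, j] = marker_vals

    endog_total = (
        other_means.sum()
        + hk_means.sum()
        + cc_means.sum()
        + marker_vals.sum()
        + config.high_mean_counts
    )
    ercc_profile = rng.lognormal(0.0, 1.0, len(ercc_genes))
    ercc_profile *= (
        config.ercc_fraction / (1 - config.ercc_fraction) * endog_total
    ) / ercc_profile.sum()
    for j in range(config.n_cells):
        M[idx_ercc, j] = ercc_profile

    # receptor assignment
    abundant_or = [None] * config.n_cells
    abundant_mean = np.zeros(config.n_cells)
    or_pool = rng.permutation(intact_ors)
    pool_pos = 0
    lo, hi = config.background_or_range
    for j, cls in enumerate(classes):
        if cls in ("canonical", "qc_fail"):
            gene = or_pool[pool_pos % len(or_pool)]
            pool_pos += 1
            abundant_or[j] = gene
            # truncate the abundance jitter: receptor levels across cells
            # span a bounded range, and an unbounded lognormal tail would
            # make a healthy cell look like a degenerate library
            abundant_mean[j] = config.high_mean_counts * min(
                float(_lognormal_jitter(rng, None, config.high_cv)), 3.0
            )
            M[gene_index[gene], j] = abundant_mean[j]
        k = int(rng.integers(lo, hi + 1))
        candidates = [g for g in all_ors if g != abundant_or[j]]
        chosen = rng.choice(len(candidates), size=k, replace=False)
        for ci in chosen:
            M[gene_index[candidates[ci]], j] = config.low_mean_counts * _lognormal_jitter(
                rng, None, config.low_cv
            )

    # type-B structure: the signature, and loss of the OR cascade markers
    for j, cls in enumerate(classes):
        if cls == "typeB":
            M[idx_sig, j] = sig_means
            for g in TYPEB_ABSENT_MARKERS:
                M[gene_index[g], j] = 0.0

    # QC-failure injections that act through the counts themselves
    for j, crit in enumerate(fail_criteria):
        if crit is None:
            continue
        col = config.n_canonical + config.n_typeB + j
        if crit == "min_genes_detected":
            endog = np.ones(n_genes, dtype=bool)
            endog[idx_ercc] = False
            M[endog, col] *= 0.003
        elif crit == "max_ercc_fraction":
            endog_sum = M[:, col].sum() - M[idx_ercc, col].sum()
            M[idx_ercc, col] *= (0.35 / 0.65 * endog_sum) / max(
                M[idx_ercc, col].sum(), 1e-12
            )
        elif crit == "max_top_gene_fraction":
            rest = M[:, col].sum() - M[gene_index[abundant_or[col]], col]
            M[gene_index[abundant_or[col]], col] = 1.5 * rest

    # library-size factors (geometric mean one) and the counts
    mlog, slog = config.library_size_lognormal
    lib = rng.lognormal(mlog, slog, config.n_cells)
    if config.n_cells:
        lib /= np.exp(np.log(lib).mean())
    counts_arr = _nb_draw(rng, M * lib[None, :], alpha)

    counts = osn_io.CountMatrix(
        pd.DataFrame(counts_arr, index=genes, columns=cell_ids),
        pd.Series("cell", index=cell_ids),
    )
    # the CountMatrix sorts genes canonically; realign local arrays
    counts_df = counts.values

    coverage = _draw_coverage(
        config, rng, counts_df, annotation, cell_ids, abundant_or
    )
    snps, allele_counts, true_allele = _draw_alleles(
        config, rng, counts_df, cell_ids, classes, abundant_or, intact_ors
    )
    qc_metrics = _draw_qc_metrics(
        config, rng, counts_df, cell_ids, fail_criteria, classes
    )

    truth_cells = pd.DataFrame(
        {
            "cell": cell_ids,
            "true_class": classes,
            "true_or": [g if c == "canonical" else "" for g, c in zip(abundant_or, classes)],
            "true_allele": true_allele,
            "true_stage": "G1",
            "qc_fail_criterion": [
                fail_criteria[j - config.n_canonical - config.n_typeB]
                if cls == "qc_fail"
                else None
                for j, cls in enumerate(classes)
            ],
        }
    )
    return Cohort(
        counts=counts,
        annotation=annotation,
        coverage=coverage,
        allele_counts=allele_counts,
        qc_metrics=qc_metrics,
        snps=snps,
        truth=CohortTruth(cells=truth_cells, signature_genes=sig_genes),
        config=config,
    )


def _allocate_failures(config: SimConfig, n_fail: int) -> list:
    """Deterministic largest-remainder split of failures over criteria."""
    if n_fail == 0 or not config.qc_fail_profile:
        return []
    names = [n for n, _ in config.qc_fail_profile]
    fracs = np.array([f for _, f in config.qc_fail_profile])
    raw = fracs * n_fail
    base = np.floor(raw).astype(int)
    rem = n_fail - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    out = []
    for name, k in zip(names, base):
        out.extend([name] * int(k))
    return out


def _draw_coverage(
    config: SimConfig,
    rng: np.random.Generator,
    counts_df: pd.DataFrame,
    annotation: pd.DataFrame,
    cell_ids: list,
    abundant_or: list,
) -> pd.DataFrame:
    """Coverage fractions for every receptor expression event.

    Abundant ORs are covered near fully (Beta(60, 3)); background events
    fall below one third of the gene length with probability
    ``background_subthird_fraction`` (a Beta on (0, 1/3)), else just
    above (a Beta on (1/3, 1))."""
    receptor_genes = pd.Index(
        annotation.loc[annotation["category"].isin(["OR", "TAAR"]), "gene"]
    )
    sub = counts_df.loc[counts_df.index.intersection(receptor_genes)]
    rows = []
    for j, cell in enumerate(cell_ids):
        expressed = sub.index[sub[cell] > 0]
        for gene in expressed:
            if gene == abundant_or[j]:
                f = rng.beta(60, 3)
            elif rng.random() < config.background_subthird_fraction:
                f = (1.0 / 3.0) * rng.beta(2, 2)
            else:
                f = 1.0 / 3.0 + (2.0 / 3.0) * rng.beta(1.5, 4)
            rows.append((cell, gene, f))
    return pd.DataFrame(rows, columns=["cell", "gene", "coverage"])


def _draw_alleles(
    config: SimConfig,
    rng: np.random.Generator,
    counts_df: pd.DataFrame,
    cell_ids: list,
    classes: list,
    abundant_or: list,
    intact_ors: list,
):
    """SNP table over a subset of intact ORs, and allele counts at the
    abundant OR of each canonical cell."""
    bases = np.array(["A", "C", "G", "T"])
    snp_bearing = [
        g for g in intact_ors if rng.random() < config.snp_gene_fraction
    ]
    snp_rows = []
    for g in snp_bearing:
        positions = np.sort(
            rng.choice(np.arange(1, 1001), size=config.snps_per_or, replace=False)
        )
        for k, pos in enumerate(positions):
            a, b = rng.choice(4, size=2, replace=False)
            snp_rows.append((g, "chrS", int(pos), bases[a], bases[b]))
    snps = pd.DataFrame(snp_rows, columns=osn_io.SNP_COLUMNS)
    snp_set = set(snp_bearing)

    allele_rows = []
    true_allele = []
    for j, (cell, cls) in enumerate(zip(cell_ids, classes)):
        gene = abundant_or[j]
        if cls != "canonical" or gene is None:
            true_allele.append("")
            continue
        allele = "A" if rng.random() < 0.5 else "B"
        true_allele.append(allele)
        if gene not in snp_set:
            continue
        total = int(round(config.allele_reads_per_count * counts_df.loc[gene, cell]))
        if total <= 0:
            continue
        per_snp = rng.multinomial(total, np.full(config.snps_per_or, 1.0 / config.snps_per_or))
        for k, n_snp in enumerate(per_snp):
            major = rng.binomial(n_snp, config.allelic_purity)
            minor = n_snp - major
            a_cnt, b_cnt = (major, minor) if allele == "A" else (minor, major)
            other = rng.binomial(n_snp, config.sequencing_error)
            allele_rows.append((cell, gene, f"{gene}_{k + 1}", a_cnt, b_cnt, other))
    allele_counts = pd.DataFrame(allele_rows, columns=ALLELE_COLUMNS)
    return snps, allele_counts, true_allele


def _draw_qc_metrics(
    config: SimConfig,
    rng: np.random.Generator,
    counts_df: pd.DataFrame,
    cell_ids: list,
    fail_criteria: list,
    classes: list,
) -> pd.DataFrame:
    """QC metric table: derived from counts where derivable, drawn
    otherwise; alignment- and depth-level failures injected here."""
    ercc_mask = counts_df.index.str.startswith("ERCC-")
    endog = counts_df.loc[~ercc_mask]
    total = counts_df.sum(axis=0)
    genes_detected = (endog > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ercc_fraction = counts_df.loc[ercc_mask].sum(axis=0) / total.replace(0, np.nan)
        top_gene_fraction = endog.max(axis=0) / endog.sum(axis=0).replace(0, np.nan)
    rows = []
    if not cell_ids:
        return pd.DataFrame(
            columns=["cell", "total_fragments", "mapped_fraction", "genes_detected",
                     "ercc_fraction", "top_gene_fraction"]
        ).set_index("cell")
    n_lead = sum(1 for c in classes if c != "qc_fail")
    for j, cell in enumerate(cell_ids):
        crit = fail_criteria[j - n_lead] if classes[j] == "qc_fail" else None
        if crit == "min_total_fragments":
            frags = rng.uniform(5e4, 4e5)
        else:
            frags = rng.uniform(2e6, 7e6)
        if crit == "min_mapped_fraction":
            mapped = rng.uniform(0.15, 0.45)
        else:
            mapped = rng.uniform(0.6, 0.85)
        rows.append(
            {
                "cell": cell,
                "total_fragments": int(frags),
                "mapped_fraction": mapped,
                "genes_detected": int(genes_detected[cell]),
                "ercc_fraction": float(np.nan_to_num(ercc_fraction[cell])),
                "top_gene_fraction": float(np.nan_to_num(top_gene_fraction[cell])),
            }
        )
    return pd.DataFrame(rows).set_index("cell")


# ---------------------------------------------------------------------------
# labelled cell-cycle reference
# ---------------------------------------------------------------------------

def generate_reference_cellcycle(config: SimConfig):
    """Labelled reference matrix over the cell-cycle genes.

    Returns (genes x samples count DataFrame, label Series with values
    "G1" and "S/G2-M").  G1 samples follow the shared base profile; in
    S/G2-M samples the cycling half is shifted up by ``cc_effect`` on the
    log10 scale.  The cohort's postmitotic cells share the G1 profile.
    """
    if config.n_cellcycle_genes < 1:
        raise ConfigurationError("n_cellcycle_genes must be >= 1")
    if config.n_ref_per_label < 2:
        raise ConfigurationError("n_ref_per_label must be >= 2")
    base, cycling = _cc_profile(config)
    rng = np.random.default_rng([config.seed % (2**31), 8])
    g1_mean = 10.0**base
    s_mean = 10.0 ** (base + config.cc_effect * cycling)
    cols, data, labels = [], [], []
    for i in range(config.n_ref_per_label):
        cols.append(f"refG1_{i + 1}")
        data.append(_nb_draw(rng, g1_mean, config.nb_dispersion))
        labels.append("G1")
    for i in range(config.n_ref_per_label):
        cols.append(f"refS_{i + 1}")
        data.append(_nb_draw(rng, s_mean, config.nb_dispersion))
        labels.append("S/G2-M")
    ref = pd.DataFrame(
        np.column_stack(data), index=cellcycle_gene_ids(config), columns=cols
    )
    return ref, pd.Series(labels, index=cols, name="stage")


# ---------------------------------------------------------------------------
# writing a cohort to disk
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write every cohort table under ``outdir`` (TSV + MTX + VCF + YAML)."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    osn_io.write_counts_tsv(cohort.counts, outdir / "counts.tsv")
    osn_io.write_counts_mtx(cohort.counts, outdir / "counts")
    osn_io.write_annotation(cohort.annotation, outdir / "annotation.tsv")
    osn_io.write_table(cohort.coverage, outdir / "coverage.tsv")
    osn_io.write_table(cohort.allele_counts, outdir / "allele_counts.tsv")
    cohort.qc_metrics.reset_index().pipe(osn_io.write_table, outdir / "qc_metrics.tsv")
    osn_io.write_snp_vcf(cohort.snps, outdir / "snps.vcf")
    osn_io.write_table(cohort.truth.cells, outdir / "truth_cells.tsv")
    (outdir / "truth_signature_genes.txt").write_text(
        "\n".join(cohort.truth.signature_genes) + "\n"
    )
    cfg = asdict(cohort.config)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
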