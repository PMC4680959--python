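# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of osnpipe.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Normalization

Size factors are strict median-of-ratios: for sample *j*,
s_j = median over genes g of c_gj / (∏_k c_gk)^(1/n), the median taken
over genes with a nonzero count in **every** sample.  No pseudo-reference
fallback is provided; if no gene qualifies the caller is told so.  For
sparse single cells an optional floor (`min_mean`, default 0; the
pipeline presets use 1 raw count) restricts the reference set to
better-measured genes, which stabilises the median without changing its
definition.  Normalized counts are c_gj / s_j; the display transform is
log10(x̃ + 1).

A useful identity for testing: scaling one sample's counts by k scales
that sample's factor by k^((n−1)/n) and every other factor by k^(−1/n),
because the geometric-mean reference absorbs k^(1/n).  Ratios of size
factors between samples — the only thing normalized counts depend on —
scale by exactly k, and that is the form the equivariance tests assert.

## Hierarchical QC

Criteria are an ordered list of (metric, comparator, cutoff).  Defaults:
total fragments ≥ 500,000; mapped fraction ≥ 0.5; genes detected
≥ 2,000; ERCC fraction ≤ 0.2; top-gene fraction ≤ 0.25.  These cutoffs
are representative single-cell RNA-seq choices and fully configurable;
the load-bearing structure is the hierarchy itself: a cell passes iff it
meets every criterion, and each failing cell is attributed to the first
criterion it violates, so attributions partition the failures.
Relaxing any single cutoff can only grow the passing set (monotonicity,
property-tested).

## Receptor calling

An OR/TAAR *expression event* is a (cell, gene) pair with normalized
counts > 0.  Events covering less than one third of the gene length are
discarded as likely mismapping or non-specific transcription; the
boundary f = 1/3 is retained.  Retained events are pooled across all
cells and a single two-component Gaussian mixture is fitted to
log10(normalized counts) — one global threshold for the cohort, because
abundance classes are a property of the OR system, not of one cell.
Events are kept per (gene, cell), not deduplicated per gene, so a gene
abundantly expressed in two cells contributes two high-class events;
with one dominant OR per cell the two conventions barely differ.

EM details: initialization splits the data at the empirical median
(restarts jitter the split), 5 restarts, tolerance 1e-8 on the
log-likelihood increment, iteration cap 5,000 (near-unimodal data
converges slowly; well-separated data in tens of iterations).  Component
standard deviations are floored at 1e-6 so exact point-mass data fits
cleanly; a component whose effective membership falls below two events
is treated as collapsed and that restart discarded.  The log-likelihood
is asserted non-decreasing at every iteration.  A separation statistic
|μ₂ − μ₁| / pooled σ below 2 marks the two-component fit as effectively
unimodal and the threshold unreliable.

The intersection τ solves w₁𝒩(x|μ₁,σ₁²) = w₂𝒩(x|μ₂,σ₂²): a quadratic in
x for σ₁ ≠ σ₂ (the root between the means is taken), a closed form for
equal variances.  The quadratic solution is property-tested against
bisection to 1e-9.  If no real root lies between the means the fit is
declared pathological and a manual threshold recommended.

Classification: abundant means normalized counts **≥ τ** (at-or-above,
so a pseudogene sitting exactly on the threshold counts as abundant).
Exactly one abundant intact OR → monogenic; zero abundant ORs of any
status → receptorless; anything else → coexpressing.  Abundant
pseudogenes set a coexpression flag but do not break monogenic status.
The dominance ratio reports the top intact OR over the next intact OR
event in the cell.  TAAR genes flow through the same classifier.

## Allele-specific expression

Reads supporting each strain base are summed over a gene's SNPs;
p = max(ΣA, ΣB)/(ΣA+ΣB).  Reads matching neither base (sequencing
error) are excluded from the denominator but their fraction is
reported.  Defaults: strain call requires ≥ 20 informative reads and
p ≥ 0.95 — loose relative to the near-total purity the pipeline is
designed to measure, and intended only to guard degenerate inputs.
Percentages are reported to two decimals.  SNPs within a gene are
summed without weighting; discordant-direction SNPs within one gene
would be visible in the per-SNP breakdown, which is always returned.

## Differential expression

The engine is a two-group negative-binomial Wald test, vectorised over
genes:

- per-gene dispersion by method of moments from the pooled within-group
  variance of normalized counts, Var(x̃) = μ·ξ + αμ² with ξ the mean
  inverse size factor, floored at α = 1e-8;
- log2 fold change of group means of normalized counts with a
  pseudocount of 0.5 (stabilises genes absent from one group);
- delta-method standard error, Wald statistic, two-sided normal p-value;
- Benjamini–Hochberg step-up on genes whose baseMean reaches 1
  normalized count; filtered genes keep their p-value but get a missing
  adjusted p-value.

This deliberately omits cross-gene dispersion shrinkage and outlier
replacement: the pipeline's decisions live downstream of the test, and
the simpler engine has a directly testable statistical contract — the
suite checks type-I error in [0.03, 0.07] on a 10-vs-10 null at
dispersion 0.1, near-uniform null p-values, and ≥ 90% power for 8-fold
changes at mean 500 with 6 vs 6.  Fold-change classification (default
up > 3, down < 1/3, FDR < 5%) applies thresholds on the linear scale.

Variable genes: eligibility requires a maximum ≥ 1,000 normalized
counts in at least one cell (at-or-above; the comparator is exposed),
CV = sample (n−1) SD / mean, selection at CV > 4, each selected gene
attributed to its maximal cell.

Unique coexpression of a pair: signature genes must be significant in
the pair-vs-rest test, ≥ high_cutoff (default 100) in both pair cells
and < low_cutoff (default 10) in every other cell — the "only highly
expressed here" notion made exact; both cutoffs are configuration.  The
pairwise scan evaluates all C(n,2) pairs (n ≥ 4, since the rest group
needs two samples) and flags the top pair as a candidate distinct cell
type when its count exceeds twice the second-best.

## Cell-cycle classification

The classifier is one principal axis with a sign rule.  Training:
log10(x̃+1) over the cell-cycle gene list, centred on reference gene
means, PCA on the reference samples, sign oriented so G1 reference
samples project negative.  A separation statistic (between-label
projection gap over pooled SD) below 2 triggers a low-confidence
warning.  Classification: G1 iff projection < 0; a projection of
exactly 0 falls on the S/G2-M side (closed positive boundary,
configurable).  The gene list is an input, not a bundled ontology
snapshot, to avoid database-version coupling.  Finer staging (S vs
G2-M) is out of scope.

## The synthetic cohort generator

The generator emulates the statistical structure of a small cohort of
FACS-sorted mature OSNs captured on a microfluidic chip:

- **Counts** are negative binomial per gene per cell: mean from the
  cell-class profile times a lognormal library-size factor (geometric
  mean 1), shared dispersion (default 0.1).  At dispersion → 0 draws
  become Poisson, enabling near-noise-free recovery checks.
- **Canonical cells** carry one abundant intact OR at mean 36,162.46
  normalized counts with lognormal cell-to-cell variation (CV 0.77,
  derived from the reported spread of high-class OR means; the
  multiplier is truncated at 3× because receptor abundance spans a
  bounded range and an unbounded tail would make a healthy cell
  resemble a degenerate library), plus 11–28 background ORs at mean
  15.99 counts (CV 1.0) — three-plus orders of magnitude lower in
  expectation.
- **Type-B cells** express a 55-gene signature (headed by Trpc2,
  Gucy1b2, Sln, Emx1, Sncg) at mean 500 normalized counts, lack the
  OR-cascade markers Adcy3/Cnga4, and have background-level ORs only.
- **Baseline transcriptome**: ~10 mature-OSN markers, 200 housekeeping
  genes (mean ~2,000 counts, so library composition is realistic and
  the top-gene QC fraction sits far from its cutoff), 971 cell-cycle
  genes on a shared G1 profile, and 6,000 genes with lognormal means
  whose global scale is solved (Brent) so the expected number of
  detected genes per cell matches the target 4,717.
- **Coverage fractions** are scaled Beta draws: abundant ORs
  Beta(60,3) (near-full coverage); background events land below 1/3
  with probability 0.86 (a Beta on (0, 1/3)) and just above otherwise —
  the sub-third rate is a structural constant, not an emergent estimate.
- **Allele counts** exist for the abundant OR of each canonical cell
  (the question monoallelism asks); roughly half of intact ORs carry 15
  SNPs.  Informative reads are 1.5× the gene's raw count, split
  multinomially over SNPs and binomially (purity 0.998) between the
  true and the other allele, with a 0.001 sequencing-error channel kept
  outside the denominator.
- **QC failures** (the 58-cell preset: 37 of 58) are injected per
  criterion in the hierarchy's order with deterministic largest-
  remainder allocation; each injected cell passes all earlier criteria,
  so the filter's first-violation attribution is exactly recoverable.
- **The labelled cell-cycle reference** derives its base profile from a
  dedicated sub-seed shared with the cohort, so cohort cells sit on the
  G1 profile; S/G2-M reference samples shift a cycling half of the
  genes up by 1.0 on the log10 scale.

What the generator does **not** emulate: read- and alignment-level
artifacts beyond the coverage-fraction abstraction, doublets, batch and
amplification effects, gene–gene correlation, zero inflation beyond NB
sampling, bursty transcription, or cells abundantly coexpressing two
intact ORs.  Passing recovery tests therefore shows the pipeline's
decision logic is correct under a faithful-but-idealised noise model;
it does not certify behaviour on real libraries with structured
artifacts.

Problem sizes throughout (21–58 cells, ~8.6k genes, 400-replicate
Monte-Carlo checks, 2,000-gene null simulations) are chosen as the
smallest at which the statistical contracts are sharply testable.

## Known limitations

- The NB Wald engine is anti-conservative at very small sample sizes in
  the way plug-in Wald tests are (~6% empirical size at the nominal 5%
  with 10 vs 10); it is not a drop-in replacement for shrinkage-based
  engines on real data.
- One global τ assumes cells share abundance classes; per-cell mixtures
  are out of scope.
- The Wald interval for allelic purity under-covers when p approaches 1
  at shallow depth; calls at the default thresholds are unaffected.
- Pseudogene re-annotation (reconstructing ORFs from read evidence) is
  not attempted; annotation status is taken as given.
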