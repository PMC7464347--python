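# Methods

## Per-sample key metrics

Tumor load is the maximum-likelihood binomial estimate `k/N` of the tumor
cell fraction from `k` detected tumor cells among `N` assayed cells. The
limits are reciprocal in `N`:

| metric | NGS | MFC | meaning |
|---|---|---|---|
| LOD | 1.9/N | 30/N | lowest TL detectable with controlled false-negative risk |
| LOQ | 2.39/N | 50/N | lowest TL quantifiable to stated accuracy |

The NGS numerators are the assay vendor's experimentally determined
constants — the LOD is defined as the tumor-cell frequency at which the
probability of falsely claiming absence of disease is 5%, the LOQ as the
lowest frequency quantifiable within 70% total error — and are taken as
given; the MFC numerators follow the consensus guidelines on plasma-cell myeloma MRD reporting. Some
laboratories additionally correct the NGS limits for the uniqueness of the
clonal rearrangement; no functional form for that correction is published,
so the plain reciprocal forms are used and the numerators are configurable
(`AssayConstants`) so a corrected multiplier can be supplied. All values
are unitless fractions; "per million cells" is treated purely as an output
format. Limits exceeding 1 (samples with fewer than ~30 events) are clamped
to 1 and logged. A tumor count of zero is a valid measurement with TL = 0,
not missing data.

## Status decision algorithm

Exactly one of six rules fires per (TL, LOD, LOQ, cut-off), as described in
the README. Tie-breaks are inclusive on the favorable side — TL equal to
the cut-off is positive-branch, LOD equal to the cut-off is assessable, TL
equal to LOQ is quantifiable — and comparisons use a relative tolerance of
1e-9 so quotients like 30/3×10⁶ compare cleanly against literal cut-offs
such as 1e-5. These conventions are arbitrary at measure-zero boundaries
but fixed and documented for reproducibility. The rule id (`B1a`…`B2c`) is
recorded on every call for audit. Rule `B1c` (TL above the cut-off yet
below the LOD) is reachable only when the LOD itself exceeds the cut-off;
the engine supports it regardless of whether such samples occur.

Two cohort-level monotonicity properties follow from the rules and are
enforced by tests: lowering the cut-off never decreases positives and never
increases negatives, and any sample whose LOD is at or below the cut-off is
always assessable.

## Cohort analytics

**Concordance.** Pairs in which either method is nonassessable are set
aside as "LOD-discordant" before agreement is assessed; Cohen's κ =
(p_o − p_e)/(1 − p_e) with marginal-product expected agreement is computed
on the remaining 2×2 table, and the table size is reported alongside κ.
On the published 2×2 table (42, 14, 14, 43; n = 113) the definition-level
computation yields κ = 0.5044. The value printed in the source study for
the same table is 0.536; the discrepancy is documented here and the
definition-level value is the one this package reports and tests — the
exact input underlying the printed value is unknown. A degenerate table
with all mass in one agreement cell (p_e = 1, p_o = 1) returns κ = 1.

**Response stratification.** MRD-negativity is tabulated per serological
remission stratum; the "≥VGPR" aggregate pools CR, nCR and VGPR only
(denominator 54+31+24 = 109 in the reference configuration), excluding
PR/MR/baseline/NA. Empty strata report proportions as undefined, not 0%.

**Tumor-load comparison.** Among concordant MRD-positive pairs the TLs are
compared on a log₁₀ scale by default (they span ~5 decades; a linear option
exists): Pearson product-moment correlation and a two-sided paired t-test.
The published analysis pairs only the doubly-positive samples, which is
the only well-defined pairing, and removes "two extreme outliers" without a
stated criterion; here the k pairs (default k = 2, configurable) with the
largest absolute residuals from the least-squares line of log MFC TL on
log NGS TL are removed and identified by patient id. A paired t-test on
identical vectors returns t = 0, p = 1 by convention (the difference is
identically zero).

## Synthetic cohort generator

The generator emulates the sampling situation of a 125-patient paired
bone-marrow MRD study; trial data are not publicly deposited, so it is the
test bed for every cohort-level routine. Per patient: response category ~
categorical(54, 31, 24, 7, 1, 1, 7)/125 over CR/nCR/VGPR/PR/MR/baseline/NA;
a residual-disease Bernoulli (truly negative marrows have TL exactly 0);
for residual disease, log₁₀ true TL ~ Normal(μ_response, 0.8) clamped at
5×10⁻² (beyond ~5% plasma cells one is no longer in the residual-disease
regime); assay-specific effective TLs multiply in independent
Normal(0, 0.4) log₁₀ noise; cells assayed ~ log-uniform over the observed
ranges (NGS 1.8×10⁵–2.3×10⁶ cell equivalents, MFC 1.0×10⁶–1.4×10⁷ events);
detected counts ~ Binomial(N, effective TL). Binomial rather than Poisson
counting respects `k ≤ N`; the Poisson form `1 − exp(−TL·N)` serves as the
analytic cross-check for detection rates of rare clones.

Calibration constants (per-response negativity probabilities 0.65/0.50/
0.18/0.05/0/0/0.40 and log₁₀ TL centers −4.5/−4.2/−3.8/−3.2/−3.0/−1.5/−4.0)
were chosen once so that stratified negativity falls near the reference
CR/nCR/VGPR rates and positive TLs center near 10⁻⁴–10⁻³·⁵; they live in
`SimulationConfig`, not in code. The cross-assay noise of 0.4 decades on a
0.8-decade TL spread plants a log-TL correlation of
0.8²/(0.8²+0.4²) = 0.8 between assays, matching the reference
outlier-corrected estimate; parameter-recovery tests verify the planted
value is recovered within sampling error at n ≈ 40 pairs.

What the generator deliberately does **not** model: background or
contamination counts (so zero-truth patients never yield false positives),
hemodilution of the aspirate, longitudinal timepoints, serological
kinetics, or clone evolution. Consequently, passing tests demonstrate the
pipeline's arithmetic and decision logic under idealized binomial sampling,
not robustness to those real-data artifacts; the first two are the natural
extension points.

Cell counts are log-uniform over the published ranges because only medians
and ranges are reported; the resulting simulated medians differ from the
published medians (a log-uniform's median is the geometric mid-range), so
reconstruction fixtures that must hit printed marginals exactly
(`reference_cohorts`) pin cell counts to the printed medians instead.

## Reconstruction cohorts

`mrdeval.reference_cohorts` builds deterministic synthetic stand-ins whose
raw measurements are chosen so the pipeline reproduces published summary
tables exactly: the 42/43/14/14/12 concordance partition, the response-
stratified negativity (60/109 NGS, 54/109 MFC — note 60/109 = 55.05%, which
the source rounds to 55.1%), and the sweep endpoint with 44/125 NGS samples
nonassessable at 10⁻⁶. They are reconstructions of marginals, not the real
per-patient data, and are labelled accordingly.

## Problem sizes and numerics

Default analysis runs use 125-patient cohorts; property tests use up to
10⁵ random rule evaluations, 100 seeded cohorts for monotonicity, and a few
hundred patients for recovery checks — all chosen as the smallest sizes at
which the Monte-Carlo error bands in the assertions are comfortably
separated from the effects under test. Randomness flows exclusively through
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
cohorts. Proportions in CSV outputs are percentages to one decimal
(matching the field's reporting style); JSON outputs carry full precision.
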