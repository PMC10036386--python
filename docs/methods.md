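# Methods

## The mixture model

Plasma cfDNA in pregnancy is a two-compartment mixture: a maternal
compartment of proportion `1 − ff` and a placental ("fetal")
compartment of proportion `ff` (the fetal fraction). A heterozygous
22q11.2 deletion carried by a fraction `c` of the cfDNA removes half of
that fraction's copies, so the expected read depth inside the deleted
interval, relative to a diploid baseline, is

    E[ratio] = 1 − c/2,    c = ff        (fetal de novo / paternally inherited)
                           c = 1 − ff    (maternal carrier, fetus unaffected)
                           c = 1         (maternal carrier, fetus affected)
                           c = 0         (no event)

Inverting the observed mean ratio `r` over the called interval gives the
**event-specific fraction** ε = 2(1 − r), clipped to [0, 1], and the
**mosaicism ratio** MR = ε / ff. Analytically MR = 1 for any fetal
event regardless of ff, (1 − ff)/ff for a non-transmitted maternal
event, and 1/ff for a transmitted one. At typical fetal fractions
(median 10.48% in the reference cohort) maternal events therefore sit
far above fetal ones, and a single cutoff MR > 3 separates the origins.
The separation genuinely fails when ff > 0.25: (1 − ff)/ff < 3, and a
non-transmitted maternal event is indistinguishable from a fetal one by
MR alone — the classifier reproduces this failure mode by construction.
An optional secondary rule flags *likely maternal* whenever ε > 0.5,
which no purely fetal event can produce.

## Coordinate model

Default coordinates are representative GRCh38 positions for the LCR22
A–D blocks and the three standard FISH probe targets, all overridable
via BED files; nothing downstream depends on the absolute values, only
on the architecture (blocks ordered A < B < C < D, probes strictly
between A and B). The canonical A–D deletion in the default model is
2.55 Mb, one bin-width away from the commonly cited ~2.54 Mb. The
deletion menu holds the recurrent LCR-to-LCR intervals (A–D 2.55 Mb,
A–B 1.40 Mb, B–D 1.15 Mb, C–D 0.55 Mb) plus a 0.65 Mb nested interval
inside A–B.

The analysis window is 7 Mb (140 bins of 50 kb) centred on the LCR
cluster. The window is deliberately wider than the largest deletion:
sample depth is normalized *within* the window (standing in for the
genome-wide normalization of a production assay), so enough unaffected
bins must remain to anchor the scale even when the A–D event removes
51 bins. Regions whose length is not a multiple of the bin width are
padded up to the next bin boundary; the padding is recorded on the
model.

## Synthetic cohorts

`simulate_sample` draws each bin independently with mean
`mean_depth × (1 − f_b·c/2)` where `f_b` is the bin's fractional
overlap with the deletion — boundary bins are attenuated
proportionally. Counts are Poisson by default; a single dispersion
parameter `d` switches to a gamma–Poisson (negative binomial) with
variance `m + d·m²`. Defaults: 1000 reads per bin, dispersion 0,
reference panel of 50 unaffected samples.

`generate_cohort` draws the latent variables of a screen-positive
cohort at the reference study's composition: 57.7% maternal carriers,
50% transmission risk, ~0.8% paternally inherited among fetal events,
85% weight on the common A–D deletion and 15% on nested intervals,
fetal fraction lognormal with median 0.1048 (σ = 0.45, truncated to
[0.02, 0.45] to match the printed range), 51.1% ultrasound-flagged, and
diagnostic-testing dispositions at the observed cohort rates. The
lognormal shape and the nested-deletion menu weights are modelling
choices, not estimates — the source series reports only medians and
ranges for these.

What the simulator does **not** model: GC/mappability bias (a per-bin
multiplicative bias hook exists, default all-ones), read-level
artefacts, twin pregnancies, fetal-fraction estimation (ff is an input
throughout), and any genome-wide content outside the 22q11.2 window.
Passing round-trip tests therefore demonstrate the internal consistency
of caller and classifier under this noise model, not performance on
real sequencing data.

## Deletion calling

A profile is normalized to unit mean depth over bins outside the
current candidate interval and divided by the reference panel's per-bin
mean; per-bin z-scores use the panel's per-bin sd (floored at 1e-3).

**Detection.** Every contiguous bin interval of ≥ 2 bins is scored with
a scale-error-corrected aggregate

    z* = Σ z_b / √k / √(1 + k/m)

where `k` is the interval length and `m` the number of bins the depth
scale was estimated from. The correction matters: the scale error
(sd ≈ σ/√m) shifts all candidate bins coherently, inflating the naive
aggregate's variance by 1 + k/m, and without it large null intervals
systematically self-select after complement rescaling. Candidates are
capped at `n − 10` bins so a scale anchor always remains. Because a
large deletion drags the sample's own mean down and masks itself under
single-pass scaling, the candidate is refined iteratively (rescale on
the complement, rescan, up to 5 rounds). The call is accepted iff the
final z* ≤ −5.0.

The threshold is a tunable default chosen specificity-first: at −5.0
the measured false-detection rate on null simulations is ~0.03%
(1/4000), well under the 1% design target, while full-size fetal
deletions remain detectable down to ff ≈ 0.05 at the default depth.
Sensitivity for *small* fetal deletions at low ff is intrinsically
limited (an 11-bin C–D event at ff = 0.08 carries a ~4σ aggregate
signal at depth 1000); the reference assay reports the same limitation.

**Localization.** Breakpoints come from a second, uncorrected scan
(argmin of Σ z_b/√k): for a uniform depression the raw aggregate grows
in magnitude all the way to the true extent, whereas the corrected
statistic penalizes length past n/2 bins and truncates calls. The
reported size is the called bin count × 0.05 Mb — always a whole number
of bins, which is why 2.35, 2.55 or 0.65 Mb are representable sizes and
2.54 Mb is not, and why every size carries a ±1-bin breakpoint
uncertainty. ε is estimated from the 10%-trimmed mean ratio of the
called bins, for robustness to partially overlapped boundary bins.

A maximum-likelihood changepoint refinement (Kadane scan of per-bin
log-likelihood ratios at the estimated depression level) was evaluated
and performed identically to the raw-argmin localization; the simpler
rule is kept.

## FISH advice

A probe "detects" a predicted interval iff they overlap by ≥ 1 bp
(hybridization efficiency and mosaicism limits of FISH are not
modelled). FISH is listed as an acceptable confirmatory assay only when
*all* configured probes overlap the predicted interval; microarray is
always recommended first, and maternal testing is advised for
likely-maternal calls. Enlarging a predicted interval can only add
probe overlaps, never remove them.

## Cohort statistics

PPV in a partially verified screening cohort is reported under five
accountings: `complete` = TP/(TP+FP) over completely tested cases;
`fetal_only` = the same restricted to suspected-fetal cases with fetal
testing; `conservative` = TP/(TP+FP+incomplete); `upper_bound` counts
every unverified case as a true positive over the whole cohort;
`lower_bound` = TP/total. On any cohort, lower ≤ conservative ≤
complete ≤ upper.

Confidence intervals default to the Wilson score interval without
continuity correction; continuity-corrected Wilson and Clopper–Pearson
are selectable. The interval method used by the original web-calculator
CIs could not be identified — none of the three reproduces those
printed bounds — so CI bounds are treated as method-dependent and only
the PPV point values are reproduced. Reported percentages are rounded
half-up to one decimal, matching the reporting convention.

The Wilcoxon rank-sum test uses midranks and is exact (full enumeration
of labelings, valid under ties) for pooled n ≤ 20, with a tie- and
continuity-corrected normal approximation beyond; the two-sided p
doubles the smaller one-sided tail, capped at 1. Fisher's exact test
reports the two-sided hypergeometric-summation p and the sample odds
ratio ad/bc (Haldane–Anscombe +0.5 when a cell is zero). Size
concordance is ordinary least squares of confirmed on estimated size.

## The 307-case fixture

The deterministic fixture rebuilds a published single-laboratory
screen-positive cohort from its marginal counts (307 = 177 suspected
maternal + 130 suspected fetal; 194 tested as 83 fetal-only /
76 maternal-only / 35 both; 17 incomplete; 177 complete with 176 true
positives and 1 false positive; 157 ultrasound-flagged, 95 cardiac;
118 fetal-tested, 54 deferred postnatal; 43 suspected-maternal cases
with fetal testing, 25 inherited). One printed count is ambiguous —
"testing available for 105" suspected-maternal cases — and is read as
*maternal* testing for 105 (97 complete + 8 incomplete), the only
reading consistent with every other margin. Which individual case
carries an ultrasound/cardiac/deferred flag is not identifiable from
marginals; flags are assigned deterministically in row order, with
ultrasound enriched among fetal-tested cases to echo the reported
association. Unverified cases keep confirmation status `unknown`,
never imputed.

## Problem sizes and determinism

Simulation-backed checks run at the sizes they are specified at: 500
samples for origin recovery (ff ∈ [0.05, 0.20]), 100 detectable cases
for size recovery and concordance (ff ∈ [0.05, 0.30], the round-trip
validity range), 500 null samples for specificity. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`;
pipeline runs embed the seed and a configuration hash in every output,
and identical seed + configuration reproduces byte-identical bundles.

## Known limitations

- ε = 2(1 − r) is this package's definition of the event-specific
  fraction, consistent with heterozygous-deletion dosage; the reference
  assay's internal definition is not public and cannot be compared.
- The caller is a single-region scan, not a genome-wide CNV pipeline:
  no GC correction, no aneuploidy calling, no segmentation beyond one
  contiguous interval per sample.
- Origin classification is evaluated on called events; samples below
  the detection limit produce no call and hence no origin assessment.
- Cohort-level medians (MR 1.023/8.354, sizes 2.35/2.75/0.65 Mb) and
  test p-values from the reference series depend on per-case data that
  was never published; they are covered qualitatively by the analytic
  model and property tests, not reproduced numerically.
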