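# Methods

## Decision model

Every suspected-VTE patient receives a D-dimer test; confirmatory imaging
(CTPA on the PE pathway, CUS on the DVT pathway) is performed only when the
concentration reaches the strategy's cut-off. A concentration strictly below
the threshold is a negative call (VTE excluded); a value exactly equal to
the threshold is positive. This tie convention is fixed throughout: "below
the cut-off" reads as a strict inequality, and it makes every classification
a deterministic function of (age, concentration, strategy).

The six strategies are threshold functions of age only:

* m1: 0.5 mg/L. The conventional assay cut-off.
* m2: age × 0.01 mg/L strictly over age 50, else 0.5. Age 50 itself uses
  0.5 ("over 50" is read as strict).
* m3: 0.5 + (66 − age) × 0.01 mg/L below age 66. From age 66 the formula
  would fall below the assay convention, so it is clamped at 0.5: a rule-out
  threshold below the assay's detection convention would be meaningless.
  Thus m3 raises the bar for *younger* patients (0.98 mg/L at 18) and meets
  m1 at 66.
* m4: 1.0 mg/L fixed.
* m5: the smallest observed concentration whose empirical specificity
  reaches 95% on the cohort at hand.
* m6: the observed concentration maximizing Youden's J = sens + spec − 1,
  ties broken toward the lower threshold.

m5/m6 are data-derived: candidate thresholds are the observed values
(empirical-ROC convention), and the rules are unusable until resolved
against a cohort; resolved values are echoed into every run report.

## Synthetic cohort generator

Only age-stratified summaries of the reference cohort are available: per
age group the D-dimer median with IQR, the count of controls below
0.5 mg/L (219/374 overall), and the count of VTE patients below 1.0 mg/L
(6/152 overall, none below 0.5). The generator turns those summaries into
patient-level data under these modelling choices:

**Marginal law.** Within each age group, D-dimer is log-normal — the
standard stand-in for a positively skewed biomarker summarized by
median/IQR. `sigma` comes from the symmetric-quartile fit
`ln(q75/q25) / (2 z_0.75)`; groups of size 1 print no IQR and borrow the
arm's median sigma.

**Hard quotas as strata.** The sub-threshold counts are imposed exactly,
not in expectation: each group is split into a below-quota stratum and an
above-quota stratum, each sampled from the correspondingly truncated
log-normal (inverse-CDF sampling; an interval whose mass falls below 1e−6
raises an infeasibility error instead of hanging). Values are quantized to
3 decimals (half-up) at generation time, with sampling margins of 6e−4
below each quota boundary so quantization can never move a value across it;
cohorts therefore round-trip bytewise through CSV and all counts are exact
for every seed.

**Zero-false-negative enforcement.** The published analysis reports zero
false negatives for m1–m3. Each VTE patient's value is therefore drawn
above max(0.5, m2 threshold, m3 threshold) for their age; the designated
sub-1.0 patients are drawn inside (that maximum, 1.0), so the 1.0 mg/L
strategy misses exactly those 6 patients and the stricter strategies miss
none, by construction. This is a calibration constraint, not an empirical
finding: the tests that assert it verify the generator, not diagnostic
reality.

**Median-preserving mu calibration.** Forcing exact quotas shifts a group's
median away from `exp(mu)` (e.g. forcing 2/35 VTE values below 1.0 pulls the
56–65 group's median about 5% low). `mu` is therefore re-solved per group so
the *stratified mixture's* population median equals the printed median; the
mixture CDF at the target is monotone in `mu`, so a Brent root-find
suffices. One printed target is genuinely unattainable: the 46–55 control
group prints median 0.5 while quota-ing 37/65 values below 0.5, so any
sample honoring the quota has its median (33rd of 65 order statistic) below
0.5 — the printed value is evidently a one-decimal rounding from below.
That group (and any other unattainable target) keeps the plain
`mu = ln(median)` fit; its generated median settles near 0.43.

**Composition.** Ages are uniform integers within group bounds (extreme
groups bounded at [18, 24] and [86, 100]). The 83 PE / 69 DVT split is
apportioned across VTE age groups by largest-remainder rounding and
assigned randomly within groups; PE implies the CTPA pathway and DVT the
CUS pathway. Controls are assigned CTPA with probability
`control_ctpa_fraction` (default 0.5 — the true pathway split of the
reference cohort is not published, and the per-pathway saved-exam split
depends on it; it is exposed in the spec file). The pretest-probability
field is carried only (low/moderate/high with fixed per-status
probabilities loosely shaped like the published Wells-score medians);
nothing downstream consumes it.

**What the generator does not emulate.** No within-group age–D-dimer
copula is imposed: the cohort-wide positive rank correlation between age
and D-dimer emerges from group-level differences only, and is much weaker
(mean Spearman ≈ 0.03) than the published patient-level correlation
(0.166). Comorbidity structure, cancer stage and the published AUCs
(0.94–0.95) are likewise not targets: the synthetic separation between
VTE and non-VTE values is governed by the group summaries plus the
enforced floors, and comes out higher than the real data's. Passing tests
demonstrate that the pipeline reproduces the published *arithmetic* and the
summary-level calibration, not that it recovers patient-level diagnostic
performance.

## Diagnostic statistics

Confusion tables partition a scope of the cohort; the subgroup analyses
pair PE cases with CTPA-pathway controls and DVT cases with CUS-pathway
controls, since the published subgroup denominators are not stated. This is
one reason printed subgroup specificities cannot be exactly reconstructed.

AUC is the Mann–Whitney statistic with half credit for ties; its variance
uses DeLong's placement components: with `V10_i` the mean pairwise win of
case i over all controls and `V01_j` the analogous control placement,
`var(AUC) = var(V10)/m + var(V01)/n` and the CI is normal-theory, clipped
to [0, 1]. Both are implemented directly (vectorized O(mn)); tests check
them against an exhaustive pairwise oracle and a bootstrap.

`metrics_from_summary` reconstructs a printed (sensitivity, specificity,
group sizes) row: integer counts by half-up rounding drive PPV/NPV, while
the likelihood ratios are computed from the given proportions directly —
the convention under which printed rows like sens 64% / spec 95% yield
PLR 12.8 (the count-reconstructed ratio would be 12.6). Ratios with a zero
denominator (PLR of a perfectly specific test) are reported as absent, not
infinite. All internal arithmetic is unrounded; half-up display rounding to
integer percent and one-decimal ratios lives in `display_metrics` only.

Spearman correlation delegates to `scipy.stats.spearmanr` (tie-corrected
mid-ranks, two-sided t-approximation p); a constant vector raises rather
than returning NaN.

## Cost model

A patient saves an examination relative to the reference strategy iff the
reference calls them positive and the evaluated strategy negative; with the
reference at 0.5 mg/L and all other thresholds at or above it, the reverse
direction is impossible and saved counts are monotone in the threshold.
Savings are counts × tariff, split by pathway. D-dimer assay costs cancel
between strategies (every strategy tests everyone) and never enter savings;
they enter only the optional percent-reduction baseline, whose default —
one assay per patient plus reference-strategy imaging within the pathway
subgroup — is a package choice (the published percent figures never state
their denominators) and is echoed in reports.

Rounding pipeline: components and totals are rounded half-up to whole
currency units for display only; annualization always scales the
*unrounded* cohort total by annual volume / cohort size (5475/526 by
default). This order reproduces the published annual figures exactly;
annualizing pre-rounded totals does not. Two known 1-unit artifacts of the
published rounding are reported as computed: 5 × €18.89 = €94.45 displays
as €94 (printed: €95, hence a €5130 vs €5131 total), and the €53,400.7
annualized inverse-age-adjusted saving displays as €53,401 (printed:
€53,400). The run layer logs a warning whenever rounded components do not
sum to the rounded total.

The ROC-optimal strategy (m6) is excluded from cost runs by default — its
false-negative load disqualifies it as a rule-out strategy — and can be
re-included by flag. Annualization uses the overall 5475/526 factor, which
is what the published annual figures imply; a per-pathway variant
(1825 PE / 3650 DVT) is expressible through `AnnualVolume` but has no
published ground truth.

## Problem sizes and numerical choices

Default cohorts are 526 patients and generate in ~15 ms, so the calibration
properties are tested over 100–200 seeds. Estimator checks use exhaustive
oracles on cohorts of ≤ 60 patients, a 2000-replicate bootstrap at 20/20,
and 500 binormal replicates at 40/40 for DeLong CI coverage. Seeds are
fixed in tests; every stochastic function takes an explicit seed or
Generator. Monetary equality is asserted exactly after half-up display
rounding; calibration tolerances are 5% (headline group mean) and 10%
(per-group medians), as stated with each test.

## Known limitations

* The generator reproduces summary statistics and hard counts, not the
  joint distribution of the real data; AUCs and data-derived cut-offs
  (m5/m6) on synthetic cohorts differ from the published 4.9 / 9.9 mg/L.
* The published subgroup metrics (and Method 5/6 false-negative counts)
  depend on unpublished denominators and cannot be reproduced from printed
  data; the package computes its own and documents the divergence rather
  than fitting to it.
* Percent-reduction figures depend on a baseline definition the published
  analysis leaves implicit; the default here is explicit and configurable.
* Cost-minimization assumes equal downstream effectiveness across
  strategies; missed diagnoses, treatment costs and quality-of-life effects
  are out of scope.
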