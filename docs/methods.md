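# Methods

This note documents the statistical machinery, the synthetic-trial generator
it is exercised on, the numerical choices, and the known limitations.

## Outcome classification

A participant's outcome calls are a pure function of her record; missing data
is a classification outcome, never an error.

* **Prolonged abstinence** (primary-outcome scaffold): the end-of-pregnancy
  self-report indicates abstinence, at most 5 lapses occurred between two
  weeks post target-quit-date (TQD) and delivery, and no week after the
  two-week grace window (weeks 3–4 of the weekly timeline) was reported as
  smoking. A missing end-of-pregnancy report classifies as non-abstinent.
  A missing *weekly* report does not disqualify: only a positive smoking
  report does. Records never carry a TQD date; the weekly timeline is indexed
  relative to it, so participants who never set a TQD are classified on the
  same four slots (a fixed convention — the source protocol is silent).
* **Validation hierarchy**: nicotine-product non-users are judged on salivary
  cotinine alone (< 10 ng/ml, strict); current users of either product on
  salivary anabasine (< 1 ng/ml) or expired CO (< 8 ppm), with the CO verdict
  prevailing whenever a CO reading exists. A non-user with a CO reading but
  no usable saliva sample is *not* validated: CO is a fallback only on the
  product-user path, because cotinine is uninformative under nicotine-product
  use while CO is specific to smoke. No usable measurement ⇒ non-abstinent.
  A participant abstinent at delivery but relapsed by the time of contact
  counts as self-reported abstinent and validated non-abstinent.
* **Reduction** (≥ 50% fewer cigarettes/day than baseline, boundary
  inclusive) is only defined for participants not point-prevalence abstinent;
  its validated version applies the same assay hierarchy.
* All thresholds live in `pregquit.constants`, strict inequalities exactly as
  defined; boundary values (cotinine 10.0, anabasine 1.0, CO 8.0) fail.

## Estimands and analysis sets

Four analysis sets for any binary outcome: intention-to-treat (all
randomized, missing = failure); per-protocol (started the allocated product
and had any study contact); exclusion of abstinent non-allocated-product
users from numerator *and* denominator (the "regular non-allocated use" flag
is the adherence-table disjunction: 5+ consecutive days in the first 4 weeks,
current use at end of pregnancy, regular use ≥ 1 week, or occasional use
≥ 3 weeks); and reclassification of those participants as non-abstinent with
denominators kept. Exclusion is outcome-specific: each outcome's own
abstinence call decides who is an abstinent switcher for that row, which is
why the excluded-set denominators differ by outcome.

The risk-ratio engine is the closed-form Woolf estimator; for a single binary
covariate this is exactly the maximum-likelihood log-link binomial
regression, so no iterative fit is used. Intervals are exp-symmetric Wald;
zero-event rows are "NC" — no continuity correction anywhere (the χ² is also
uncorrected). Report rounding is half-up, two decimals for ratios.

The contamination calculator mirrors the worked illustration's integer
bookkeeping (expected counts rounded half-up); a continuous mode
(`integer_bookkeeping=False`) supports the grid property that
abstinent-only exclusion dominates both ITT-with-crossover and all-switcher
exclusion in maximum absolute deviation from the true rates.

**Design calculation**: pooled-variance normal approximation, no continuity
correction, per-arm n the ceiling of

    (z_{1−α/2}·√(2·p̄q̄) + z_{1−β}·√(p₁q₁ + p₂q₂))² / (p₁−p₂)².

This choice uniquely reproduces the trial's 570 per arm from (0.08, 0.14,
α=0.05, 1−β=0.90). The formula is mildly conservative against direct
simulation of the pooled z-test (for (0.10, 0.30, 0.05, 0.80) it gives 62 per
arm where simulated power first reaches 80% near 59); the test suite asserts
achieved power at the formula's n is at or slightly above nominal, not that
the formula inverts the simulation exactly.

**Bhapkar test**: Wald statistic on the first k−1 marginal differences with
the multinomial covariance estimated under the alternative, df = k−1;
verified against an explicit vec-multinomial quadratic form.

**Cluster-robust interval for twin-inclusive birth outcomes**: the point
estimate is the plain ratio of infant-level proportions; the interval is the
percentile interval over mother-level bootstrap resampling (default 2,000
replicates, seeded, multinomial cluster weights). This stands in for a
model-based cluster sandwich estimator; in the all-singleton limit it matches
the analytic Wald interval to within 1% log-scale half-width, and on
correlated twin cohorts its empirical coverage is ~95%.

## Bayes factors

Half-normal prior on the true log RR (mode 0, scale = expected log effect),
point null at zero, normal likelihood with known se. Closed form:

    BF₁₀ = 2·N(d; 0, se² + s²)·Φ(μ_post/σ_post) / N(d; 0, se²),

computed in log space (the null density underflows when |d| ≫ se) and
cross-checked against adaptive quadrature of the density *ratio* to 10⁻⁶
relative error. The default prior scale is log 1.8, anchored on the quit-rate
ratio of the earlier e-cigarette-vs-NRT cessation trial; the exact anchor
used for the published factors is not printed, so the primary-contrast factor
is checked against the plausible reconstruction band (≈ 2.67–2.80; this
implementation gives 2.79) and the other factors at category level
(supports-effect at the conventional 3 and 1/3 cut-offs). The birthweight
prior (from a nicotine-vs-placebo patch study) is unknown; that factor is
computed but not asserted against any published value.

## Multiple imputation

Chained equations over three binary variables — self-reported sustained
status, biochemical validation result, current nicotine use — separately by
arm (m = 50 completed datasets, 10 cycles by default). Each incomplete
variable is regressed on the other two plus seven auxiliaries (FTCD, lives
with a smoker, cigarettes/day, education as two indicators, employment,
allocated daily use over the four intervention weeks, week-4 point
abstinence) by iteratively reweighted least squares with ridge 10⁻⁴ (guards
perfect separation); missing values are redrawn from the fitted
probabilities each cycle. The validated sustained-abstinence outcome is
derived passively as (self ∧ validation) after imputation, never imputed
directly. Rubin's rules pool on the log-RR scale with
T = W + (1 + 1/m)·B and the large-sample degrees of freedom.

Numerical/design notes:

* Coefficients are used at their fitted values, *not* redrawn from an
  approximate posterior. With event rates near 5–10%, perturbing the
  coefficients inflates imputed probabilities through the logistic
  nonlinearity and measurably attenuates the pooled RR; the fitted-value
  redraw is the least biased variant at this scale. The cost is that B
  understates coefficient uncertainty — pooled intervals are somewhat
  anti-conservative.
* Initialization draws each missing value from the variable's observed
  empirical distribution; with zero missingness the pipeline returns the
  complete-case answer exactly (B = 0, normal reference).
* Known limitation, measured: on fully-ascertained trial-like cohorts with a
  20% completely-at-random mask, the pooled log RR carries a small positive
  finite-sample bias of ≈ +0.015 (≈ 1.5% on the RR; Monte-Carlo se ≈ 0.005
  at 200 replicates), stable across m ∈ {8, 20} and cycles ∈ {4, 10}. It
  stems from misspecification of the additive-logistic imputation model
  against the generator's structured truth (crossover-driven nicotine use
  interacts with quitting in the patch arm; week-4 abstinence is a
  near-separating predictor) at per-arm event counts of ~40–65. The
  corresponding recovery test asserts unbiasedness to 2 Monte-Carlo standard
  errors and therefore fails by design rather than hiding the bias.
* MI output is labelled a sensitivity analysis throughout: missingness in
  cessation trials is not random, and missing-as-failure remains the primary
  convention.

## Synthetic-trial generator

The generator's defaults *are* the study conditions: arms of 571/569;
prolonged-quit propensities 0.118 / 0.061 on the allocated product (chosen so
that, after crossover rescue and 93%/91% ascertainment, the observed ITT
self-reported prolonged rates land near 11.0% / 7.7%); crossover among
allocated-product failures 0.032 / 0.193, with switchers succeeding at the
other product's rate (marginal regular non-allocated use ≈ 2.8% vs ≈ 18%);
saliva return 0.551 among self-reported quitters; 8% of self-reported
quitters biochemically misreporting; a 5% relapsed-by-contact state among
quitters reached late; baseline cotinine log-normal with median 115 ng/ml and
IQR ≈ (75, 170); abstainer cotinine log-normal with median 2 ng/ml (well
under the 10 ng/ml cut-off; product users keep high cotinine but low
anabasine/CO, exercising the user validation path); a birth model with ~1%
twins, preterm probability 0.115 / 0.075 by end-of-pregnancy smoking status,
and birthweight tied to gestational age (140 g/week below 39 weeks) so that
low birthweight (< 2,500 g) is a derived flag with marginal frequency
≈ 0.12–0.14 and mean birthweight ≈ 3.1 kg.

Randomness: one seed sequence per cohort, spawned into a fixed child stream
per arm, so cohorts are byte-identical given (config, seed) and one arm's
draws are independent of the other's size.

What the generator deliberately does not emulate: joint distributions the
trial never reported (product use and quitting are independent except through
the crossover-rescue channel; assay values are independent log-normals given
smoking status; no time dynamics, no behavioural feedback, no external shocks
to product use). Passing tests therefore demonstrate that the *procedures*
behave correctly under the trial's marginal structure, not that the synthetic
cohorts reproduce unpublished participant-level joint behaviour — which is
also why per-protocol denominators, the multiply imputed quit rates and the
paired nicotine-strength test are exercised on synthetic data without
asserting the trial's printed values for them.

The worked-example generator has two modes: expected-value (deterministic
half-up rounding of expected counts, reproducing the illustration's
arithmetic exactly: ITT 28%/24%, all-switcher exclusion 100%/33%,
abstinent-only exclusion 12%/21%) and stochastic (per-participant draws that
converge to the same rates).

## Problem sizes in the test suite

Simulation-backed checks use sizes chosen to keep Monte-Carlo error well
inside the asserted bands: interval coverage over 1,000 trial-like cohorts
(binomial se ≈ 0.7% around 95%), estimand-dominance over 400 random
parameter draws, BF closed-form-vs-quadrature over 1,000 random triples,
MCAR recovery over 200 replicates with m = 8 and 4 cycles, and twin-cluster
coverage over 500 cohorts of 150 pairs per arm with 500 bootstrap replicates.
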