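# Methods

## The audit model

One row of the call table is one OHCA emergency call, with all event times
in seconds from the moment the call was answered (voice-log granularity is
seconds; fractional seconds are accepted and never rounded on read).
Missingness is explicit everywhere: `None`/empty-cell is distinguishable
from `false`/`0` for every nullable field, and unknown enum labels are an
error rather than a silent reclassification — audit data must not be
quietly coerced.

### Exclusion cascade

The cascade applies three per-record classifiers in sequence, with a fixed
reason priority so each excluded call is counted exactly once:
study-level `ALIVE_DURING_CALL` before `MISSING_AUDIO`; recognizability
`CPR_IN_PROGRESS` before the recorded barrier.  The schema stores a single
dominant barrier per call per filter, which is how single-reason flowchart
bookkeeping stays conservative: at every stage the retained count plus the
per-reason exclusion counts equals the stage input, and the report
constructor asserts this.  `n_recognized` is recognition *among
recognizable* calls — the goal-2 numerator and the denominator of the
DA-CPR availability filter.  Registry-level exclusions upstream of the
audited sample (cases unavailable at extraction, EMS-witnessed arrests,
regional-dispatch regions, the national caseload) cannot be derived from a
call table and are carried as fixed context counts in the report.

### Performance goals

Proportion goals (1–3) are plain counts over the appropriate stage cohort.
Time goals (4–5) report the median and quartiles of the non-missing times
(type-7 linear interpolation of order statistics, the common statistical-
software default; the convention is configurable in spirit but fixed here
since printed medians are not recomputable without raw data) and
threshold attainment with two deliberate conventions:

* strict `<` at every threshold, matching the "< 60 s" phrasing of the
  benchmarks, so a time exactly at the threshold does not attain it;
* the attainment *percentage* denominator is the full stage cohort
  including time-missing records.  This matches the printed arithmetic of
  the source tables (e.g. 150/760 ≈ 20% recognized within 60 s despite 117
  missing recognition times): a call whose time could not be established
  certainly did not demonstrably meet the target.

Medians and IQRs, by contrast, are computed over non-missing times only;
no imputation is attempted.  Printed-style percentages are rounded
half-away-from-zero to the nearest integer; raw values are always kept
alongside.  Benchmark comparison is strict for time goals as well
(`met_high` iff median < 60 s, etc.).

### Additional-survivors estimator

`(p_met − p_not_met) × n_not_met`, floored.  Three choices:

* **Floor, not round.** The published worked arithmetic reports
  1.414% × 749 as 10 lives although the product is 10.59; truncation
  matches all three published examples, so the integer estimate is
  `floor(raw)` and the raw value is always reported.
* **Missing times miss the target.** A call with no established time
  cannot have met it, so it belongs to the not-met stratum; unknown
  30-day outcomes are excluded from the stratum survival *rates* (rates
  need known outcomes) but retained in `n_not_met` (the multiplier counts
  patients).
* **Non-negativity.** "Additional lives" is non-negative by construction;
  a negative raw estimate is floored at 0 for the headline integer and
  flagged `negative_effect`.

The national extrapolation multiplies the floored estimate by
`N_national / n_sample` and is reported unrounded and labelled an
approximation: it assumes the national caseload shares the sample's
characteristics, and no acceptance-grade meaning is attached to it.

The estimator is descriptive, not causal: it adjusts for nothing (initial
rhythm, age, witnessed status all differ between fast- and slow-handled
calls), and its printed-rate inputs cannot be re-derived from the
published tables, so in explicit-rates mode the rates are taken as given.

### Spline survival curves

Survival probability against a delay variable is modelled as
`logit(p) = β₀ + f(delay)` with `f` a restricted cubic spline in Harrell's
truncated-power form: for knots `t₁ < … < t_k` the design is `x` plus
`k − 2` truncated-cubic terms normalized by `(t_k − t₁)²`, which makes the
fit linear beyond the boundary knots with continuous value, slope and
curvature, and keeps all coefficients on a comparable scale.  Default
knots: 4, at the 5/35/65/95% quantiles of the observed delays
(configurable 3–7 at the conventional quantile sets); tied data that
collapse knots are an error advising fewer knots.

Fitting maximizes the Bernoulli likelihood by IRLS (statsmodels GLM,
binomial family), convergence at relative deviance change < 1e−8 within
100 iterations.  Complete separation or iteration-cap exhaustion yields a
*flagged* model (`converged=False`), never an exception; records with a
missing delay or outcome are dropped and counted.  Confidence bands are
pointwise Wald intervals from the coefficient covariance on the logit
scale, optional because the band type used in the original figures is not
specified.  Beyond the outermost knots the curve is a logit-linear
extrapolation and should be read with the usual caution at the data edge.

## The synthetic-cohort generator

The generator emulates the study conditions of a 1000-call national audit
sample; its defaults are the audit's own frequencies and are not tuned:

* stage frequencies 35/1000 alive during call, 29/1000 missing audio;
  barrier mix 97/23/10/9/4/33 per 936 included; recognition 645/760 among
  recognizable and 97/176 among non-recognizable (so overall recognition
  is 742/936); DA-CPR barriers 49/13/5/5/13 per 645; directed compressions
  343/560, spontaneous compressions 161/217 among available non-directed
  calls;
* event delays are log-normal — positive support and right skew match the
  reported median ≪ q3 asymmetry — with `(μ, σ)` matched by quartiles to
  the printed median/IQR triples (recognition 113 [62, 204] s, dispatch
  88 [64, 131] s, any compression 214 [146, 315] s, directed compression
  240 [176, 332] s, instructions 201 [137, 300] s).  `μ = ln(median)`; σ
  averages the spreads implied by the two quartiles;
* covariate marginals and missingness rates follow the published
  characteristics table (witnessed 59% of known, residential 73%, cardiac
  cause 58%, shockable rhythm 18%, age ≈ N(72, 14.8²) clipped to
  [1, 105], …).  Joint covariate dependence is *not* modelled;
* 30-day survival is Bernoulli with
  `logit(p) = α + β·(delay to first compression)`, slope β = −0.004 /s
  (roughly a one-third odds reduction per 100 s, a realistic strong decay)
  and calls without compressions assigned a 900 s reference delay
  (no bystander CPR until EMS arrival); the intercept α is root-found per
  cohort so that mean survival among included calls is 66/936 ≈ 7.05%.
  Survival is drawn from the *latent* compression delay before missingness
  masks are applied, so time-missing calls still carry coherent outcomes;
* missingness: recognition time 117/645, dispatch 1/936, compression time
  136/504, directed-compression time 40/343, instruction time 7/343,
  survival 47/936.

**Within-call ordering.** All caller-side delays of one call are driven by
a single standard-normal latent — a "call tempo": a slow call is slow at
recognition, instruction and compression alike.  This comonotone
construction preserves every configured marginal exactly (each delay is
its own quantile function evaluated at the shared latent) and makes
recognition ≤ instruction ≤ directed compression near-automatic; the rare
upper-tail inversions that remain where the distributions' spreads differ
are clamped.  The alternative — independent sampling with
truncation-resampling of the later event — was measured to inflate the
instruction and directed-compression medians by ~34% and ~62% and was
rejected for that reason.  Dispatch time is independent of the tempo
latent (it is dispatcher-side).

Randomness comes from numpy's `default_rng` (PCG64), fixed by the `seed`
parameter; identical parameters and seed reproduce the cohort
field-for-field.

**The `paper_counts` preset** is a deterministic 1000-call cohort whose
categorical structure reproduces every reference count exactly (stages
936/760/645/560, recognition 742 and 645, compressions 343 and 504, all
threshold-attainment and missing-time counts, 66 survivors with 47 unknown
among 936).  Times are filled from bucket-conditional log-normal
quantiles, so threshold counts are exact while medians land where the
bucket structure puts them; they are indicative, not target quantities.
(The published counts are in fact mutually inconsistent with the published
recognition median — 267 of 528 non-missing recognition times below 90 s
cannot coexist with a 113 s median — so no deterministic cohort could
reproduce both; the counts are the reproducible quantities and take
precedence.)  Survivors are spread over the delay ordering by a smoothly
decaying quota (weight `expit(−delay/250 s)`), so survival decreases with
delay without being linearly separable, which keeps spline fits on the
preset well-behaved.

**What passing tests do and do not show.**  The generator reproduces
marginal structure: stage proportions, delay medians/IQRs, covariate
marginals, an overall survival level, and a survival–delay gradient.  It
does not emulate joint covariate dependence, confounding between case mix
and call handling, dispatcher- or centre-level clustering, or the
unpublished stratum survival rates.  Tests passing on synthetic cohorts
therefore validate the *pipeline arithmetic and its conventions*, not the
epidemiology of any real registry.

## Numerical choices and degenerate inputs

* Quantiles: numpy `percentile` default (type-7) throughout, cross-checked
  in tests against an independent sort-based oracle.
* Empty denominators: a proportion goal over an empty cohort reports an
  undefined percentage, `met=False`, and an explicit `undefined` flag; an
  empty time variable yields a flagged empty metric with zero attainment.
* Stratification with no known outcomes in either stratum is an error
  naming the stratum (a rate cannot be formed), not a silent zero.
* Spline fits require at least one event and one non-event; constant
  outcomes are an error, separation is a flag.
* Report JSON is a pure function of (input bytes, config): re-running
  byte-identical output, verified in tests.

## Problem sizes

The test suite runs the deterministic 1000-call preset, property tests on
cohorts of up to ~30 records (50 derandomized examples each), spline
recovery at n = 5000, and one shared 20 000-call cohort for Monte-Carlo
parameter-recovery checks (proportions within 3 binomial standard errors,
delay medians within 5%, overall survival within 1 percentage point) —
sizes chosen so the whole suite completes in well under a minute while the
Monte-Carlo tolerances remain meaningful.

## Known limitations

* The estimator inherits the published method's optimism: no adjustment
  for survival predictors correlated with call-handling speed.
* Explicit-rates mode accepts stratum rates that cannot be re-derived from
  any public table; they are inputs, not outputs.
* The national extrapolation's scaling convention is ambiguous in the
  source material; it is reported unrounded and excluded from
  acceptance-grade quantities.
* Figure-level curve values of the original study are not machine-readable
  and are not reproduction targets; curves are validated against their
  mathematical properties (likelihood optimum, linear tails, monotonicity
  under monotone truth) instead.
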