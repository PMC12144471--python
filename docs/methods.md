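# Methods

`ppdwear` re-implements, as a reusable and fully tested pipeline, a
digital-phenotyping analysis of wearable-device wear time across four
pregnancy periods in females with and without postpartum depression (PPD).
The source data for studies of this kind (EHR events plus consumer-wearable
step and sleep streams under a bring-your-own-device model) are
access-restricted, so the package ships a synthetic generator that emulates
their structure; every stage of the analysis is exercised against it.

## Cohort phenotyping

A person enters the PPD cohort if, relative to her delivery date, she has
(1) a PPD diagnosis, (2) a depression diagnosis during the postpartum
period, or (3) an antidepressant exposure during the postpartum period,
within 24 months of delivery. Month-based phrasings are fixed to day counts
(24 months = 730 days, 9 months = 270 days) so the rules are reproducible
across locales. The PPD-diagnosis rule is inclusive of the delivery date;
the depression and antidepressant rules use an exclusive lower bound
because those events must fall strictly *during* the postpartum period.
Everyone else with a delivery is non-PPD; persons with depression evidence
only outside the 24-month window are labeled non-PPD and flagged in the
log. The index date is the earliest qualifying event (PPD cohort) or
delivery + 58 days (non-PPD), the median delivery-to-diagnosis delay.
When several deliveries exist the earliest is used. Pregnancy start is the
earliest recorded pregnancy event before delivery, else delivery − 270
days. Raw source codes are treated as opaque; vocabulary resolution is out
of scope.

## Period windows

Four half-open `[start, end)` windows per person, in chronological order:

| period       | PPD cohort                      | non-PPD cohort            |
|--------------|---------------------------------|---------------------------|
| prepregnancy | `[index − 730 d, preg_start)`   | same                      |
| pregnancy    | `[preg_start, delivery)`        | same                      |
| postpartum   | `[delivery, index − 14 d)`      | `[delivery, index)`       |
| PPD / PPD-eq | `[index − 14 d, index + 31 d)`  | `[index, index + 31 d)`   |

Inclusive endpoints ("30 days after the index") are folded in as `+1 day`.
The non-PPD fourth window has no 14-day lead because those persons had no
symptom onset; its index mirrors the 2-year prepregnancy lookback so the
cohorts stay comparable. The delivery day itself belongs to postpartum.
Boundaries are forced monotone (each start raised to the previous
boundary), so in the rare case of an index within 14 days of delivery the
PPD window is truncated at delivery and pregnancy is never overlapped; the
nominal window lengths (45 days PPD, 31 days PPD-equivalent) hold whenever
anchors are far enough apart. Window starts are then raised to the person's
first recorded step date, so nobody is counted as not wearing a device they
did not yet own; no upper clipping is applied — days after a device was
abandoned count as unworn.

## Wear derivation

An hour is worn iff its step count is ≥ 1 (a zero-step row does not encode
wear, so results do not depend on whether an exporter writes explicit
zeros). A day is worn (lenient) iff ≥ 1 worn hour; a day is a valid worn
day under the strict sensitivity rule iff ≥ 10 worn hours and a daily total
strictly between 100 and 45,000 steps. A day is worn-to-sleep iff it has a
main-sleep record. Per person-period summaries use every calendar day of
the clipped window as the denominator — days with no rows are unworn — and
report percent worn (lenient and strict), percent worn-to-sleep, the mean
hours on worn days, and the consistency statistic: the maximum run of
consecutive worn days.

## Statistical comparisons

* **Percent outcomes** (worn, strict, worn-to-sleep; one model per period):
  OLS of the per-person percentage on cohort plus covariates (age at index,
  continuous; race/ethnicity and the ten-level annual-income survey answer,
  treatment-coded). Cohort means are estimated marginal means over a
  reference grid balanced across categorical levels with age at its sample
  mean; 95% CIs use the coefficient covariance with normal quantiles; the
  cohort p-value is the OLS t-test of the cohort coefficient. Percentages
  are modeled on the 0–100 linear scale. An alternative observed-grid
  averaging convention is not implemented; the balanced grid matches the
  default of the estimated-marginal-means tooling standard in this setting.
* **Hours per worn day**: linear mixed model on worn-day rows with the same
  fixed effects and a person random intercept, fit by REML. The cohort
  p-value uses a normal (Wald) approximation — degrees-of-freedom
  corrections (Satterthwaite/Kenward–Roger) are out of scope and the choice
  is deliberately simple and documented. A zero random-intercept variance
  is a boundary solution and is accepted as converged; a stalled gradient
  optimizer is retried with Powell before erroring.
* **Correlations**: within-cohort Pearson r between period pairs
  (prepregnancy↔PPD, pregnancy↔PPD) for percent worn and for the
  consistency statistic; 95% CI by Fisher z with se `1/√(n−3)`; two-sided p
  from the t distribution with n−2 df; n ≥ 3 and non-constant inputs
  required.
* **Multiplicity**: each analysis family has four tests; the threshold is
  α/4 (0.0125 at α = 0.05, displayed as ".013"). Decisions always use the
  unrounded value.

Covariate levels present in only one row of a model's data are refused
(collapsing silently would change the design); the pipeline performs the
requested re-leveling explicitly, merging sub-singleton levels into an
`(other)` category once across all periods and logging it.

## Synthetic data generator

The generator emulates the study conditions, not any particular dataset:

* **Cohort sizes** default to 41 PPD / 101 non-PPD persons.
* **Events**: every person gets pregnancy-start and delivery events
  (pregnancy length 270 days, deliveries spread across a calendar year);
  PPD persons additionally get one qualifying event (type uniform over the
  three rules) at delivery + delay, delay lognormal with median 58 days and
  shape 0.6, clipped to [1, 730] so truth labels are always recoverable.
* **Daily wear** is a stationary two-state Markov chain per period with
  stationary worn probability p and lag-1 correlation ρ (default 0.3; the
  marginal law is Bernoulli(p) for every day). Defaults for p are the
  reported per-period adjusted means (PPD 47.5/46.8/69.9/66.6%, non-PPD
  48.6/40.5/50.0/46.4%). Day-to-day run-length behaviour has no published
  anchor, so ρ is exposed as configuration.
* **Frailty**: a per-person N(0, σ²) offset on the logit scale (σ default
  2.5) shared across periods induces within-person cross-period
  correlation and a wide between-person spread, matching the dispersion
  implied by the reported confidence intervals. Because
  `E[expit(logit(p)+σZ)] ≠ p`, the location is adjusted per cohort-period —
  solved by 64-node Gauss–Hermite quadrature and Brent root-finding — so
  the population mean worn probability equals the configured value for any
  σ.
* **Hours and steps**: a worn day receives k distinct step-hours,
  k = round(N(μ_h, σ_h)) clipped to [1, 24] (defaults 16 ± 3 h, echoing the
  15–17 h/day wear typical of such cohorts), with per-hour step counts
  Poisson (default mean 400) floored at 1 so presence encodes wear.
  A per-person offset on μ_h (sd 1.5 h) represents between-person habitual
  wear duration; without it the mixed model's random-intercept variance
  would be exactly zero by construction.
* **Sleep**: each worn day carries a main-sleep record with probability
  0.85; unworn days carry none.
* **Device ownership**: the first-wear date is drawn uniformly within the
  prepregnancy window (so first-date clipping is exercised); data before it
  are suppressed. A `window_start` mode pins ownership to the earliest
  window, giving clipping-free conditions for parameter-recovery tests.

What the generator does **not** emulate: heart rate or other modalities,
device-model heterogeneity, informative (missing-not-at-random) dropout,
seasonal or weekday structure, and EHR coding noise (labels derive from
planted events, so phenotype recovery is exact by design). Passing tests
therefore demonstrate correctness of the pipeline's logic and calibration
of its estimators under the assumed data-generating process, not robustness
to real-world coding error or wear-behaviour drift.

## Numerical and design notes

* Dates are ISO-8601; tables are CSV (RFC 4180) or Parquet.
* All randomness flows from one `numpy` `default_rng` seed; generation is
  deterministic and byte-identical across reruns, and results are invariant
  to input row order.
* Empty windows emit no summary row; a person with no step data at all is
  dropped by the eligibility filter with a logged reason.
* Small-cell suppression in the descriptive table ("<20") is a rendering
  option only and never mutates analysis outputs.
* Simulation sizes in the test suite (e.g. 500 persons per cohort for
  round-trip recovery, 500 replicates for estimator calibration, 2000 for
  CI coverage) were chosen so Monte-Carlo error is small relative to the
  assertion tolerances while the suite stays quick to run.

## Known limitations

* The Wald p-value for the mixed model is slightly anticonservative at
  small cohort sizes; the calibration test uses 40 persons per cohort where
  the effect is negligible.
* The balanced EMM reference grid weights rare covariate levels equally
  with common ones; with very unbalanced categories the estimated marginal
  means can sit far from raw cohort means (both are reported).
* Qualitative reproduction of the original significance pattern at large n
  is intrinsically limited: the reported pregnancy-period contrast (6.3
  percentage points) is detectable at n = 2000/cohort for any
  between-person spread a bounded percentage can have, so the package's
  large-n pattern check reproduces three of the four period decisions.
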