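# Methods

## Model and assumptions

A child-anthropometry indicator prevalence is the proportion of z-scores
below a threshold T (−2.0 throughout). For a normal distribution with mean
μ and SD σ that proportion is Φ((T − μ)/σ). Three assumptions underlie
everything downstream:

1. the observed z-score distribution is adequately normal;
2. in the absence of non-directional measurement error its SD would lie in
   the 0.8–1.2 range seen in high-quality anthropometric data, with 1.0
   used as the point reference;
3. directional (mean-shifting) error is small, so the observed mean can be
   taken at face value.

Under these, the prevalence bias attributable to non-directional error is
`Φ((T−μ)/σ_obs) − Φ((T−μ)/σ_ref)`. Because assumption 3 can fail silently,
the bias estimate is a diagnostic of data quality only and must not be used
to correct a reported prevalence.

Non-directional error is modelled as an additive, independent, zero-mean
normal perturbation per observation. It inflates variance additively
(σ_obs² = σ_true² + σ_err²) and changes individual classifications: an
observation moved below T is a "false positive", one moved above is a
"false negative" — defined relative to the noise-free sample, not to a
clinical gold standard. The net prevalence shift is identically
(FP − FN)/n, which the implementation asserts to 1e-12 (literal bitwise
equality is not guaranteed because a/n − b/n and (a−b)/n can differ in the
last ulp).

## Engines and numerical choices

- The closed-form CDF engine (scipy.stats.norm) is the default wherever a
  figure-level number is produced: it is exact and bit-reproducible. The
  Monte Carlo engine (numpy PCG64, 500,000 draws per distribution by
  default) reproduces the simulation-based construction and is validated
  against the closed form cellwise within 4 binomial standard errors; the
  generator name is recorded in output metadata.
- "Below threshold" is strict (`z < T`). Ties are measure-zero for
  continuous draws; the fixed convention keeps empirical counts
  deterministic.
- Proportions live in [0, 1] internally; percentage formatting happens only
  in the CLI/report layer.
- Experiments that both simulate and perturb use independent child streams
  spawned from one SeedSequence, so a base sample can be re-perturbed
  reproducibly.
- Extrema are located on the closed-form map only; Monte Carlo noise can
  flip the argmax between near-flat neighbouring cells.

## Grid defaults

The bias map spans μ ∈ [−4.5, 0.5] and σ ∈ [0.8, 2.0], the parameter region
relevant to LMIC child anthropometry, symmetric about μ = T = −2. The grid
spacing is a design choice: mean step 0.25 (which makes the reported
extremum locations −0.75 and −3.25 exact grid points; the continuous argmax
at σ = 2.0 is μ ≈ −0.64, and on the 0.25 grid −0.75 beats −0.50 by a small
margin) and SD step 0.1 (so the 0.8/1.0/1.2 anchors are grid points). Both
are configurable. Because |bias| grows monotonically in |σ − σ_ref|, both
whole-map extrema sit on the σ = 2.0 boundary; per-σ-slice extrema are also
exposed since the flat-top of the bias curve makes "the" extremum location
mildly convention-dependent.

## Survey assessment

- Weighted moments use the population form with Σw as denominator:
  mean = Σwz/Σw, sd = √(Σw(z−mean)²/Σw). Survey weights are expansion
  weights; a reliability-weight (effective-sample-size) correction would be
  negligible at survey n and is not applied. Any common rescaling of the
  weights leaves both moments unchanged.
- Missing z-scores are dropped per indicator, not listwise, because the
  three indicators have different missingness patterns. Fewer than two
  non-missing values raises an explicit insufficient-data error.
- Eligibility: rows with age outside [0, 60) months are dropped at read
  time (switchable). No biological-plausibility exclusion (|HAZ| > 6 etc.)
  is applied by default; an optional flag blanks such values.
- The age-heaping ratio counts children whose age, rounded to the nearest
  integer month, lies within ±1 month (inclusive) of 24, 36 or 48 months,
  divided by all children in the survey. 12 months is not a default target
  because eligibility designs that split at 18 months can create a
  12-month cluster unrelated to age estimation; `excluded_ages` can
  additionally remove such clusters from the denominator. Under uniform
  0–59-month ages the expectation is 9/60 = 15%. The ratio deliberately
  ignores survey weights.
- Digit-preference tests are chi-square goodness-of-fit against a uniform
  null: first-decimal digits (0–9) for measured quantities, integer months
  (0–59) for age. The uniform null is this package's stated definition of
  "no preference"; it is a screening statistic, not a calibrated test of
  any specific heaping mechanism. Below ~30 values a warning is issued.
- The cross-survey statistic is the Pearson correlation between the
  heaping ratio and the HAZ weighted SD; it requires ≥ 3 surveys and raises
  an undefined-correlation error when either variable has (near-)zero
  variance (ptp < 1e-12).

## Synthetic surveys

The generator emulates the structure the assessment layer assumes, per
child: true age uniform over the 0–60-month window; recorded age snapped to
the nearest of {24, 36, 48} with probability `heaping_fraction`
(snap-to-target rather than rounding-to-year keeps the under-18-month
region clean); latent z ~ N(true_mean, true_sd²) per indicator with
additive N(0, noise_sd²) recorded error; log-normal weights with a given CV
normalised to mean 1 (weighted moments are scale-invariant, so mean 1 is
purely for inspectability); independent per-indicator missingness. Defaults
are one survey of 1,000 children with true SD 1.0 and LMIC-plausible means
(HAZ −1.5, WHZ −0.4, WAZ −1.0), weight CV 0.3, no noise, no heaping, no
missingness.

`generate_survey_collection` produces k = 21 surveys (mirroring the scale
of the case study) with heaping fractions evenly spaced over 0.05–0.50 and
HAZ noise SD = 2 × heaping fraction. That monotone link builds in a
positive heaping-vs-SD association so the correlation machinery can be
exercised end to end; it is a test construction, not a mechanistic model of
how caregiver age estimation propagates into height-for-age error. Real
data differ in ways the generator does not emulate: cluster/household
sampling structure, non-normal latent distributions, age-dependent and
correlated errors, and heaping at other salient ages. Passing recovery
tests therefore demonstrates the estimators and diagnostics are correct
under the stated model, not that real surveys satisfy the model.

## Problem sizes

The default simulation size is 500,000 observations per distribution, which
the SD-inflation and worked-example computations use directly. Property
and oracle tests run at 30,000–200,000 draws and synthetic surveys of
300–50,000 children — sizes at which binomial/moment standard errors are
small enough for 4-SE assertions to be sharp while the full suite stays
fast.

## Limitations

- Everything conditions on normality; skewed or heavy-tailed z-score
  distributions are out of scope.
- The reference-SD assumption is population-level folklore encoded as a
  parameter; communities with genuinely heterogeneous nutrition can have
  authentic SDs outside 0.8–1.2, which is exactly why the range-anchored
  interval, not the point bias, is the headline output.
- Directional error is representable (`error_mean`) but excluded from the
  bias map's interpretation.
- The 21-survey case-study comparison requires the original per-survey
  data, which must be supplied by the user under `data/s1/`; the package
  ships no copy.
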