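# Methods

## The problem

Anthropometric weight prediction replaces a weighing scale with a linear
function of body measurements that a flexible tape (and, for some equations,
calipers) can obtain, including on bedridden patients. This package
implements the standard validation workflow for such equations: predict
weight for every participant in a cohort whose true weight was measured,
then summarise agreement with within-tolerance percentages (P10/P20), mean
percentage error (MPE), and Bland–Altman limits of agreement, overall and
within sex and nutrition-status subgroups.

## Equation registry

The nine equations are stored declaratively (variable → coefficient maps
plus an intercept, per sex branch where the source published two fits), so
the transcription can be audited in one place (`registry_to_text()`).
Conventions:

- Units are fixed as published: cm for height, knee height and all
  circumferences, mm for skinfold thickness, years for age, kg out. Ingest
  rejects out-of-range values instead of converting — silent unit conversion
  is the dominant failure mode for these formulas.
- Coded sex is male = 1, female = 2 where an equation carries a sex term
  (Rabito 3). Chumlea, Crandall, Lorenz and Jung use separate published
  male/female coefficient sets.
- Predictions are returned at full floating precision; rounding (2 decimal
  places, half-up) happens only in report formatting, so downstream metrics
  never compound rounding error.
- Negative or zero predictions are mathematically possible at extreme small
  inputs. They are returned as-is and counted as `n_implausible` in reports
  rather than masked: hiding them would conceal exactly the pathology a
  validation exercise is meant to expose.
- Published R² values are carried as provenance metadata only (the Jung
  female value is implausibly low next to its male counterpart but is kept
  verbatim); no computation uses them.

A record missing any required variable makes the equation non-evaluable for
that record; such cells are flagged and excluded pairwise, never imputed.

## Accuracy statistics

The source literature frequently omits sign conventions, and published MPE
and LOA columns are not always mutually consistent; this package therefore
fixes and documents one convention, echoed into every run manifest:

- percentage error = 100·(predicted − actual)/actual, so overprediction is
  positive; MPE is its arithmetic mean.
- PX = 100 · #{|predicted − actual|/actual ≤ X/100} / n, boundary inclusive
  ("within 10%" includes exactly 10%; at 0.1 kg weight resolution the
  choice is negligible, but it must be fixed). P10 ≤ P20 by construction
  and is asserted as an invariant on every report row.
- Bland–Altman differences are predicted − actual; the plot x-axis is the
  pair mean. Bias is the mean difference, s the sample SD (n−1), limits of
  agreement bias ± 1.96·s (the conventional multiplier, not a t quantile).
  95% CIs use SE = s/√n for the bias and SE = s·√(3/n) for each limit, with
  a Student-t critical value at n−1 df — the classic large-sample recipe.
  n < 3 is rejected (the CIs need df ≥ 2); zero-variance differences
  collapse the limits onto the bias and flag the result degenerate.
- Nutrition subgroups use BMI = weight/(height/100)² of the *measured*
  weight, with WHO adult cutoffs (<18.5 / [18.5, 25) / [25, 30) / ≥30),
  lower boundaries inclusive. The cutoffs are the default for adult
  cohorts; nothing in the implementation depends on them beyond this
  mapping.
- Quantiles (medians/IQRs in descriptive tables) use linear interpolation
  between order statistics — the default in mainstream statistical
  software, declared in the manifest because IQRs at a few hundred records
  are sensitive to the definition.

## Synthetic cohorts

The generator emulates the *structure* of a quota-sampled adult validation
study, not the true multivariate anthropometry of any population. Defaults
(all config-exposed):

- 30 participants per stratum across 2 sexes × 4 nutrition categories
  (240 total), matching the typical size of such validation studies.
- Height ~ Normal, sex-specific: male 167 ± 8.5 cm, female 159 ± 6.4 cm
  (means at the target cohort medians; SDs back-computed from IQR widths,
  IQR ≈ 1.349·σ).
- BMI ~ Normal truncated to the stratum interval (underweight 17.2 ± 1.5 on
  [14, 18.5); normal 21.7 ± 2.0; overweight 27.3 ± 1.5; obese 33.5 ± 3.0 on
  [30, 45)); weight = BMI·(height/100)². Every emitted record's BMI lies in
  its stratum's interval by construction.
- Each circumference/caliper variable is a linear function of weight,
  height, BMI and sex plus Gaussian noise, truncated above a positivity
  floor. Coefficients were calibrated once so the cohort medians bracket a
  typical young-adult field cohort (weight ≈ 64.5 kg, height ≈ 162.5 cm,
  MAC ≈ 28.6 cm, AC ≈ 81.8 cm, CC ≈ 34.5 cm, HC ≈ 96.5 cm, KH ≈ 51.5 cm,
  SST ≈ 12 mm); they are package defaults, not claims about physiology.
- Age = 18 + lognormal (median 11 y above 18, σ = 0.887), capped at 90,
  giving a young-adult median near 29 with a long right tail.

Truncated normals are sampled exactly with `scipy.stats.truncnorm` under a
single seeded `numpy.random.Generator` per cohort, consumed stratum by
stratum in fixed order — cohorts are byte-identical given a seed, and
appending strata cannot perturb earlier draws. Impossible truncation bounds
(a location many SDs outside its interval, an empty interval, non-positive
scales) are rejected as configuration errors up front rather than silently
relaxed; exact truncated sampling was preferred over rejection loops because
it removes the iteration-cap failure mode entirely.

Planted-truth cohorts regenerate the same measurement fields (a separate
noise stream derived from the seed leaves them untouched), then overwrite
measured weight with the planted equation's prediction plus Normal(0, σ)
noise truncated to stay positive. On such a cohort the planted equation is
ground truth, so the pipeline must score it P10 = P20 = 100 at zero noise
and rank it top by P10 in nearly all seeds at 2 kg noise — the
ranking-recovery tests exercise the *framework*, independent of any real
data.

What passing these tests shows — and does not. The synthetic cohort has
strictly linear-Gaussian measurement relationships, no measurement error on
weight, no missingness, and no age dependence of body composition. Tests on
it validate the arithmetic and the pipeline's bookkeeping (stratification,
pairwise exclusion, determinism), not how any equation performs on real
patients; conclusions about real cohorts require ingesting real data.

## Problem sizes

The test suite and the acceptance script run the full pipeline on 240-record
cohorts (the standard size for this design), 10-seed ranking-recovery
sweeps, a 50-seed calibration check, 10⁴ randomized oracle comparisons per
equation set, and a single 10⁵-pair Monte-Carlo convergence check for the
Bland–Altman limits — sizes chosen to make the statistical assertions sharp
(3 Monte-Carlo SEs) while keeping a full run under a minute.

## Known limitations

- Reproduction of the published validation tables requires the study's
  deposited cohort file, which cannot be redistributed with the package;
  the corresponding checks fail with an explicit message until it is
  supplied at `data/study_data.xlsx`.
- The PAWPER XL-MAC method is excluded: its model is not specified in open
  literature in evaluable form.
- Equation coefficients are never re-fitted; the package validates, it does
  not calibrate.
- The ingest layer is deliberately strict (reject, log, never coerce);
  cohorts with exotic encodings need a custom `IngestSchema` rather than
  leniency flags.
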