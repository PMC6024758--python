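# Methods

## Scope and model

The package implements the spot-to-24-h extrapolation chain used in
population iodine surveillance and the statistics used to judge it
against measured 24-h collections.  Nothing is fitted: the three
creatinine prediction equations (Tanaka, Kawasaki, Mage) are fixed,
published closed forms, and the agreement statistics (Cohen's kappa,
sensitivity/specificity, log-scale Bland–Altman limits of agreement,
rank statistics) are standard estimators computed on the supplied pairs.

### Prediction equations

All three return predicted 24-h creatinine excretion (PrCr) in mg/day
from age (years), weight (kg) and height (cm); Kawasaki and Mage are
sex-specific and Mage additionally uses BMI and a black/African-ancestry
indicator `A`.  The Mage form is multiplicative in both sexes,
`k·(140 − age)·weight^1.5·height^0.5·(1 + 0.18·A·(b1 − b2·BMI))`; with
`A = 0` the bracket collapses to 1.  Conventions adopted where the
source material is loose:

- **Spot creatinine unit.** Spot urinary creatinine is accepted in
  mg/dL (the common clinical reporting unit) and converted to mg/L
  before forming the iodine-to-creatinine ratio, so the units in
  `PrUIE = (UIC µg/L ÷ UCr mg/L) × PrCr mg/day` cancel to µg/day
  auditable by eye.  A `ucr_unit` flag accepts mg/L directly; declaring
  the same concentration in either unit gives identical PrUIE (tested).
- **Non-positive predictions.** The linear equations can go negative
  for inputs far outside their calibration range.  These raise a
  flagged error (scalar API) or are set to missing with a logged count
  (vectorised pipeline) — never clamped, since a clamped value would
  bias every downstream excretion estimate.
- **Missing ancestry indicator.** The Mage prediction is returned as
  missing and the participant drops out of Mage-based analyses
  list-wise, for that equation only.  Assuming `A = 0` would silently
  shift the Mage PrCr for an identifiable subgroup.
- **BMI.** Recomputed from weight and height when absent; a supplied
  BMI is kept but must agree with the recomputed value within
  0.5 kg/m².
- **IOM intake equation.** Implemented as
  `(UIC/0.92) × (0.0009 L·h⁻¹·kg⁻¹ × 24 × weight)`, i.e. including the
  ×24 factor that turns the hourly urine-output rate into a daily
  volume; without it the bracket is not a daily volume and the result
  is off by a factor of 24.

### Classification

Estimated intake = excretion / 0.92 (bioavailability), classified
against the adult EAR of 95 µg/day with a strict `<`: exactly 95 counts
as adequate.  The boundary convention is immaterial on continuous data
but is pinned down and tested.  Population classification uses the
median spot UIC (< 100 µg/L ⇒ deficient) plus the cumulative fractions
below 100 and 50 µg/L.  The completeness screen drops 24-h collections
with volume ≤ 300 mL or daily creatinine ≤ 4 mmol (women) / ≤ 6 mmol
(men); the thresholds are inclusive exclusions and configurable.

### Agreement statistics

Kappa is computed from the 2×2 table as `(p_o − p_e)/(1 − p_e)` with the
chance term from the marginals; a single-category table makes
`p_e = 1` and raises rather than returning a conventional value.
Sensitivity is the fraction of measured-below-EAR participants also
predicted below; specificity the mirror image.

Bland–Altman agreement is computed on natural logs because excretion is
right-skewed and method error is multiplicative.  The ratio is taken in
the **prediction/measurement** direction, so a mean below 100% reads
directly as average under-prediction; a `direction` flag flips it (the
two directions are exact reciprocals, which is tested).  The sd of the
log differences uses the n−1 sample estimator; limits are
`exp(mean ± 1.96·sd) × 100`.  Pairs with non-positive values are
excluded with a warning and a count in the result (no offset shift:
log of zero is undefined and any offset would be arbitrary).  Fewer
than 3 usable pairs is an error.  Rank statistics (Spearman, two-sided
Mann–Whitney) and quartiles are delegated to scipy/numpy; they are
descriptive and carry no multiplicity correction.

## Synthetic cohort generator

The generator exists because raw paired spot/24-h survey data of this
kind is not public.  It emulates the marginal structure of a middle-aged,
majority-female adult cohort and — crucially — gives every record a
latent ground truth so that recovery can be verified, not assumed.

All positive quantities are log-normal.  Location parameters are the
emulated medians; dispersions are matched to target quartiles on the log
scale (`lognormal_sigma_from_median_iqr` solves
`median·(r − 1/r) = IQR` for `r = exp(z₇₅σ)`) or derived from a
multiplicative CV (`σ = √ln(1+CV²)`).

Defaults (frozen; chosen once as emulation targets, not estimates):

| parameter | default | meaning |
|---|---|---|
| `n` | 457 | cohort size |
| `frac_female` | 0.76 | sample composition |
| `age_median/iqr` | 52 / 24 y | clipped to 18–90 y |
| `height_median` | 158 (F) / 170 (M) cm | log-sd 0.04 |
| `bmi_median/iqr` | 30.3/9.3 (F), 25.7/7.3 (M) kg/m² | weight = BMI·h² |
| `muie_median` | 124 µg/day | latent usual excretion median |
| `muie_log_sd` | 0.45 | between-person ln-sd of usual excretion |
| `day24_cv` | 0.32 | day-to-day CV of the 24-h excretion |
| `volume_median/iqr` | 1400 / 1390 mL | 24-h urine volume |
| `spot_dilution_median` | 1.468 | morning-void vs daily-average concentration |
| `spot_dilution_log_sd` | 0.35 | spread of the shared dilution factor |
| `spot_cv` | 0.38 | intra-individual CV of spot UIC |
| `spot_cr_cv` | 0.50 | intra-individual CV of spot creatinine concentration |
| `creatinine_pop_cv` | 0.25 | person-level deviation from the Kawasaki baseline |
| `creatinine_day_cv` | 0.15 | day noise on recorded 24-h creatinine |
| `frac_black` | 0.73 | ancestry indicator probability |
| `frac_missing_ethnicity` | 26/455 | missing-completely-at-random |

Mechanism worth spelling out: the spot sample shares one latent dilution
factor between its iodine and creatinine concentrations.  The factor
cancels in the iodine-to-creatinine ratio, which is what makes the ratio
informative about the latent usual excretion at all; the *non-shared*
analyte noises (`spot_cv`, `spot_cr_cv`) are what degrade it.  The
dilution median of 1.468 makes the median spot concentration exceed the
daily-average concentration (124/1.4 ≈ 88.6 µg/L) by the amount needed
to put the median spot UIC at 130 µg/L — morning voids are more
concentrated than the daily average.  With `muie_log_sd = 0.45` and the
noise CVs above, the predicted-vs-measured Spearman ρ lands near 0.4 and
the log-scale Bland–Altman limits span roughly 20–450%, the realistic
regime for single spot samples.  True daily creatinine is the Kawasaki
anthropometric baseline times person-level noise, so creatinine-equation
error enters the pipeline the way it would in the field.

**What the generator does not emulate.** Survey design (clustering,
weights), covariate structure beyond sex/age/anthropometry, seasonal or
weekday intake patterns, assay error, and any dependence of iodine
excretion on anthropometry (latent excretion is drawn independently of
body size).  The marginal IQRs of spot UIC and mUIE come out somewhat
different from the emulated cohort's because the between-person spread
was set to make the *joint* behaviour (rank correlation, LOA width)
realistic rather than to match every marginal quartile; medians are
matched.  Passing recovery tests therefore demonstrates the pipeline's
internal correctness and its behaviour under realistic noise, not that
any real population has these parameters.

With all noise parameters at zero and the dilution factor pinned at 1,
the spot ratio times the true creatinine reproduces the measured
excretion exactly and the below-EAR prevalence is recovered without
error — the pipeline's identity check.

## Numerical and interface choices

- The seed fully determines a cohort; CSV serialisation uses full float
  repr, so equal seeds give byte-identical files.
- The pipeline is deterministic given input and config (tested by
  byte-comparing two runs); randomness exists only in `generate`.
- Exclusion and missing-data counts are logged and reported per
  analysis, since n legitimately differs between equation tables.
- Report sample sizes used in tests: cohorts of 457 (the emulated study
  size) for recovery checks, 10⁴ for Monte-Carlo limits-of-agreement
  coverage, 10⁵ for marginal-convergence checks.
- The command-line layer (`generate`, `run`, `report`) is a thin wrapper
  over `cohort.generate_cohort` and `pipeline.run_pipeline`; a YAML file
  can override any config default, with flags taking precedence.

## Known limitations

- No adjustment of the UIC distribution for intra-individual variance
  (NCI-style usual-intake methods); prevalence estimates from single
  spot samples inherit the full within-person spread.
- No proportional-bias (regression-based) Bland–Altman extension and no
  confidence intervals around the limits of agreement.
- No pregnancy/lactation cut-offs; adult EAR and MUIC thresholds only.
- The contingency-table statistics treat the 2×2 counts as fixed;
  no survey weights.
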