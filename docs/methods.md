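# Methods

## The estimation problem

An encounter-intercept sample from general practice observes person *i*
with probability proportional to their annual GP visit count *Aᵢ*
(length-biased sampling), and never observes people who did not attend that
year. The estimand is the prevalence of diagnosed chronic conditions in the
whole population. The pipeline makes three corrections, in order:

1. **Within-stratum attendance correction.** Each patient is weighted by
   `C = B/A`. Weighting by `1/A` undoes selection proportional to `A`; the
   constant `B` (see below) only sets the scale of the weights and cancels
   from every prevalence ratio. The comparison "old method" sets `C = 1`,
   i.e. it corrects only between strata, not within.
2. **Post-stratification.** With `E_s` the C-weighted sample share and
   `D_s` the population share of age-sex stratum *s*, each patient gets
   `F = D_s/E_s`, so the weighted sample reproduces the population age-sex
   distribution exactly (this is an algebraic identity, asserted as a
   test).
3. **Non-attender adjustment.** `G_s`, the proportion of stratum *s* that
   saw a GP at least once in the year, multiplies the *numerator* only:
   non-attenders are assumed to carry no diagnosed chronic conditions (a
   diagnosis requires a clinical contact) but they belong to the population
   denominator. The estimator is `Σ C·F·G·I / Σ C·F`, and every patient's
   numerator/denominator ratio equals the `G` of their stratum.

`B` is computed as the harmonic mean of the reported visit counts,
`n / Σ(1/Aᵢ)`. Under sampling proportional to visits, the sample mean of
`1/A` estimates `1/E[A]` among attenders, so `B` estimates the average
annual attendance of people who attended at least once — the natural
"adjusted mean" to report next to the (length-biased) raw sample mean.
Because prevalence ratios are invariant to the scale of `B` (asserted
numerically to 1e-10), any positive constant would give identical
estimates; the harmonic mean is fixed for reproducibility of the reported
`B` itself.

### Display convention for the worked example

Internally all arithmetic is at full precision. The worked-example helper
(`table1_worked_example`) rounds `C` and `F` to 2 decimals and composes the
final numerator `C·F·G` and denominator `C·F` from those *rounded*
intermediates — the convention under which a printed example table is
internally consistent (e.g. `F = 0.35` with `G = 0.9653` prints a
numerator of 0.34, whereas full precision would print 0.33).

## Missing data

Two rules, applied strictly in this order because visit-imputation cells
depend on condition counts:

* **Condition response.** A blank response is treated as "no chronic
  conditions" — deliberately biasing against overestimation — unless
  chronic conditions were managed at the sampled encounter, in which case
  those chronic conditions are assigned to the patient. Both passes are
  idempotent.
* **Visit count.** Missing `A` gets the arithmetic mean of observed `A` in
  the patient's (10-year age band anchored at 0 × sex × condition-count
  band {0,1,2,3+}) cell. Empty cells collapse the count band first, then
  sex, then fall back to the global mean — age, the strongest predictor of
  attendance, is preserved longest. Imputed values stay fractional: `C =
  B/A` is a ratio and needs no integer `A`. Patients with missing age or
  sex fall straight to the global mean and are excluded from population
  weighting (no stratum is assignable), while remaining in encounter-level
  estimates.

## Multimorbidity

Counts are of distinct *diagnosed chronic* conditions (catalog-flagged;
acute codes never count). Body systems are the 17 ICPC-2 chapters, counted
once per patient. Multimorbidity is ≥2 chronic conditions; complex
multimorbidity is ≥3 chronic conditions spanning ≥3 chapters. The packaged
condition→chapter catalog covers the common chronic conditions of
Australian general-practice prevalence studies and is an approximation —
users can supply their own via CSV/YAML, and unknown codes are a hard
error, never a silent default.

## Variance

Estimates are ratios of weighted totals under a single-stage cluster
design (≈30 consecutive patients per GP). The primary method is the
Taylor-linearised ratio estimator over cluster totals: with cluster totals
`y_g`, `x_g`, total `X` and `R = Y/X`, residuals `e_g = (y_g − R·x_g)/X`
give `var(R) = G/(G−1)·Σe_g²` (with-replacement first-stage
approximation), and the CI uses t on `G − 1` degrees of freedom, truncated
to [0,1]. `D` and `G` come from administrative sources and are treated as
known constants. A GP-resampling percentile bootstrap is provided as a
cross-check; on simulated data its width agrees with the linearised width
within a few percent, and the linearised CI's empirical coverage over 500
replicate samples is ~94–96%. Treating the post-stratified weights as
fixed makes the linearised CI mildly conservative; the deliberate
"blank response → no conditions" rule introduces a small downward bias
(~0.2–0.4 percentage points on a 15% condition at the default missingness
rates), which works in the opposite direction. Significance between two
estimates is declared only when their 95% CIs are disjoint — more
conservative than p < 0.05.

## The synthetic generator

`SimulationConfig` defaults define the study conditions used throughout the
tests and drivers:

* **Strata:** 5-year age bands × sex up to 85+, with a smooth national-style
  age pyramid and a slight female excess at older ages.
* **Conditions:** eight common chronic conditions drawn independently per
  person at stratum-specific prevalences rising with age (an optional
  log-normal shared frailty induces comorbidity correlation; default off,
  as no correlation structure is assumed by the estimator).
* **Visits:** attenders draw zero-truncated negative binomial counts with
  mean `visit_base(stratum) × visit_effect^(condition count)`;
  `visit_effect = 1.5` encodes "people with more chronic conditions attend
  more often", and dispersion 1.1 gives the heavy right tail of attendance
  data. The base rates were set so the attender mean is ≈4.5 visits/year
  with a length-biased sample mean of ≈10–12. Non-attendance is a
  per-stratum probability (`zero_inflation`), highest for young men and
  near zero for the very old, giving `G` from ≈0.75 to ≈0.97.
* **Diagnosis requires attendance:** a non-attender's latent conditions are
  never diagnosed, so the generated ground truth (prevalence of *diagnosed*
  conditions) coincides with the estimand of the weighting pipeline. This
  encodes the same assumption the `G` adjustment makes, and it is what
  makes "the new method recovers the truth" a well-posed, testable claim.
* **Sampling:** 1,000 GPs × 30 patients by default, drawn from a
  2,000,000-person population so the sample is ≈2% of attenders. The
  sampling fraction matters: PPS-without-replacement saturates inclusion
  probabilities for very frequent attenders when the fraction is large,
  which breaks proportionality and biases the corrected estimator; the
  default population size keeps the design in the regime the estimator
  assumes (and that clinic-intercept studies operate in). Sampled patients
  are randomly permuted into GP clusters; within-GP correlation beyond the
  design clustering is out of scope.
* **Observation layer:** reported visits equal true visits (an optional
  under-report factor exists, default off); condition responses go missing
  at 3.0% and visit counts at 4.1% — the rates observed in practice for
  this instrument; encounter-managed problems are a random subset of the
  patient's conditions plus occasional acute codes.

What passing tests show — and don't. The generator draws conditions
independently given stratum, uses a single national `G` source with no
error, and has no under-reporting of visits by default; real encounter
data violate all three to unknown degrees. Recovery of truth here
validates the algebra and its implementation, not the substantive accuracy
of any real-world estimate.

## Problem sizes and numerical choices

The heavy checks run at deliberately chosen scales: end-to-end bias over
20 seeds of 1,000 GPs × 30 patients (new-method |bias| < 1 percentage
point; old-method CI disjoint from truth); CI coverage over 600 replicate
samples of 100 GPs from two independent populations (100 GPs makes the
check sharp — at much larger cluster counts the CI narrows to where the
missingness-rule bias dominates coverage). Ties and degenerate inputs:
half-open age intervals `[low, high)`; strata with population share but no
sampled patients are dropped with their share renormalised over covered
strata and reported as uncovered mass; zero or missing visit counts,
unknown condition codes, non-partitioning age bands, fewer than two
clusters, and zero denominators are all hard errors. Extreme
self-reported visit counts are not capped (weights above the 99th
percentile are a matter for the audit table, not silent trimming).
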