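# Methods

This note documents the statistical model, the synthetic-registry
generator, the numerical choices, and the known limits of what the
package's tests demonstrate.

## Estimand and model

The target is the per-patient *predicted benefit* of direct transport
to a Level-1 trauma center,

    benefit_i = P(death | x_i, T=0) − P(death | x_i, T=1),

the difference between the counterfactual in-hospital mortality
probabilities under the comparator destination (T=0) and the
higher-level destination (T=1).  Both probabilities come from one
logistic model; counterfactuals are produced by rebuilding the design
row with the treatment indicator (and every treatment-interaction
column) forced to 0 or 1 while all other covariates keep their observed
values.  A positive benefit means Level-1 care is predicted to lower
that patient's death risk.

Model terms:

| Term | Form | Rationale |
|---|---|---|
| age, saturation, pulse, SBP, RR | restricted cubic spline, 4 knots | continuous vitals with plausibly nonlinear risk |
| GCS, AIS head/neck, thorax, abdomen, extremity, spine | quadratic `x + x²` | short ordinal scales; quadratic captures curvature without spline overhead |
| sex, Charlson comorbidity index (CCI) | linear | |
| treatment | indicator | Level-1 vs Level-2/3 (or Level-1/2 vs Level-3) |
| treatment × {AIS head/neck, AIS thorax, AIS abdomen, SBP, CCI} | products; SBP and CCI centered at the training mean | candidate effect modifiers; centering keeps the treatment main effect interpretable as the effect at average SBP/CCI and zero AIS |

Splines use the Harrell restricted-cubic construction with knots at the
{5, 35, 65, 95}% quantiles of the training data (a standard default;
configurable).  The basis is normalized by the squared boundary-knot
span, is linear beyond the boundary knots, and stores the training data
range so out-of-range prediction is detected and logged (predictions
proceed along the linear tails).

### Fitting

All models are fitted by Newton/IRLS with step-halving (the penalized
log-likelihood is non-decreasing across iterations), convergence at
relative log-likelihood change < 1e-10 or gradient max-norm < 1e-8, and
a separation guard (|β| > 30 in an unpenalized fit raises an error that
advises a ridge refit).  The interaction model maximizes

    ℓ(β) − (λ/2) Σ_{j ∈ interactions} β_j²,

i.e. the ridge penalty applies **only to the five interaction
coefficients** — penalization exists to keep the subtle effect
modification from overfitting, not to shrink the well-identified main
effects.  A switch to penalize all non-intercept terms exists.  At λ=0
the penalized path reproduces the ML fit exactly (tested to 1e-6
relative; the ML path itself is tested against statsmodels).  The
default weight is λ=4; `lam="auto"` selects λ from
{0,1,2,4,…,256} by 10-fold outcome-stratified cross-validated
log-likelihood (seeded; ties to the smaller λ).  The reported
covariance is the inverse (penalized) observed information; for
penalized fits this is an approximation, which the bootstrap inherits.

With m>1 imputations, coefficients and covariances are pooled by
Rubin's rules (within + (1+1/m)·between), and per-patient benefit is
averaged across imputations before classification and binning.

### Benefit classification, calibration, cross-table

Benefit/harm classes use strict thresholds: benefit > 0.01 →
"benefit", benefit < −0.01 → "harm", otherwise "neither" (±0.01
exactly is "neither").  The 1% cut-off is a clinical convention, not a
statistical optimum.

Calibration-for-benefit ranks patients by predicted benefit (stable
order for ties) into 20 equal-count bins (sizes differ by ≤1) and
compares the mean predicted benefit per bin with the *observed* benefit
— the raw comparator-arm minus treated-arm mortality difference in the
bin.  Bins with an empty arm carry an explicit NaN, never a silent
zero.  A weighted least-squares line (weights = bin size) summarizes
the curve.

**Attenuation under confounding.** Raw within-bin arm differences are
unbiased for the bin's benefit only when treatment is exchangeable
within the bin.  Under severity-confounded assignment (sicker patients
go to Level-1) the treated arm of every bin is sicker, the within-bin
difference understates benefit, and the slope attenuates — with this
package's generator to about 0.6 *even when the fitted model is exactly
the generating model*.  The self-consistency check
(`self_consistency_calibration`) therefore re-randomizes assignment
(Bernoulli at the cohort's treated fraction) before re-simulating
outcomes from the fitted model; under randomization the slope is ~1 up
to binomial noise, which is what the acceptance test asserts (slope in
[0.85, 1.15] at n≈280k analyzed patients from a 400k cohort, one seed).
Observational calibration slopes reported by the pipeline should be
read with this attenuation floor in mind.

The ISS cross-table tabulates {ISS>15, ISS≤15} × {benefit>1%, ≤1%} with
per-cell arm counts, arm mortality and observed benefit, quantifying
how far the conventional ISS>15 triage rule diverges from model-based
benefit.

### Substantial benefit (parametric bootstrap)

1000 coefficient vectors are drawn from MVN(β̂, Σ̂) via Cholesky
(diagonal jitter 1e-10 for near-singular Σ̂); each draw yields a benefit
per patient; a patient is flagged *substantial* when the benefit is
positive in ≥950/1000 draws (≥0.95 at other replicate counts).  Counts
are stored so other thresholds can be re-evaluated without redrawing.
Uncertainty comes from coefficient sampling only — cases are not
resampled, and the completed (imputed) dataset is held fixed.  Because
every patient's flag is computed from the *same* draws, flags are
strongly correlated within a cohort: under a null generator the flagged
fraction of a single cohort is heavy-tailed (usually ~0, occasionally
>10%).  The false-flag *rate* is therefore measured as the average over
replicate null cohorts in the acceptance suite.

## Cohort preparation

- AIS regions are merged by maximum: head/neck, upper/lower extremity,
  skin/unspecified → other.  A region's severity is its worst injury.
- ISS is the Baker score: sum of squares of the three highest AIS
  values over the six conventional regions (head/neck, face, thorax,
  abdomen, extremity, external/other); any AIS 6 sets ISS = 75.  AIS
  spine is carried as a model covariate but is not an ISS region in
  this schema.
- Exclusion cascade, applied sequentially with per-rule counts:
  non-ambulance/helicopter transport; age < 18; isolated limb injury
  (extremity AIS 1–5, all other merged AIS 0); ISS < 4; no vital signs
  at arrival (a schema flag); center level 4/undesignated; missing
  mortality.  The cascade is idempotent.
- Treatment is defined by the first transport destination.  The schema
  records the final center plus a transferred-in flag, so transferred
  patients are classified as comparator under both contrasts (their
  first facility's level is unrecorded).
- Imputation: predictive mean matching.  Each vital with missing
  entries gets a linear model on the always-observed covariates plus
  treatment and outcome; missing entries take the observed value of one
  of the 5 nearest donors by predicted mean.  Observed cells, treatment
  and outcome are never altered; PMM only ever imputes observed values,
  so ranges are automatically respected.  m is configurable (default 1,
  matching common registry practice); a complete-case mode exists.
  A variable over 90% missing aborts with a diagnostic.

## The synthetic registry generator

The generator emulates the structure of a national trauma-registry
extract; defaults were chosen once to reproduce registry-typical
marginals qualitatively (median age ~51 with IQR ≈ [32, 68], GCS mass
at 15 with ~7–9% comatose, per-region AIS>2 shares of roughly 27/23/7/
7/11/1% for head-neck/thorax/abdomen/spine/extremity/face, SBP ≈
N(139, 25), ~65% male, overall mortality in the 2–10% band) and the
qualitative confounding reversal (unadjusted treatment OR > 1, adjusted
< 1):

- **Assignment**: Bernoulli Level-1 with log-odds increasing in AIS
  head/neck, GCS deficit and hypotension; non-Level-1 patients split
  Level-2/Level-3 (15.3% Level-3); 10% of comparator patients are
  relabelled transferred-in with final center Level-1, so the derived
  treatment equals the generating one exactly.
- **Outcome**: logistic, with linear effects for the centered
  continuous vitals and quadratic effects for GCS deficit and the
  merged AIS scores — all inside the span of the analysis bases, so
  recovery and calibration tests have an exact truth.  The treatment
  log-odds shift is −0.06 at baseline plus interactions
  (−0.040·AIS head/neck, −0.030·AIS thorax, −0.025·AIS abdomen,
  +0.0025·(SBP−137), +0.050·CCI), concentrating benefit in
  severe head/torso injury and shock and pushing toward harm at high
  comorbidity.  Probabilities are clipped to [1e-6, 1−1e-6].
  A config switch adds a mild unmodeled AIS×GCS synergy for
  robustness experiments.
- **Missingness**: MAR; the per-patient masking probability depends
  only on age, AIS head/neck and center level, normalized so the
  expected marginal rate equals the configured rate (defaults: the
  registry-typical 45.4% saturation, 35.3% RR, 34.2% SBP, 33.6% pulse,
  1.5% GCS, 8.1% mortality).  The mechanism never reads the value it
  masks (tested by construction).
- Every cohort carries `true_p0`, `true_p1` and
  `true_benefit = true_p0 − true_p1` per patient.

What the generator does **not** emulate — hence what passing tests do
not show about real data: hospital-level clustering and volume effects,
informative (MNAR) missingness, measurement error in prehospital
vitals, transfer dynamics beyond a passive flag, correlated
multi-region injury patterns beyond the few built-in couplings
(GCS↓ with head injury, SBP↓ with torso injury), and coding artifacts
(duplicates, ICD mapping).  Recovery results are therefore evidence
that the *pipeline* is correct, not that the model is unbiased on any
particular registry.

## Problem sizes and seeds

Statistical tests run at the sizes their noise budgets require:
parameter recovery uses 20 cohorts of 50,000; the confounding reversal
and benefit recovery use 200,000; calibration self-consistency uses
400,000; the null false-flag rate averages 6 cohorts of 40,000.  All
stochastic stages are seeded and deterministic given the seed; the
acceptance script derives every stage seed from its single `--seed`
argument.

## Known limitations

- The penalized-fit covariance (inverse penalized information) ignores
  penalty-induced bias; substantial-benefit flags near the 0.95
  boundary inherit that approximation.
- The 1% threshold and the 950/1000 rule are conventions; neither
  distinguishes negligible from impactful benefit among flagged
  patients.
- Observed benefit (bins and cross-table cells) is a raw arm
  difference, deliberately unadjusted; under confounded assignment it
  is attenuated (see above).
- The imputation model is linear-additive PMM; strongly nonlinear
  missingness structure would call for richer imputation models.
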