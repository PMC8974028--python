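# Methods

## The dysregulation score

A subject's dysregulation score is the Mahalanobis distance of their
biomarker vector from the centroid of a reference population (RP):
D_M(x) = √((x − μ)ᵀ Σ⁻¹ (x − μ)), with μ and Σ the RP's mean vector and
covariance matrix on the analysis scale.  The model's assumptions are
those of the distance itself: after marginal transforms the joint
biomarker distribution is roughly elliptical, so that the covariance
captures the geometry of "normal" physiological variation and distance in
its metric is comparable across directions.  No biomarker receives weight
beyond what the covariance implies.  Because observed D_M is approximately
log-normal, downstream analyses use log D_M (natural log; rows with
D_M = 0 have log-DM set missing and flagged rather than −∞).

### Calibration pipeline

Fitting an RP on a cohort's complete cases proceeds:

1. **Transforms.** Per biomarker, the label in {identity, log, sqrt} that
   minimizes |bias-corrected sample skewness| of the transformed training
   values.  Skewness is the simplest deterministic proxy for "approach
   normality"; a formal normality test statistic would add noise without
   changing the ordering in practice.  log/sqrt candidates are shifted by
   offset = max(0, 1e−6 − min) so they are defined on all training values.
   Ties within 1e−9 resolve to the least aggressive transform
   (identity > sqrt > log) for stability of the standard.  Transforms are
   selected once — on pooled training data when several cohorts are
   involved — frozen into the RP, and never re-selected at scoring time.
   A constant training column falls back to identity with a warning flag.
2. **Standardization.** Each transformed biomarker is centered and scaled
   by the RP's mean and SD (n−1 denominator).  Scored cohorts are always
   standardized by the *RP's* statistics, never their own; using the
   scored cohort's statistics would silently recalibrate the metric.
3. **Centroid and covariance.** μ = column means of the standardized RP
   sample (≈ 0 by construction when the RP standardizes itself — asserted
   at fit time) and Σ = sample covariance (n−1).  Σ must pass a Cholesky
   positive-definiteness check; failure points at collinear markers.  μ is
   stored even though ≈ 0 because composite workflows may standardize with
   one sample and take moments from another; the general form of the
   distance is always evaluated.

The quadratic form is computed through a Cholesky solve of Σ, not an
explicit inverse; tests pin it to the explicit-inverse formula within
1e−10.  Standardization makes Σ the RP's correlation matrix, and the
distance is invariant to per-marker affine rescaling applied consistently
to fit and score data (tested to 1e−8), so the choice of raw units is
immaterial.

An optional covariance shrinkage flag ((1−w)·Σ + w·I) exists for users
fitting on small reference samples; it is off by default and marked
non-standard, since a shrunken metric is no longer the plain sample
calibration.

**Missing data** are never imputed: RP fitting and scoring are
complete-case per marker set, with excluded row counts reported.  Rows
whose value falls outside a log/sqrt domain after the offset become
missing and are counted in the transform report.

### Composite reference populations

A composite RP samples an equal number of complete cases from each source
cohort — uniformly, without replacement, from a single integer seed,
visiting sources in the order given — concatenates them, and fits as
above (transforms selected on the pooled sample).  Equal allocation keeps
any one study from dominating the calibration.  The sampled subject ids
are recorded in the RP provenance, so a composite calibration is exactly
reproducible.

## Suite selection

The selection procedure asks which small marker sets give a score that is
(a) insensitive to the choice of calibrating population and (b) still
close to the full-panel score.

**Pre-selection.** For every biomarker and demographic subset (defaults:
everyone, sex groups, pooled age tertiles; callers can add splits), the
subset mean is computed per cohort on the transformed scale.  A marker is
excluded when the largest pairwise standardized mean difference
|m_i − m_j| / s_pooled across cohorts exceeds a threshold for any subset
(default 0.5 SD; the underlying criterion in the literature is
qualitative, so the threshold is an explicit, configurable default and
every exclusion is reported with the triggering subset and statistic), or
optionally when a cohort's overall raw-scale mean lies outside the
marker's clinical bounds.

**Subset enumeration.** Every k-subset of the retained candidates (or a
seeded uniform sample drawn by lexicographic unranking when C(n, k)
exceeds the 10⁶ budget; C(22,10) = 646,646 fits) is scored per cohort on
two Pearson correlations of log-DM: own-RP vs composite-RP (RP
stability) and subset vs full-set, both own-RP (signal).  Evaluations are
returned in a deterministic total order — mean RP stability descending,
mean signal descending, then marker names — and per-subset fit failures
are flagged, not dropped.  The final promotion of a subset to a
"standard" is deliberately manual: availability and physiological breadth
are judgment calls, so the module ranks and reports but never picks, and
DM9/DM17 ship as fixed constants.

**Stability matrices.** Entry (i, j) correlates, over the subjects of
study population j, log-DM calibrated on j itself with log-DM calibrated
on reference i; within-population stability treats demographic subsets as
alternative RPs.  The summary `mean_r` is the arithmetic mean over all
cells whose row and column labels differ; an optional pooled-RP row can be
included or excluded from that mean, since averaging conventions differ
between users.  Correlations use complete cases, no winsorization.

**Redundancy.** Pairwise transformed-scale correlations among set members
are reported with |r| > 0.8 flagged — purely informational.  The distance
itself discounts redundancy through Σ⁻¹, but suites built entirely from
redundant markers carry less breadth of signal, so the table is worth
reading before settling on a suite.

## Allostatic load

The comparator metric counts components in their risk-direction quartile
of a fitting population: strictly above the 75th percentile for most,
strictly below the 25th for HDL, IGF-1 and DHEAS.  Percentiles use linear
interpolation between order statistics (the convention is recorded in the
fitted specification).  Ties at the cutoff score zero under the default
strict boundary; an inclusive flag flips the convention.  Quartiles are
pooled across subjects by default (a group-by fit is available by passing
a subset cohort), and rows missing components are scored on what is
present with the missing count reported — the classical descriptions do
not state a missing rule, so the permissive one is used and surfaced.
With continuous components each contributes with probability ¼ on the
fitting cohort, so mean AL ≈ K/4; AL is invariant to monotone transforms
of a component applied consistently to fit and scoring data.

## Outcome associations

Metrics are divided by their sample SD (n−1, finite values) before
modelling, so all effects are hazard/rate/odds ratios per SD and
comparable across metrics (self-assessed health enters as a numeric 1–5
score on the "higher = worse" orientation, inverted upstream where a
survey codes it the other way).  Families:

- **Mortality:** Cox proportional hazards with *age as the timescale* —
  left truncation at entry age, event/censoring at exit age — so age is
  adjusted nonparametrically by the baseline hazard.  Efron tie handling
  (lifelines' default) is the declared convention.
- **Frailty criteria count, comorbidity count:** Poisson regression.
  Frailty is bounded at 5 while Poisson is unbounded; the model is used
  as stated and the bound noted as a caveat (at realistic rates the mass
  above 5 is negligible).
- **CVD, diabetes:** logistic regression, with suspected separation
  flagged when the metric's Wald SE explodes.

Non-Cox models adjust for age through a cubic B-spline basis (configurable
df, default 5, interior knots at age quantiles).  Three covariate sets:
(1) age + sex; (2) + physical/cognitive function (walk time, MMSE);
(3) + socio-economic status (education, race when present).  Declared
covariates absent from a cohort are skipped rather than fatal, since
outcome availability differs across real cohorts.  Wald 95% intervals and
p-values are reported without multiplicity correction; `compare_metrics`
fits the full metric × outcome × covariate-set cross-product, records
per-cell failures in-table, and is deterministic for fixed input.  Only
single-timepoint analyses are implemented (first visit cross-sectionally,
first event for survival); repeated-visit random-intercept models are out
of scope.

## Synthetic cohorts

The generator reproduces the structure the metric and the selection
procedure lean on: positive, roughly log-normal biomarkers (latent
multivariate normal with a shared correlation matrix — exchangeable
ρ = 0.3 by default — mapped through identity or exp per marker, with
plausible adult reference magnitudes as defaults), dataset-specific mean
shifts expressed in latent-SD units (so pre-selection thresholds read
directly), optional variance multipliers, demographics (sex ~
Bernoulli(0.5), age ~ Uniform(20, 90), education/race/marital strings),
per-marker Bernoulli missingness, and outcomes driven by a unit-variance
risk score.

The risk score defaults to an equal-weight signed combination of the
standardized latent markers.  Because a distance metric is blind to the
*sign* of a coherent shift, an optional `deviation_weight` mixes in the
standardized Mahalanobis deviation magnitude of the latent vector
(renormalized so the risk keeps unit variance); with it the simulated
world's risk is dysregulation-like and log-DM carries the hazard signal,
which is how the worked example produces per-SD hazard ratios near 1.3.
Survival times are exponential given the hazard 0.04·exp(0.3·risk) per
year with 10 years of follow-up (≈ 30–40% events); frailty is Poisson
(mean 1.2, log-rate slope 0.2) clipped to 0–5; comorbidity count is
unclipped Poisson (mean 2.0); diseases are Bernoulli with 20% baseline
prevalence and log-OR 0.4; self-assessed health is a rounded noisy
readout of the risk clipped to 1–5.  One global seed spawns per-dataset
streams deterministically; identical configurations reproduce
byte-identical cohorts.

What the generator does **not** emulate: real survey marginals or units
beyond order-of-magnitude plausibility, age trends in biomarkers (slopes
default to zero), informative missingness, repeated visits, or
non-exponential hazard shapes.  Passing tests therefore demonstrate that
the *procedures* behave as designed under the assumed structure — not
that any particular real cohort satisfies that structure.

## Problem sizes and numerical conventions

The test suite and acceptance script run at the sizes the analyses are
specified for: stability pairs at n = 2000, p = 9; the χ² law with an RP
of n = 5000 and scored draws of 2000 over 40 replicates (the scored draw
is kept smaller than the RP so that the estimation error shared by all
scored subjects stays below the Kolmogorov–Smirnov noise floor);
pre-selection detection over 100 replicates of three 1000-subject
cohorts; allostatic calibration at n = 4000; association recovery at
n = 3000 with 200-replicate coverage and 500-replicate type-I error
checks.  Throughout: SDs and covariances use the n−1 denominator,
skewness is the bias-corrected moment estimator, percentiles interpolate
linearly, Pearson correlations are complete-case, and every stochastic
step flows from a single integer seed.

## Known limitations

- The built-in `pre22` candidate pool is provisional; the defensible path
  to a pre-selected list is running `pre_select` on one's own cohorts.
- Complete-case scoring can bias samples where missingness correlates
  with health; the per-row exclusion counts make the loss visible but do
  not correct it.
- The covariance is a plain sample estimate; with p approaching n the
  metric degrades (the shrinkage flag is a stopgap, not a recommendation).
- Cox models assume non-informative censoring and proportional hazards on
  the age scale; no diagnostics are built in.
- The Poisson family ignores the frailty count's upper bound of 5.
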