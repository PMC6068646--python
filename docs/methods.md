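# Methods

## Spatial model

Log10 total soil mercury at location *s* (planar meters) is modelled as

    Y(s) = x(s)ᵀβ + B(s) + ε,

with signal Z(s) = x(s)ᵀβ + B(s). The drift regressors x(s) are functions of
d(s) = log10(max(distance to canal, 1 m)); the 1 m floor keeps the logarithm
finite for locations on the canal and is negligible at the kilometer scale
of a study region. Four drift families are supported — linear (1, d),
quadratic (1, d, d²), broken-stick (1, d, max(0, d − bp)) with a continuous
hinge at bp = 2 on the log10 scale, and inverse (1, d, (1 + d)⁻¹) — compared
by AIC/BIC on Gaussian OLS fits. The parameter count k in AIC = 2k − 2 logL
includes the error variance, and logL is evaluated at the MLE variance
RSS/n. The quadratic drift is the downstream default regardless of a
per-run selection (it increases again at large distances, which is
implausible but harmless inside the sampled domain); callers may override.

B is a stationary isotropic Gaussian field with stable exponential
covariance C(r) = σ² exp(−(r/α)^γ). The shape exponent is fixed at γ = 0.5,
giving a continuous but non-differentiable field, appropriate for
contamination deposited in a pointwise manner; γ = 1 recovers the
exponential model. The covariance is parameterized with an explicit range α
(m) so that sill, nugget and range are separately reported. ε is iid with
nugget variance τ².

### REML estimation

(σ², τ², α) maximize the restricted likelihood; β is the GLS estimate at the
optimum. Implementation notes:

- With all three parameters free, the overall scale is profiled out:
  Σ = σ²(C_α + θI), θ = τ²/σ², leaving a 2-D Nelder–Mead search over
  (log θ, log α) with σ̂² in closed form. Fixed-parameter variants (e.g.
  τ² = 0, or σ² = 0 which reduces exactly to OLS) use reduced or direct
  objectives.
- Multi-start initialization (default 3 starts) from OLS residual variance
  and pairwise-distance quantiles; stopping at xatol 10⁻³ on log
  parameters.
- The range search is capped at 3× the maximum pairwise distance: as
  α → ∞ the correlation matrix approaches the degenerate all-ones limit
  while the restricted likelihood can stay flat, so estimates beyond the
  domain scale carry no information and are excluded.
- Duplicated sample locations are jittered by 10⁻³ m with a warning so Σ
  stays non-singular.
- Identifiability: with γ = 0.5 the likelihood surface has a σ²–α ridge
  (approximately the microergodic combination σ²/√α is well identified,
  the two factors separately much less so). Reliable separate recovery of
  α requires a sampling geometry whose extent and near-canal band are
  large multiples of α; shrinking the domain while keeping α fixed
  destroys the separation. The package's validation studies therefore
  keep the full study geometry (2400 × 800 m box, 200 m near-canal band)
  when assessing parameter recovery and reduce only the sample count.

Plain Gaussian REML is the estimator; no robustified estimating equations
are provided (a robust variant would need tuning constants that are
deliberately out of scope here).

### Kriging prediction

The universal-kriging BLUP of the signal at s₀ is

    p(s₀) = x₀ᵀβ̂ + c₀ᵀΣ⁻¹(y − Xβ̂),
    var(s₀) = σ² − c₀ᵀΣ⁻¹c₀ + dᵀ(XᵀΣ⁻¹X)⁻¹d,  d = x₀ − XᵀΣ⁻¹c₀,

so the reported standard error refers to the signal Z(s₀) — it excludes the
nugget (ε is measurement noise, not part of the exposure surface); a flag
adds τ² for response prediction. With τ² = 0 the predictor interpolates the
data exactly; with σ² = 0 it reduces to the drift regression and its mean
standard error. Grid prediction evaluates cell centers row-major, with a
configurable cell-count cap. Model checking uses Cholesky-whitened
residuals against standard-normal quantiles (QQ), and the Matheron
method-of-moments semivariogram (default 15 equal-width lag bins up to half
the maximum pairwise distance) against the fitted curve.

### Cross-validation

k-fold (default 6) with uniformly random folds of near-equal size; spatial
blocking is deliberately not used. Each fold refits everything — variogram
parameters by REML and β by GLS — on the training portion, the strictest
reading of out-of-sample validation; hyperparameters (drift kind, γ) stay
fixed. Reported: Pearson correlation of measured vs predicted log10 values
and the least-squares line of predicted on measured. Smoothing implies a
calibration slope below 1 (high values underestimated, low overestimated).

## HBM preprocessing

- Topsoil filter: only the 0–20 cm layer enters the analysis.
- Limit of determination 0.1 mg/kg; values below are replaced by half the
  limit and flagged (idempotent).
- Urinary mercury is creatinine-adjusted (µg/g); samples with creatinine
  outside the closed WHO range [0.3, 3.0] g/L are excluded, with the rule
  name logged.
- Covariates: square-root transformed amalgam-filling and sea-fish-portion
  counts, 0/1 indicators (recent sea fish, smoking, birth country near the
  sea, garden vegetables, hair dyeing), age in years. The urine covariate
  set includes the last-3-days sea-fish indicator; the hair set swaps it
  for hair dyeing (a 30-day fish recall cannot plausibly affect the
  long-term hair measure). The below-detection-limit indicator accompanies
  measured exposure only; an age × mother interaction is included in
  measured-exposure models by default and omitted from predicted-exposure
  models, both overridable.
- Exposure linkage: measured = nearest prepared sample on the participant's
  parcel (falling back to the parcel of the overall-nearest sample when no
  parcel is recorded; participants on unsampled parcels get a missing
  measured exposure and are excluded from measured-exposure models with a
  logged reason); predicted = kriging at the residence coordinates, with
  its standard error.

## Mixed models

log10 outcomes are regressed on exposure and covariates with an independent
Gaussian family random intercept (mothers and children in one model), by
REML via statsmodels MixedLM. Fixed-effect inference is Wald with a
Gaussian reference: CI = estimate ± 1.96·SE, two-sided p from the normal
tail. This convention is documented rather than derived; with ~64 families
it is mildly liberal for family-level covariates (empirical type-I error
for a null cluster-level coefficient runs around 6–12% at nominal 5–10%
levels), which is accepted and stated here. Variance components get Wald
intervals on the log scale from a numerical Hessian of an in-package REML
profile likelihood; a family variance estimated at the zero boundary is
reported with a degenerate [0, 0] interval. p-values are mapped to evidence
categories for lay communication: very strong (< 0.001), strong (< 0.01),
evidence [0.01, 0.05), weak [0.05, 0.1), little or none (≥ 0.1); exact 0.05
and 0.1 fall on the lower-evidence side.

## Berkson error model

Kriging-predicted exposure is the center of a Berkson structure:
x_true = x_pred + u, u ~ N(0, se²) with the per-residence kriging standard
errors, errors independent across participants (spatial correlation of u is
deliberately ignored). Because the outcome model is linear and Gaussian,
the latent exposure integrates out analytically: record i's residual
variance becomes σ²_ε + β²_soil·se²ᵢ. The default fitter iterates this
closed form — REML for (σ²_family, σ²_ε) with the known variance offsets,
GLS for β, β_soil re-entering the offsets — to convergence (usually 3–5
iterations). Corrected intervals use a t reference with between-family
degrees of freedom (number of families minus the number of family-constant
regressors): the exposure carries cluster-level information only, and the
plain Gaussian reference discards the extra uncertainty from estimating the
variance components; the t correction restores calibration at the same
nominal 95% level. In a linear model, Berkson error inflates uncertainty
without attenuating the slope, so corrected point estimates track the naive
ones while intervals widen. An MCMC sampler (emcee) over the same marginal
likelihood — priors N(0, 10³) on fixed effects, half-Gaussian(1) on both
standard deviations, configurable — is provided as a cross-check; with all
se = 0 the procedure returns the naive fit unchanged.

## Synthetic data

The simulator generates the statistical structure the analysis assumes, so
every stage runs and is testable without any external data.

- Soil: sample locations follow the study design's intensity — 60% within
  200 m of the canal, 40% uniform over the box (proportions configurable);
  log10 values are quadratic drift (default β = (2.34, −2.23, 0.38)) plus
  an exact-Cholesky draw of the Gaussian field (defaults σ² = 0.32,
  τ² = 0.003, α = 46.67 m, γ = 0.5) plus nugget noise, back-transformed to
  mg/kg, with below-LOD values substituted and flagged. A smaller batch of
  deeper-layer samples (drift shifted −0.4, iid noise) exercises the
  topsoil filter. Parcels are a 100 m grid. The LOD step can be disabled
  (`lod=None`) for studies of the uncensored Gaussian model — parameter
  recovery and prediction fidelity are properties of that model, and
  censoring ~15–30% of values to a point mass would measure the censoring
  artefact instead; the substitution rule itself is tested directly.
- Cohort: 64 families (one mother aged 25–45, children aged 2–11 summing
  to 107 by default) in three village clusters offset from the canal; all
  family members share the residence and its true latent log10 soil value,
  drawn from the exact conditional law of the same field given the soil
  samples. Outcomes follow the linear mixed models with configurable
  coefficients (defaults on the order of: amalgam 0.33, recent sea fish
  0.32, age −0.04 for urine; sea fish 0.17, near-sea birth 0.19 for hair),
  a shared family intercept and Gaussian residuals. Covariate
  distributions are invented and recorded in the fixture manifest:
  amalgam Poisson(2) mothers / Poisson(0.2) children, sea-fish portions
  Poisson(3), family-level Bernoulli indicators, creatinine lognormal
  around 1 g/L with 3% outside the WHO range to exercise the exclusion.
- `scaled_study_config(n)` shrinks the bounding box so sampling density
  matches the full-scale default (3000 samples on 2400 × 800 m) — the
  right scaling when prediction quality (which depends on density) is the
  object of study. When separate recovery of the range parameter is the
  object, the full geometry must be kept and only n reduced (see
  Identifiability above).

Not emulated: real parcel topology and land use, anisotropy, non-Gaussian
tails, spatially correlated questionnaire behavior, and classical (as
opposed to Berkson) measurement error. Passing tests on this generator
therefore show internal consistency of the estimators under the stated
model, not robustness to those features of real data.

## Validation study sizes

The test suite exercises: kriging against an independently coded
bordered-system oracle on 50 small instances; REML recovery on 20
replicates of n = 500 at the default spatial parameters (full study
geometry); drift selection on 50 replicates of n = 1500 under the quadratic
drift with iid noise at the total variance σ² + τ² = 0.323 — the error
model of the OLS candidates being compared; 6-fold CV on 10 replicates of
n = 600 density-matched fields; coverage of the mixed-model CIs on 100
cohort replicates; Berkson behavior on 50 replicates; and full-pipeline
null runs (soil-derived effects zero, 10 replicates). These sizes were
chosen to make each property measurable with modest Monte-Carlo error.

## Known limitations

- Wald-z inference in the mixed models is liberal for family-level
  covariates at 64 families (documented above); joint statements across
  several such tests inherit that liberality.
- α and σ² are individually hard to identify at small n or small domains
  (the ridge above); report σ²/√α when in doubt.
- The Berkson model assumes independent errors; kriging errors at nearby
  residences are in truth positively correlated, so the corrected
  intervals are, if anything, slightly narrow for spatially clustered
  cohorts.
- Universal kriging smooths extremes; the calibration slope below 1 is a
  feature of the predictor, and exceedance-probability questions would
  need indicator kriging, which is out of scope.
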