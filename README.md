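# hgkrige

Geostatistical exposure assessment for soil-contamination health studies:
external-drift (universal) kriging of log soil mercury with REML variance
estimation, k-fold cross-validation, linkage of predicted exposures to a
human-biomonitoring (HBM) cohort, linear mixed models with a family random
intercept, and a Berkson measurement-error variant that propagates kriging
prediction uncertainty into the exposure–outcome regression.

The package is aimed at environmental epidemiologists who have (a) a dense
table of georeferenced total-mercury topsoil measurements around a
contaminating line feature (here: a canal that historically distributed
mercury-laden wastewater), and (b) urine and hair mercury values for mothers
and children living in the area, and who want to know whether soil
concentrations — measured at the nearest sampling point or predicted at the
exact residence — are associated with the biomonitoring values.

## Model

Soil. The log10 concentration at location *s* follows the spatial linear
model

    Y(s) = x(s)ᵀβ + B(s) + ε,

where the external drift x(s)ᵀβ is a quadratic polynomial in log10 distance
to the canal (chosen by AIC among linear, quadratic, broken-stick and
inverse alternatives), B is a stationary zero-mean Gaussian random field
with stable exponential covariance

    C(r) = σ² exp(−(r/α)^γ),  γ = 0.5 fixed,

σ² the sill, α the range (m), and ε iid noise with nugget variance τ².
(σ², τ², α) are estimated by Gaussian REML; prediction at unsampled
locations is the universal-kriging BLUP of the signal Z(s) = x(s)ᵀβ + B(s),
with a standard error that includes drift-estimation uncertainty.

HBM. log10 outcomes (urinary Hg in µg/g creatinine after exclusion of
samples with creatinine outside 0.3–3.0 g/L; hair Hg in µg/g) are regressed
on soil exposure and questionnaire covariates with a Gaussian family random
intercept. For kriging-predicted exposure, a Berkson error model
x_true = x_pred + u, u ~ N(0, se²) with the kriging standard errors is
marginalized in closed form (per-record residual variance σ²_ε + β²_soil se²)
and fitted iteratively; an MCMC sampler over the same marginal model serves
as a cross-check.

Soil values below the 0.1 mg/kg limit of determination are replaced by half
the limit and flagged; only the 0–20 cm topsoil layer is analysed.

## Worked example

No soil or HBM data are distributed; the built-in simulator generates a
study with the same statistical structure (documented defaults: drift
β = (2.34, −2.23, 0.38), σ² = 0.32, τ² = 0.003, α = 46.67 m, a 64-family /
171-participant cohort). The whole pipeline runs from the shell:

```sh
hgkrige run-all --seed 7 --out demo_out
```

which logs, stage by stage,

```
INFO hgkrige stage=preprocess topsoil=600 below_lod=123
INFO hgkrige stage=kriging sill=0.2904 nugget=0.0000 range=40.66
INFO hgkrige stage=crossval pearson_r=0.843 slope=0.711
INFO hgkrige stage=regression outcome=urine exposure=measured soil_p=0.508
INFO hgkrige stage=regression outcome=urine exposure=predicted soil_p=0.232
```

and writes eight report files (drift comparison table, fitted kriging
parameters, cross-validation summary, prediction grid, and the four mixed
model tables; the predicted-exposure tables carry extra columns with the
Berkson-corrected estimates). Reading the output: the REML estimates are
close to the generating values; the 6-fold cross-validation correlation
(~0.84 on this dense simulated field) with a calibration slope below 1
reflects the expected smoothing — high concentrations are somewhat
underestimated and low ones overestimated; and the soil coefficient in the
mixed models is small with a large p-value, as simulated.

The same analysis is available as a library:

```python
import hgkrige as h

cfg = h.scaled_study_config(600, seed=1, n_families=64, n_children_total=107)
soil_raw, field = h.simulate_soil_field(cfg, return_field=True)
participants, _ = h.simulate_participants(cfg, field)

soil = h.prepare_soil(soil_raw)                      # topsoil + half-LOD + log10
model = h.reml_fit(soil, h.DriftSpec("quadratic"), cfg.canal)
cv = h.cross_validate(soil, h.DriftSpec("quadratic"), cfg.canal, k=6, seed=1)
print(model.vp, cv.pearson_r)
```

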