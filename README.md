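# gaitfosr

Function-on-scalar regression for normative walking biomechanics.

`gaitfosr` fits penalized-spline functional additive models that predict
100-point gait-cycle waveforms — joint angles (deg), ground reaction
forces (N/kg), joint moments (Nm/kg) and joint powers (W/kg) — from seven
scalar covariates: sex, age, walking speed, body mass, height, cadence
and side. Each of the 16 supported outcomes gets its own model of the form

```
y_i(t) = beta0(t) + f_age(age_i, t) + f_speed(speed_i, t)
       + f_cadence(cadence_i, t) + f_height(height_i, t)
       + f_mass(mass_i, t) + sex_i * beta_sex + side_i * beta_side
       + b_i(t) + eps_i(t)
```

where the five `f(x, t)` terms are sum-to-zero-constrained tensor-product
B-spline surfaces (difference penalties in both directions), `b_i(t)` are
subject-level random curves on a shared time basis (ridge penalty,
predicted as BLUPs), and smoothing parameters are selected by REML via
Fellner–Schall updates (GCV available). Predictions come with pointwise
95% Wald bands or population-SD bands; model accuracy is summarised per
curve by RMSE, relative RMSE (% of the average curve range) and Pearson
correlation, aggregated per outcome as mean (SD) over a participant-level
80:20 train/test split.

A synthetic cohort generator with known ground-truth effect surfaces
(nonlinear age and speed effects, within-subject curve correlation,
Gaussian noise, three speed conditions per subject at 0.7x / 1.0x / 1.3x
the comfortable speed) makes the whole pipeline testable offline.

## Command-line usage

```bash
# generate a synthetic cohort (covariates.csv, curves.csv, truth.json)
gaitfosr simulate --n-subjects 100 --seed 1 --out-dir data/

# fit all outcomes present in the data on the training partition
# of a participant-level 80:20 split
gaitfosr fit --curves data/curves.csv --covariates data/covariates.csv \
    --out-dir fits/

# predict a normative waveform with a 95% CI band for a new profile
gaitfosr predict --fit fits/hip_sagittal_angle \
    --sex female --age 34 --speed 1.3 --mass 62 --height 1.68 \
    --cadence 112 --side left --kind ci --out prediction.csv

# evaluate on the held-out participants (mean (SD) per outcome)
gaitfosr evaluate --fits fits/ --curves data/curves.csv \
    --covariates data/covariates.csv --out report.csv

# smooth covariate-effect curves at the training quartiles
gaitfosr effects --fit fits/hip_sagittal_angle --covariate speed \
    --out speed_effect.csv
```

Model and pipeline settings (basis sizes, smoothing method, fixed-lambda
overrides, split fraction/seed, evaluation window, outcome selection) are
configured through a validated YAML file passed with `--config`; defaults
reproduce the study design (0.8 split, quartiles 0.25/0.5/0.75, 95%
level, full-cycle evaluation window).

## File formats

- Waveform CSV (long): `subject_id,outcome,side,speed_condition,t,value`,
  with `t` covering 0–99 exactly once per curve.
- Covariate CSV: one row per observation with
  `subject_id,sex,age,speed,mass,height,cadence,side,speed_condition`.
- Fitted models are saved as a directory bundle (`manifest.json` +
  `arrays.npz`); loading a bundle reproduces predictions bit-identically.

Indicator coding is fixed: sex male=0 / female=1, side left=0 / right=1.

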