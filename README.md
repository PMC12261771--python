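# preshock

Early prediction of circulatory shock from four routinely monitored
ICU waveforms — arterial blood pressure (ABP), ECG, respiration
(RESP) and pulse oximetry (SpO2) — one hour before onset, without
blood draws, using a **self-controlled design**: the negative class
for each patient is sampled from that same patient at a shock-remote
time, so the model learns deviations from an individual baseline
rather than differences between patients.

The package is an end-to-end, tested pipeline for that analysis:

1. **Synthetic cohort** (`preshock.simulate`) — a seedable generator
   of multi-day, multi-channel ICU records with ground-truth shock
   events (a scripted MAP collapse crossing 65 mmHg, plus a
   qualifying lactate), sparse labs, covariates, dropout gaps, and
   configurable pre-shock physiological drift injected only into the
   90 minutes before onset.  It stands in for the credentialed
   clinical archive the design targets, which cannot ship here.
2. **Event labeling** (`preshock.labeling`) — shock = beat-averaged
   MAP ≤ 65 mmHg for more than 1 minute with serum lactate
   ≥ 2 mmol/L within 12 h of the episode onset (first event per
   patient).  A 30-min observation window ends 60 min before onset;
   a 30-min self-control window sits beyond a 24-h washout before
   the event (Scenario 1) or a 7-day washout after it (Scenario 2).
   Cohort exclusions (missing channel, < 90 min pre-onset data,
   > 50 % missing samples, no feasible control) are applied and
   logged.
3. **Feature engine** (`preshock.features`, `preshock.complexity`) —
   a fixed, versioned catalog of **299 features per 10-minute
   sub-window**: 90 ABP (nine beat-level pressure parameters × a
   ten-statistic battery), 89 ECG heart-rate-variability indices,
   112 RESP (nine breath-cycle parameters × ten statistics + 22
   respiratory-rate-variability indices) and 8 SpO2 features.  The
   nonlinear measures (SampEn, ApEn, multiscale entropy, Lempel-Ziv
   complexity, CTM, Hurst, DFA/MFDFA, Lyapunov, correlation
   dimension, Poincaré SD1/SD2) are implemented in-package and
   oracle-tested against brute-force references.
4. **Model pipeline** (`preshock.modeling`) — chained-equation
   imputation, mutual-information ranking with top-65 selection, a
   patient-level 60/20/20 split, six models (weighted ensemble,
   XGBoost, LightGBM, histogram gradient boosting, random forest,
   extremely randomized trees), patient-bootstrap 95 % CIs, Shapley /
   permutation importance, and per-feature logistic confirmation
   (unadjusted and adjusted for age, sex, BMI, neck and waist
   circumference).

See `docs/methods.md` for the model, parameter and catalog details.

## Worked example

The numbered drivers under `analysis/` run the study on a seeded
40-patient synthetic cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort + ground-truth manifest
python analysis/02_label_events.py         # events, windows, exclusions
python analysis/03_extract_features.py     # 299-feature table (regenerates features.csv)
python analysis/04_train_models.py         # selection, six-model bench
python analysis/05_importance_and_regression.py
```

Step 02 verifies the labeling chain against the generator's ground
truth:

```
windows: 80; excluded: 0
onset error vs ground truth: max 1.0 s over 40 detected events
```

every simulated shock onset is re-detected from the raw waveforms
within one second of truth, and each of the 40 patients contributes
one observation and one Scenario-1 control window (80 windows → 400
feature rows).  Step 04 prints the test-set bench (8 held-out
patients, 80 rows):

```
           model   auc  auc_lo  auc_hi  accuracy_pct  sensitivity_pct  specificity_pct
WeightedEnsemble 1.000   1.000   1.000        98.750           97.500          100.000
         XGBoost 0.988   0.963   1.000        98.750           97.500          100.000
        LightGBM 1.000   1.000   1.000       100.000          100.000          100.000
          HistGB 1.000   1.000   1.000       100.000          100.000          100.000
              RF 1.000   1.000   1.000       100.000          100.000          100.000
              ET 1.000   1.000   1.000       100.000          100.000          100.000
best model: WeightedEnsemble
```

The injected pre-shock drift is deliberately strong relative to the
clean synthetic baselines, so the bench separates observation from
control windows essentially perfectly, and attribution concentrates
on a single dominant family — step 05 reports
`ABP_TimeSBP2DBP_SampEn` carrying an ensemble permutation AUC-drop of
0.475 (and mean |SHAP| 4.88 in the boosted model) with the redundant
remainder at zero, plus the per-unit odds ratios of the five injected
families, whose signs all match the injected directions (pNN50 ↑,
respiratory width ↓, cycle rate ↓, systolic-diastolic-interval sample
entropy ↑, diastolic step amplitude ↓; the strongest effects hit
complete separation and are flagged accordingly).  The interesting
checks are the calibration ones: with drift disabled the same
pipeline's test AUC drops to chance — the suite asserts it lands in
[0.4, 0.6] and that observation/control feature distributions are
statistically exchangeable.

A `preshock` console command exposes the same pipeline stage-by-stage
with on-disk artifacts and config sidecars:

```bash
preshock all --config run.yaml --seed 3
```

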