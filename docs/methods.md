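# Methods

`preshock` implements a self-controlled analysis of impending
circulatory shock from four routinely monitored ICU waveforms:
arterial blood pressure (ABP), ECG, respiration (RESP) and pulse
oximetry (SpO2).  Because the credentialed clinical waveform archive
the design targets cannot ship with the package, a seedable synthetic
cohort generator stands in for it; every downstream stage (event
labeling, windowing, feature extraction, selection, modeling) is
archive-agnostic and consumes the same `WaveformRecord` container it
would get from WFDB or CSV files.

## Shock definition and the self-controlled design

A shock event is a hypotensive episode — beat-averaged mean arterial
pressure (MAP) at or below 65 mmHg sustained strictly longer than one
minute on a 1 Hz MAP series — qualified by a serum lactate of at
least 2 mmol/L drawn within 12 h of the episode onset.  Only the
first qualifying event per patient is analysed.  The comparison
operator for lactate is configurable (`ge`, the default, or `gt`)
because the two conventions differ only at the boundary value and the
choice is worth exposing for sensitivity analysis; likewise the
">1 min" rule is implemented strictly (a 60 s run does not qualify, a
61 s run does).

Prediction uses a 30-minute observation window ending one hour before
onset (the intervening hour is a prediction blackout).  The negative
class comes from the same patient: a 30-minute control window either
ending at the 24-hour washout boundary before onset (Scenario 1,
preferred when feasible because it precedes all shock physiology) or
starting at the 7-day washout boundary after it (Scenario 2).
Controls are placed flush against the washout boundary for
determinism.  Patients with no feasible control are excluded, since a
self-controlled contrast requires a within-patient negative; the
other exclusions (a missing channel, under 90 min of pre-onset data,
more than 50% missing samples in any used window/channel) follow the
cohort-construction rules of the study design.  "More than 50%
missing" is applied per channel per used window — the strictest
defensible reading — and each exclusion is logged with its first
triggered reason.

Each 30-minute window is tiled into five 10-minute sub-windows at
5-minute steps (10-min rolling window, 5-min overlap); each
sub-window is one feature row, and all rows of a patient inherit the
patient's split assignment so no patient appears in two partitions.

## The synthetic cohort

The generator scripts one patient at a time from a per-patient seeded
stream (`SeedSequence([seed, patient_index])`), so cohorts are
byte-reproducible and lazily streamed.  Default study conditions:

* Record layout: 24.75 h before onset and 2 h after, which hosts the
  observation window, the 24-h washout and a Scenario-1 control.  All
  included patients are shock patients (`shock_fraction = 1`); the
  self-controlled design draws its negatives within-patient, and
  non-shock patients are supported only for null/detection tests.
* Sampling rates: ABP 62.5 Hz, ECG 125 Hz, RESP 12.5 Hz, SpO2 1 Hz —
  integer decimations of monitor-archive rates, chosen to resolve
  beat- and breath-level fiducials while keeping a multi-day record
  tractable; the ECG rate must exceed 90 Hz for the 3-45 Hz passband.
* Hemodynamics: MAP baseline 85 ± 4 mmHg between patients (floor 76),
  pulse pressure 45 ± 6 mmHg with 3 mmHg beat-to-beat jitter, heart
  rate 85 ± 10 bpm.  The ABP pulse is a linear upstroke over ~30% of
  the beat followed by an exponential decay normalized to land
  exactly on the diastolic pressure, so the beat average has the
  closed form DBP + s(rf)·PP used as an oracle in tests, and
  systolic-timing jitter does not perturb diastolic values.
* R-R structure: AR(1) baseline wander plus low-frequency (0.095 Hz)
  and respiratory-frequency oscillations and white jitter (12 ms SD),
  clipped to 420-1400 ms.  The ECG channel is a clean R-peak spike
  train: every cardiac feature in the catalog derives from the R-R
  point process, which carries the physiology.
* Respiration: raised-cosine cycles, 16 ± 1.2 breaths/min between
  patients, with per-cycle amplitude and symmetry noise.  SpO2 is a
  slowly wandering trend near 97%.
* The shock episode is a scripted MAP trajectory: decline to 74 mmHg
  over four minutes, collapse at 3 mmHg/s crossing 65 mmHg exactly at
  the true onset, a 12-minute plateau at 58 mmHg, then recovery.  The
  steep crossing pins the detectable onset to the truth within one
  1 Hz sample; outside the episode the trajectory never drops below
  ~72 mmHg, so the event is unique.  A qualifying lactate
  (2.5-5.5 mmol/L) is emitted 0.5-8 h after onset; baseline lactates
  (~1.0 ± 0.25, capped at 1.8) arrive every 4-12 h.
* Missingness: ~1% of each channel masked in 0.2-1 s gaps.

### Injected pre-shock drift

Drift is active only inside the 90 minutes before onset and perturbs
the generative parameters of the five headline feature families, with
directions matching the reported risk associations:

| family                      | mechanism                                   | default magnitude |
|-----------------------------|---------------------------------------------|-------------------|
| ECG_HRV_pNN50 up            | extra white R-R jitter                      | 20 ms SD          |
| RESP_Width_Mean down        | rise-fraction (symmetry) shift              | +0.22             |
| RESP_Cycle_Rate_Mean down   | breath-rate delta                           | -2.0 /min         |
| ABP_TimeSBP2DBP_SampEn up   | systolic-timing jitter                      | 0.035 beat frac   |
| ABP_AmplitudeDBP_Median down| pulse-pressure jitter scaling               | x0.55             |

The source material reports only directions (and odds ratios on its
own cohort), not effect magnitudes, so magnitudes are free parameters
chosen once to make recovery informative: large enough that the
pipeline should find the signal, small enough that the respiratory
families are not drowned out of the top-65 selection by the dozens of
correlated R-R and pressure-amplitude features.  The width and rate
mechanisms interact (slower breathing lengthens cycles, which widens
the decay limb), so the symmetry shift is sized to dominate; the
pulse decay normalization exists precisely so the timing-jitter
mechanism does not leak into diastolic amplitudes.

All randomness is drawn before effects are applied, and effects are
deterministic transforms of those draws; `inject_preshock_drift`
re-synthesizes a record with effects and splices only the drift
window, so samples outside it are bit-identical (verified in tests).
One numerical caveat discovered during development and now guarded by
the null tests: per-sample phase inside a beat/breath must be
computed from integer within-segment offsets, because float32 sample
indices lose sub-sample precision ~24 h into a record and the
resulting late-record quantization noise is exactly the kind of
artifact a self-controlled contrast amplifies.

### What the generator does not emulate

No pulse morphology beyond the rise/decay template (no dicrotic
notch), no arrhythmias or ectopy, no ventilator interaction, no
artifact classes other than dropout gaps and white noise, no
treatment response, and no relation between covariates and outcome
(covariates exist to exercise the adjusted regression only).  Passing
recovery tests therefore demonstrates that the pipeline measures what
it claims to measure on signals with known ground truth — not that
the reported clinical effect sizes generalize.

## Signal conditioning

ECG is band-passed 3-45 Hz (zero-phase 4th-order Butterworth; forward-
backward filtering avoids phase distortion that would bias interval
features).  R peaks come from an amplitude-threshold detector with a
200 ms refractory period; R-R intervals outside the open interval
(400, 1500) ms — heart rate below 40 or above 150 bpm — are replaced
by linear interpolation between valid neighbours.  ABP is masked by a
signal-quality index at 0.5 s check-window granularity (pressure
outside 20-300 mmHg, zero variance, or within-window slew above
25 mmHg/sample); criteria use within-window differences only, so an
isolated artifact invalidates exactly its own window.  Respiration is
smoothed with a zero-phase 1 Hz low-pass, then segmented into
trough-peak-trough cycles by prominence (0.25 x SD) with a 1.5 s
minimum cycle; record endpoints count as trough candidates so
boundary-complete cycles are kept.  Raw-signal gaps under 2 s are
linearly interpolated before fiducial detection; chained-equation
imputation is applied at the feature-table level (sklearn's
IterativeImputer, 10 iterations, seeded), because imputing raw
waveform samples by chained equations is ill-posed — this is the one
deliberate reinterpretation of the stated preprocessing order, at
what we judge the defensible granularity.

## The 299-feature catalog

The catalog is fixed, ordered and versioned; every window yields all
299 keys (degenerate inputs produce NaN missing-markers, which the
imputer later fills).

* **ABP (90):** nine beat-level parameters — systolic and diastolic
  pressure, pulse pressure, MeanAP (waveform average between adjacent
  onsets), formulaic MAP (DBP + PP/3, kept distinct from MeanAP),
  heart rate, TimeSBP2DBP (systolic peak to next diastolic point),
  and absolute differences of consecutive systolic / diastolic values
  — each summarized by the ten-statistic battery (min, mean, max,
  median, SD, skewness, excess kurtosis, Hurst exponent, largest
  Lyapunov exponent, sample entropy).
* **ECG (89):** an HRV panel over the cleaned R-R series spanning
  time (SDNN, SDANN, RMSSD, pNN10/20/30/50, MCVNN = MAD/median, ...),
  frequency (ULF/VLF/LF/HF absolute, relative, log and normalized
  powers via Welch on a 4 Hz-resampled series; band peaks),
  time-frequency (STFT and discrete-wavelet LF/HF summaries), and
  nonlinear (Poincare SD1/SD2 and derived indices, ApEn, SampEn,
  multiscale entropy at scales 2-5, DFA alpha-1/alpha-2/overall,
  correlation dimension, Hurst, Lyapunov, LZC, CTM, entropy and
  fractal-dimension measures, fragmentation and asymmetry indices,
  and the multifractal-DFA alpha-1 peak).  The exact 89-member list
  is pinned in `catalog.py`; ULF and SDANN are computed on the
  10-minute sub-window even though they are conventionally defined on
  longer records — on 10 minutes they reflect slow trend power and
  segment spread, a documented caveat.
* **RESP (112):** nine per-cycle parameters (rise amplitude, width =
  peak-to-next-trough time, peak-peak and trough-trough intervals,
  decay amplitude, cycle rate, respiratory volume per time proxy =
  amplitude/duration, peak-trough symmetry and rise-decay symmetry,
  both ratios in (0,1) with 0.5 = symmetric) x the ten-statistic
  battery, plus a 22-index respiratory-rate-variability panel over
  breath-to-breath intervals: time-domain spread measures, band
  powers by Welch, Burg (AR spectral estimate) and Lomb-Scargle,
  wavelet LF/HF, SampEn, Poincare SD1/SD2, and the MFDFA alpha-1
  peak.  RRV bands are LF 0.01-0.05 Hz and HF 0.05-0.15 Hz.
* **SpO2 (8):** min, mean, max, median, SD, SampEn, LZC, CTM.

## Complexity metrics

All nonlinear measures are implemented in-package as pure,
deterministic functions and are oracle-tested against independent
brute-force implementations:

* SampEn(m=2, r=0.2 x series SD, Chebyshev distance, self-matches
  excluded, equal m/m+1 template counts); ApEn with self-matches
  included; multiscale entropy coarse-grains by averaging and holds r
  fixed from the raw series so scale 1 reproduces SampEn exactly.
  Using the sub-window's own SD for r makes these measures invariant
  to affine rescaling.
* Lempel-Ziv complexity parses the median-binarized sequence by
  exhaustive-history LZ76 and normalizes by n/log2(n).
* CTM is the fraction of successive-difference scatter points within
  radius rho (default 0.1 x SD) of the origin.
* Hurst uses rescaled-range regression with the Anis-Lloyd-Peters
  small-sample correction (plain R/S is biased upward ~0.55-0.6 for
  i.i.d. noise at these lengths; the correction centres it at 0.5).
* DFA is order-1 with log-spaced scales covering the profile from
  both ends; MFDFA returns the singularity-spectrum mode over
  q in {-5...5} (q=0 via the log-average).
* The largest Lyapunov exponent follows Rosenstein's nearest-
  neighbour divergence slope (m=2, delay 1, temporal exclusion band,
  8 follow steps); correlation dimension is Grassberger-Procaccia
  slope over the 10th-60th distance percentiles.  Both evenly
  subsample inputs beyond 400 points; both are declared estimator
  choices — the study design names the quantities without fixing
  algorithms.
* Degenerate inputs return documented constants (flat series: SampEn
  0, Hurst 0.5, DFA 0.5, Lyapunov 0, CD 0, CTM 1) or NaN
  missing-markers rather than raising, so extraction never aborts a
  window.

## Selection, models and evaluation

Mutual information between each imputed feature and the window label
is estimated with scikit-learn's k-nearest-neighbour estimator under
a fixed seed; ties break by catalog order. The default selection
keeps the top 65 (a sweep utility over k = 30-100 on validation AUC
is provided).  Patients are shuffled by seed and partitioned
60/20/20 into train/validation/test; all rows of a patient share its
partition.

The bench fits five seeded base learners — XGBoost (max depth 6,
L2-regularized logistic objective), LightGBM (31 leaves), a histogram
gradient-boosting classifier (max depth 6), random forest and
extremely randomized trees (both 100 estimators, Gini) — and a
weighted ensemble built by greedy forward selection with replacement
over validation AUC (10 rounds), giving convex weights and a
validation AUC no worse than the best single model.

Evaluation reports accuracy, AUC, sensitivity and specificity at a
0.5 probability threshold (configurable), with 95% percentile
bootstrap CIs resampled at the patient level (1000 resamples by
default) — rows within a patient are correlated, so row-level
resampling would understate uncertainty.  Importance for the
best-performing model (highest test AUC) uses the exact tree-explainer
Shapley values native to XGBoost/LightGBM, falling back to permutation
AUC-drop (5 repeats, seeded) for the ensemble and the sklearn forests.
Per-feature logistic confirmation emits unadjusted and adjusted
(age, sex, BMI, neck and waist circumference) odds ratios with Wald
CIs; complete separation — common when injected effects are strong —
is flagged (`converged = False`) and a ridge-penalized refit supplies
a finite, correctly signed coefficient with CI and p withheld.

## Problem sizes and calibration checks

The default test suite exercises the full pipeline on a 60-patient
drifted cohort (effect recovery: test AUC, top-65 membership and
odds-ratio signs of the five injected families) and a 120-patient
zero-drift cohort (null calibration: ensemble test AUC within
[0.4, 0.6], and feature-wise exchangeability of observation vs
control windows by KS tests on per-patient window means under
Benjamini-Hochberg control).  The null cohort is larger because
chance-level AUC concentrates as the test partition grows: with 24
test patients its spread makes [0.4, 0.6] a ~2.5-sigma band, sized
from pilot variance estimates before the suite seeds were frozen.
The acceptance script recomputes the selection count on a 12-patient
cohort, which is ample for a cardinality check.

## Known limitations

Synthetic waveforms are far cleaner than clinical archives; detector
hit rates here are upper bounds.  SDANN/ULF on 10-minute windows are
trend proxies.  The HRV/RRV panels pin plausible, versioned index
lists whose exact membership beyond the named indices is a package
choice.  Odds ratios on strongly drifted synthetic cohorts routinely
hit separation and are reported as signed, flagged estimates.  The
breath detector's endpoint-trough convention adds two
boundary-truncated cycles per window; their parameters are genuine
but slightly noisier.
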