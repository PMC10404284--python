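# Methods

## Problem and study design

`pulsedx` implements a diagnostic (not prognostic) classification pipeline for
detecting the transition of a chronic heart-failure (HF) or COPD patient from
the compensated to the decompensated state, using only heart rate (HR, bpm)
and oxygen saturation (SpO2/Ox, %) sampled at 1 Hz by a pulse oximeter during
a standardized protocol: walking at a normal pace for at most 6 minutes,
followed by 4 minutes of seated recovery.

The unit of analysis is a *comparative unit*: the ordered difference between
two evaluations of the same patient. Each patient contributes up to three
evaluations — V1 during hospitalization (decompensated) and V2/V3 at home
about a month later (compensated) — and therefore up to six ordered pairs.
A pair is labeled 1 ("change to decompensation") exactly when its destination
is V1, otherwise 0. A recovery class (V1→home) is deliberately not modeled;
those pairs are labeled 0. This design lets each patient act as their own
control and avoids fixed population-wide thresholds.

## Synthetic cohort generator

No patient recordings are distributed, so the package ships a generator whose
defaults encode the study conditions:

* **Effect sizes.** Decompensation raises HR by a per-patient shift drawn
  uniformly from 5–7 bpm, lowers SpO2 by 1–2 percentage points, and slows the
  post-exercise HR recovery (exponential time constant 80 s vs 45 s when
  compensated). These magnitudes are the ones reported by ambulatory-monitoring
  studies of COPD exacerbation and HF decompensation.
* **Signal model.** HR(t) = patient baseline + state shift + a logistic rise
  toward the exercise plateau (midpoint 60 s, width 20 s, amplitude 20–35 bpm)
  during the walk, an exponential decay back to rest during recovery, a
  patient-specific respiratory sinusoid (0.5–2 bpm at 0.15–0.35 Hz), and white
  noise (sd 2 bpm). SpO2(t) = baseline − state drop − an effort-related dip
  (1–3 points, time constant 60 s) + a slow oscillation + noise (sd 0.8),
  clipped to [70, 100]. Patient traits are drawn once per patient; a
  per-evaluation "day" jitter (sd 1.5 bpm / 0.4 points) models visit-to-visit
  baseline variation. With noise, jitter and dropout disabled the planted
  shifts can be read back exactly from the walk-phase means, which the tests
  exploit.
* **Protocol timing.** Walk duration is drawn per evaluation from a normal
  distribution (mean 355 s, sd 20 s) truncated to [180, 360] s — matching
  observed walking times of ~6 minutes — and recovery is fixed at 240 s.
* **Dropout.** Sensor-contact loss is drawn once per evaluation (uniform in
  0–12% by default) and placed as 1–3 *contiguous* masked runs per signal and
  phase, mimicking sensor detachment rather than i.i.d. missingness. Masked
  values are flagged, never altered.
* **Visit structure.** V1 is always present; V2 and V3 are each absent with
  probability 0.15 (never both). mMRC dyspnea at home is at least one point
  better than at V1 unless `p_mmrc_violation` requests filter-violating
  patients. V2 and V3 are treated as i.i.d. around the patient's compensated
  baseline; no extra V2–V3 correlation is modeled.

What the generator does **not** emulate: arrhythmia, motion artifacts,
activity outside the protocol, oximeter quantization, or any physiological
coupling beyond the additive components above. Passing tests therefore show
that the pipeline recovers effects of the stated magnitude under this
statistical structure — not that it would reach the same performance on real
recordings.

## Preprocessing and exclusion filters

Evaluations are split at the recorded walk/recovery boundary (no automatic
boundary detection). Filters mirror the study rules:

1. an evaluation is excluded if its missing-sample loss rate is **strictly
   greater than 10%** in any phase of either signal (exactly 10% is retained);
2. home evaluations without a ≥ 1 point mMRC improvement over V1 are excluded;
3. patients left without a valid V1 or without any valid home evaluation are
   removed entirely (both cases leave the patient with only one label class).

Filtering is idempotent and fully logged. No imputation is performed;
temporal statistics use observed samples only.

The third signal, HRminusOx, is the pointwise difference of z-scored HR and
SpO2. The standardization is fitted per evaluation over the *concatenated*
walk+recovery observed samples: a per-phase fit would force the phase means
of the difference to zero and destroy the informative mean features. A
zero-dispersion input produces an all-zero, flagged difference. Whether the
original analysis standardized per evaluation or across the corpus is not
stated; per-evaluation is the default and corpus statistics can be supplied
explicitly.

## Features (96 per evaluation)

For each of 3 signals × 2 phases, 16 characteristics:

* temporal (3): mean, standard deviation (population convention, ÷N), range;
* harmonic (7): frequency and amplitude of the largest and second-largest
  magnitude bins ("first/second harmonic", ties toward the lower frequency),
  magnitude-weighted skewness and *excess* kurtosis of frequency, and the sum
  of all magnitudes;
* spectral PCA (6): projections onto the first six principal components of
  the group's normalized spectra.

Spectra are computed on a fixed per-phase grid so that evaluations of unequal
duration are comparable: masked runs are linearly interpolated (the ≤ 10%
loss bound limits the distortion; this is the only place gaps are filled),
the mean is removed, and the series is zero-padded to 512 points (walk) or
256 points (recovery) — the next power of two above the nominal phase length.
The DC bin is dropped, leaving bins at k/N Hz up to the 0.5 Hz Nyquist limit.
Harmonic amplitudes and the magnitude sum use the raw spectrum; spectral
moments and PCA use the unit-sum-normalized spectrum (otherwise the sum
feature would be identically 1). Weighted moments over frequency (rather than
moments of the amplitude values) are the default reading of "distribution of
the harmonics".

PCA components carry a deterministic sign (largest-magnitude loading
positive) and are refitted inside each validation fold by default to avoid
leakage; `refit_pca=False` reproduces the single all-data fit.

## Selection, scaling, tuning

Three tree classifiers (random forest, gradient boosting, LightGBM) are each
fitted on the units; the **union** of their top-10 impurity-importance lists
forms the candidate set (union, not intersection: 19 selected from three
top-10 lists is only possible with overlap). Features with variance below
1e-8 and the weaker member of any pair with |Pearson r| > 0.95 are pruned,
with every drop logged. The thresholds are deliberately conservative — they
act only on near-degenerate columns. Age, sex and baseline disease can
compete as candidate predictors (`augment_covariates`). The historical
19-name list is available as a frozen preset (`SELECTED_19_PRESET`) for users
who want to reproduce that exact predictor set.

Features are scaled as (x − median)/IQR with statistics fitted on training
rows only; quantiles use linear interpolation, a zero IQR becomes a divisor
of 1 with a log entry, and the fitted row set is recorded for leakage audits.

Hyperparameters are chosen by exhaustive grid search under 5-fold CV,
stratified by label and grouped by patient. The grids are not part of the
original report; the shipped defaults are modest (tree depth {2,4,8,∞};
100/300 estimators for the ensembles; k ∈ {3,5,9} for KNN; C ∈ {0.1,1,10}
with linear/RBF kernels for SVM; C ∈ {0.1,1,10} for logistic regression).
Selection is by mean fold accuracy with ties broken toward the simpler model
(fewer estimators, smaller depth, fewer neighbors, stronger regularization,
linear before RBF). Rows are canonically reordered before fold assignment so
results do not depend on input order. By default tuning (and feature
selection) run once on all units before validation — the original procedure,
which its authors themselves flag as potential validation leakage — and
`nested=True` re-tunes inside each training fold. Class imbalance (~1:2) is
left unweighted by default.

## Validation and aggregation

Internal validation is leave-one-patient-out: for each patient, the spectral
PCA bases, the scaler and the classifier are fitted on all other patients'
units and the held-out patient's units are classified. Outcomes are tallied
per patient (TP: predicted and labeled 1; TN: 0/0; FP: 1/0; FN: 0/1), and
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy = (TP+TN)/total
are computed per patient. **Cohort values are unweighted means over
patients**, not pooled-count ratios — patients contribute unequal unit
counts, so the two aggregations genuinely differ, and the pooled totals are
reported separately. Every retained patient has both a positive and a
negative unit by construction (valid V1 + ≥1 home visit); if a user-supplied
cohort violates this, the patient is dropped from the affected mean with a
warning. Predictive values (PPV/NPV) are not reported by default because the
1:2 class proportion is far from the community prevalence.

### Chance band for null calibration

To test that no technique detects signal on a zero-effect cohort, accuracy is
compared with the 95% band around the accuracy expected when predictions are
independent of labels, p_e = q·p1 + (1−q)·p0 (q = positive-prediction rate).
Two corrections matter:

* Units are **clustered**: each A→B unit has its exact negation B→A within
  the same patient, and units sharing an evaluation share its noise, so the
  independent-trials binomial SE under-covers. `chance_band` therefore
  supports a cluster-robust SE with patients as clusters.
* The check is **one-sided** (accuracy must not exceed the upper edge).
  Cross-validated accuracy on null data is pessimistically biased — holding a
  patient out shifts the training distribution against the held-out units —
  so honest chance-level behavior can land below p_e; only the upper edge
  tests spurious detection.

For the same reason the null run uses the frozen 19-feature preset rather
than data-driven selection: selecting features on all units before LOPO
inflates held-out accuracy on pure noise (classic selection leakage), which
would confound the calibration check.

## Numerical conventions and degenerate inputs

* Standard deviations are population (÷N) throughout the feature space.
* IQR quantiles: linear interpolation (numpy default).
* All-zero spectra yield all-zero harmonic features with a degeneracy flag;
  a zero-variance PCA ensemble reports zero explained variance.
* Harmonic ties break toward the lower frequency; PCA signs are fixed by the
  largest-magnitude loading.
* Reproducibility: a single global seed fans out to per-stage seeds via
  `numpy.random.SeedSequence(seed).spawn()`; identical resolved configs give
  byte-identical outputs.

## Problem sizes used in the shipped checks

The packaged test-suite and the acceptance script exercise the pipeline on
simulated cohorts of 60 patients (the analyzed cohort size of the original
study) for the planted-effect and null runs, 200 patients for the
distributional null of the generator, and smaller constructed fixtures for
exact arithmetic checks.

## Known limitations

* The generator's realism is statistical, not physiological (see above).
* The exact 19-feature list of the original analysis is a property of its
  (undeposited) data; the preset reproduces the *names*, not the claim that
  selection on new data would return them.
* The paper-faithful tuning/selection order is knowingly leakage-prone; the
  nested options exist precisely because of that.
* Spectral leakage from the rectangular window means the "second harmonic"
  of a near-pure tone is usually the main tone's sidelobe; this matches the
  plain-FFT reading of the method and is consistent across all evaluations.
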