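# pulsedx

Diagnostic models of **decompensated heart failure (HF) / COPD exacerbation**
from 1 Hz pulse-oximeter recordings (heart rate and SpO2) taken during a
standardized walk (≤ 6 min) + seated recovery (4 min) protocol.

The package is for biostatisticians and physiological-monitoring researchers
who want a tested, reproducible implementation of the whole method — from raw
two-phase recordings to patient-wise diagnostic metrics — plus a synthetic
cohort generator so every stage can be exercised without patient data.

## The method

Each patient is evaluated up to three times: **V1** in hospital while
decompensated, **V2**/**V3** at home while compensated. For every evaluation,
96 characteristics are extracted — for each of 3 signals (HR, Ox, and the
standardized difference HR−Ox) × 2 phases (walk, recovery):

* temporal: mean, standard deviation, range;
* harmonic: frequency/amplitude of the two largest FFT magnitude bins,
  magnitude-weighted skewness and excess kurtosis, sum of all magnitudes;
* spectral PCA: projections onto the first 6 principal components of the
  normalized magnitude spectrum (512-point FFT for the walk, 256 for
  recovery).

The classifier input is the **comparative unit**: for an ordered visit pair
(A → B), the feature difference Δ = f(B) − f(A), labeled 1 exactly when B =
V1 ("change to decompensation"), else 0. A three-visit patient yields 6 units
(2 positive), a two-visit patient 2 units (1:1).

Predictors are the union of the top-10 importance rankings of random forest,
gradient boosting and LightGBM, pruned of near-constant and redundant
(|r| > 0.95) columns. Features are scaled by training-set median/IQR,
hyperparameters tuned by patient-grouped 5-fold grid search, and eight
classifier families (decision tree, random forest, KNN, SVM, logistic
regression, naive Bayes, gradient boosting, LightGBM) are validated
**leave-one-patient-out**. Per patient, predictions are tallied as TP/TN/FP/FN
and sensitivity S = TP/(TP+FN), specificity E = TN/(TN+FP) and accuracy
A = (TP+TN)/n are computed; cohort S/E/A are the *unweighted means over
patients* (not pooled ratios — patients have unequal unit counts).

Evaluations with > 10% missing samples in any phase, home evaluations without
a ≥ 1-point mMRC dyspnea improvement over V1, and patients left without a
valid V1 or home visit are excluded, mirroring the study's filters. No
imputation is performed.

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

```python
import pulsedx as px

# simulate a 60-patient cohort with the reported decompensation effects:
# HR +5-7 bpm, SpO2 -1-2 points, slowed heart-rate recovery
cohort = px.generate_cohort(px.SimulationConfig(n_patients=60, seed=1))
filtered, excl = px.apply_filters(cohort)
print(f"{len(filtered)} of {len(cohort)} patients retained "
      f"({len(excl)} exclusions logged)")

results = px.lopo_evaluate(filtered, ["logistic_regression", "svm"], seed=0)
print(px.report(results).to_string(index=False))
```

prints

```
50 of 60 patients retained (33 exclusions logged)
          technique  true_positive  false_negative  true_negative  false_positive  sensitivity  specificity  accuracy
logistic_regression             76               0            128               0        100.0        100.0     100.0
                svm             76               0            128               0        100.0        100.0     100.0
```

Ten simulated patients lose an evaluation to the >10% sensor-dropout filter
or a home visit entirely; the 50 retained contribute 204 units (76 positive).
At the planted effect sizes the transition is cleanly separable, so both
headline techniques classify every held-out patient's units correctly —
sensitivity, specificity and accuracy are reported in percent as patient-wise
means, with the pooled confusion totals alongside.

The same pipeline is available from the shell:

```bash
pulsedx simulate --n-patients 60 --seed 1 --out cohort/
pulsedx run-all --seed 7 --out runs/demo          # full pipeline, 8 techniques
pulsedx evaluate --cohort cohort/ --preset-19 --out runs/preset
```

Every run directory contains the resolved config, per-stage seeds, exclusion
log, feature matrix, units table, selection report, and the technique
comparison table (CSV + JSON).

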