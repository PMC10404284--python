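"""Leave-one-patient-out validation and per-patient diagnostic metrics.

Each fold holds out all comparative units of one patient; the spectral PCA
bases, the median/IQR scaler, and the classifier are fitted on the remaining
patients and the held-out units are classified.  Predictions are tallied per
patient as TP/TN/FP/FN, sensitivity (S), specificity (E) and accuracy (A) are
computed per patient, and cohort values are the *unweighted means over
patients* — deliberately not the pooled-count ratios, because patients
contribute unequal numbers of units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparisons import build_units, feature_columns, units_to_frame
from .features import FeatureExtractor
from .modeling import ModelSpec, fit_scaler, grid_search, make_estimator
from .records import PatientRecord
from .selection import augment_covariates, select_features

logger = logging.getLogger("pulsedx")

OUTCOMES = ("TP", "TN", "FP", "FN")


def classify_outcome(prediction: int, label: int) -> str:
    """Confusion-cell name for one (prediction, label) pair."""
    if prediction not in (0, 1) or label not in (0, 1):
        raise ValueError("prediction and label must be 0 or 1")
    return {(1, 1): "TP", (0, 0): "TN", (1, 0): "FP", (0, 1): "FN"}[(prediction, label)]


@dataclass
class PatientMetrics:
    patient_id: str
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None


@dataclass
class CohortMetrics:
    """Patient-wise mean S/E/A plus pooled confusion totals (kept separate)."""

    mean_sensitivity: float
    mean_specificity: float
    mean_accuracy: float
    pooled_tp: int
    pooled_fn: int
    pooled_tn: int
    pooled_fp: int
    n_patients: int


def aggregate(per_patient: list[PatientMetrics]) -> CohortMetrics:
    """Unweighted means over patients; patients with an undefined metric are
    dropped from that mean with a warning (a valid cohort has none)."""

    def mean_of(attr: str) -> float:
        values = [getattr(m, attr) for m in per_patient]
        defined = [v for v in values if v is not None]
        if len(defined) < len(values):
            warnings.warn(
                f"{len(values) - len(defined)} patient(s) dropped from the "
                f"{attr} mean (metric undefined for their unit mix)",
                stacklevel=2,
            )
        return float(np.mean(defined)) if defined else float("nan")

    return CohortMetrics(
        mean_sensitivity=mean_of("sensitivity"),
        mean_specificity=mean_of("specificity"),
        mean_accuracy=mean_of("accuracy"),
        pooled_tp=sum(m.tp for m in per_patient),
        pooled_fn=sum(m.fn for m in per_patient),
        pooled_tn=sum(m.tn for m in per_patient),
        pooled_fp=sum(m.fp for m in per_patient),
        n_patients=len(per_patient),
    )


def pooled_rates(metrics: CohortMetrics) -> tuple[float, float, float]:
    """Pooled-count S/E/A — reported for contrast with the patient-wise means."""
    s = metrics.pooled_tp / (metrics.pooled_tp + metrics.pooled_fn)
    e = metrics.pooled_tn / (metrics.pooled_tn + metrics.pooled_fp)
    n = metrics.pooled_tp + metrics.pooled_fn + metrics.pooled_tn + metrics.pooled_fp
    a = (metrics.pooled_tp + metrics.pooled_tn) / n
    return s, e, a


@dataclass
class LopoResult:
    technique: str
    per_patient: list[PatientMetrics]
    cohort: CohortMetrics
    chosen_params: dict
    selected_features: list[str]
    provenance: list[dict] = field(default_factory=list)


def _units_frame_for(
    cohort: list[PatientRecord],
    extractor: FeatureExtractor,
    pca_eval_ids: list[str],
    use_covariates: bool,
) -> pd.DataFrame:
    pca = extractor.fit_pca(pca_eval_ids)
    units = []
    for patient in cohort:
        feats = {
            ev.visit: extractor.features(ev.eval_id, pca)
            for ev in patient.evaluations
        }
        if len(feats) >= 2:
            units.extend(build_units(patient, feats))
    frame = units_to_frame(units)
    if use_covariates:
        frame = augment_covariates(frame, cohort)
    return frame


def lopo_evaluate(
    cohort: list[PatientRecord],
    techniques: list[str],
    *,
    seed: int = 0,
    selected_features: list[str] | None = None,
    refit_pca: bool = True,
    nested: bool = False,
    use_covariates: bool = False,
    top_k: int = 10,
    k: int = 5,
    grids: dict[str, list[dict]] | None = None,
) -> dict[str, LopoResult]:
    """Leave-one-patient-out validation of one or more techniques.

    Feature selection and (unless ``nested``) hyperparameter tuning are
    performed once on all units, mirroring the study's procedure; the
    spectral PCA bases and the scaler are refitted per fold on the training
    patients only (``refit_pca=False`` reuses the all-data PCA, the study's
    apparent — leakage-prone — convention).  ``nested`` re-runs the grid
    search inside each fold's training set.
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-patient-out needs at least 3 patients")
    all_eval_ids = [ev.eval_id for p in cohort for ev in p.evaluations]
    extractor = FeatureExtractor([ev for p in cohort for ev in p.evaluations])

    full_frame = _units_frame_for(cohort, extractor, all_eval_ids, use_covariates)
    if selected_features is None:
        selected_features = select_features(full_frame, top_k=top_k, seed=seed).selected
    missing = [f for f in selected_features if f not in full_frame.columns]
    if missing:
        raise ValueError(f"selected features not present in units: {missing}")

    y_all = full_frame["label"].to_numpy()
    g_all = full_frame["patient_id"].to_numpy()

    specs: dict[str, ModelSpec] = {}
    for technique in techniques:
        spec = ModelSpec(technique=technique, seed=seed)
        if grids and technique in grids:
            spec.grid = grids[technique]
        if not nested:
            chosen, _ = grid_search(
                full_frame[selected_features], y_all, g_all, spec, k=k, seed=seed
            )
            spec.chosen = chosen
        specs[technique] = spec

    results = {
        t: LopoResult(
            technique=t,
            per_patient=[],
            cohort=None,  # filled below
            chosen_params=specs[t].chosen or {},
            selected_features=list(selected_features),
        )
        for t in techniques
    }

    for held_out in cohort:
        train_patients = [p for p in cohort if p.patient_id != held_out.patient_id]
        train_eval_ids = [ev.eval_id for p in train_patients for ev in p.evaluations]
        if refit_pca:
            frame = _units_frame_for(
                cohort, extractor, train_eval_ids, use_covariates
            )
        else:
            frame = full_frame
        is_held = frame["patient_id"] == held_out.patient_id
        train_frame = frame[~is_held]
        test_frame = frame[is_held]
        if test_frame.empty:
            continue
        y_train = train_frame["label"].to_numpy()
        if len(np.unique(y_train)) < 2:
            raise ValueError("a training fold contains a single class")
        X_train = train_frame[selected_features]
        X_test = test_frame[selected_features]
        scaler = fit_scaler(X_train)
        Xs_train = scaler.transform(X_train)
        Xs_test = scaler.transform(X_test)
        for technique in techniques:
            spec = specs[technique]
            if nested:
                chosen, _ = grid_search(
                    X_train,
                    y_train,
                    train_frame["patient_id"].to_numpy(),
                    spec,
                    k=k,
                    seed=seed,
                )
            else:
                chosen = spec.chosen
            model = make_estimator(technique, chosen, seed=seed)
            model.fit(Xs_train, y_train)
            preds = model.predict(Xs_test).astype(int)
            pm = PatientMetrics(patient_id=held_out.patient_id)
            for pred, label in zip(preds, test_frame["label"]):
                outcome = classify_outcome(int(pred), int(label))
                setattr(pm, outcome.lower(), getattr(pm, outcome.lower()) + 1)
            results[technique].per_patient.append(pm)
            results[technique].provenance.append(
                {
                    "held_out": held_out.patient_id,
                    "train_patients": [p.patient_id for p in train_patients],
                    "n_train_units": int(len(train_frame)),
                    "scaler_rows": list(scaler.fitted_rows),
                    "params": chosen,
                }
            )
        logger.debug(
            "fold %s: %d train units / %d test units",
            held_out.patient_id,
            len(train_frame),
            len(test_frame),
        )

    for technique in techniques:
        results[technique].cohort = aggregate(results[technique].per_patient)
    return results


def report(results: dict[str, LopoResult]) -> pd.DataFrame:
    """One row per technique: pooled confusion totals and mean S/E/A in
    percent (1 decimal), sorted by descending mean accuracy."""
    rows = []
    for technique, res in results.items():
        c = res.cohort
        rows.append(
            {
                "technique": technique,
                "true_positive": c.pooled_tp,
                "false_negative": c.pooled_fn,
                "true_negative": c.pooled_tn,
                "false_positive": c.pooled_fp,
                "sensitivity": round(100 * c.mean_sensitivity, 1),
                "specificity": round(100 * c.mean_specificity, 1),
                "accuracy": round(100 * c.mean_accuracy, 1),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values("accuracy", ascending=False, kind="stable").reset_index(
        drop=True
    )


def chance_band(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    clusters: np.ndarray | None = None,
    alpha_z: float = 1.96,
) -> tuple[float, float]:
    """95% band for the accuracy expected when predictions are independent of
    labels: p_e = q*p1 + (1-q)*p0 with q the positive-prediction rate.

    Comparative units are not independent trials — every A->B unit has its
    exact negation B->A within the same patient, and units sharing an
    evaluation share its feature noise — so with ``clusters`` (patient ids)
    the standard error is cluster-robust (summed per-cluster deviations of
    correct counts); without it the plain binomial SE is used.  An accuracy
    above the band indicates real association with the labels; below it,
    inverted association.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = y_true.size
    p1 = y_true.mean()
    q = y_pred.mean()
    p_e = q * p1 + (1 - q) * (1 - p1)
    if clusters is None:
        se = np.sqrt(p_e * (1 - p_e) / n)
    else:
        clusters = np.asarray(clusters)
        correct = (y_true == y_pred).astype(float)
        dev_sq = 0.0
        for c in np.unique(clusters):
            inside = clusters == c
            dev_sq += (correct[inside].sum() - p_e * inside.sum()) ** 2
        se = np.sqrt(dev_sq) / n
    half = alpha_z * se
    return float(p_e - half), float(p_e + half)


def chance_band_from_metrics(
    per_patient: list[PatientMetrics], alpha_z: float = 1.96
) -> tuple[float, float, float]:
    """(pooled accuracy, band low, band high) with patients as the clusters.

    Equivalent to :func:`chance_band` with patient-id clusters: the per-cluster
    correct count is TP+TN and only counts enter the statistic.
    """
    n = sum(m.total for m in per_patient)
    p1 = sum(m.tp + m.fn for m in per_patient) / n
    q = sum(m.tp + m.fp for m in per_patient) / n
    p_e = q * p1 + (1 - q) * (1 - p1)
    dev_sq = sum(((m.tp + m.tn) - p_e * m.total) ** 2 for m in per_patient)
    se = np.sqrt(dev_sq) / n
    acc = sum(m.tp + m.tn for m in per_patient) / n
    return float(acc), float(p_e - alpha_z * se), float(p_e + alpha_z * se)
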