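"""Phase splitting, loss-rate exclusion filters, and the standardized HR-Ox
difference signal.

The filters reproduce the study's inclusion rules: an evaluation is excluded
when its missing-sample loss rate exceeds 10% (strictly) in any phase of any
signal; home evaluations (V2, V3) are excluded when the patient's dyspnea did
not improve by at least one mMRC point relative to the decompensated visit
(V1); and patients are removed entirely when they are left without a valid V1
or without any valid home evaluation (either case makes the downstream
labeled comparisons one-sided).  No imputation is performed anywhere:
temporal statistics use observed samples only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .records import EvaluationRecord, PatientRecord, PhaseSignal

#: Strict exclusion threshold: "greater than 10%" — exactly 0.10 is retained.
LOSS_RATE_THRESHOLD = 0.10
#: Required dyspnea improvement (mMRC points) at home visits.
MIN_MMRC_IMPROVEMENT = 1


def split_phases(evaluation: EvaluationRecord) -> tuple[PhaseSignal, PhaseSignal, PhaseSignal, PhaseSignal]:
    """Split a recording into (HR walk, HR recovery, Ox walk, Ox recovery).

    The walk covers samples [0, walk_duration); recovery covers the following
    ``recovery_duration`` samples.  Raises ``ValueError`` when the phase
    boundary falls outside the recording.
    """
    wd = evaluation.walk_duration
    rd = evaluation.recovery_duration
    n = evaluation.hr.size
    if wd <= 0 or wd + rd > n:
        raise ValueError(
            f"phase boundary outside recording: walk={wd}, recovery={rd}, length={n}"
        )
    w, r = slice(0, wd), slice(wd, wd + rd)
    return (
        PhaseSignal("HR", "walk", evaluation.hr[w], evaluation.hr_mask[w]),
        PhaseSignal("HR", "recovery", evaluation.hr[r], evaluation.hr_mask[r]),
        PhaseSignal("Ox", "walk", evaluation.spo2[w], evaluation.spo2_mask[w]),
        PhaseSignal("Ox", "recovery", evaluation.spo2[r], evaluation.spo2_mask[r]),
    )


def loss_rate(signal: PhaseSignal) -> float:
    """Missing measures divided by the total number of measures."""
    if len(signal) == 0:
        raise ValueError("loss rate undefined for an empty signal")
    return signal.n_missing / len(signal)


@dataclass
class Exclusion:
    patient_id: str
    visit: str  # "*" for whole-patient removals
    rule: str
    detail: str


def _evaluation_loss_ok(ev: EvaluationRecord, threshold: float) -> tuple[bool, str]:
    for sig in split_phases(ev):
        r = loss_rate(sig)
        if r > threshold:
            return False, f"{sig.kind} {sig.phase} loss rate {r:.4f} > {threshold}"
    return True, ""


def apply_filters(
    cohort: list[PatientRecord], loss_threshold: float = LOSS_RATE_THRESHOLD
) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Apply the exclusion rules; returns the filtered cohort and a log.

    Rules, in order: (1) drop evaluations whose loss rate exceeds
    ``loss_threshold`` in any phase of HR or Ox; (2) drop home evaluations
    without a >= 1 point mMRC improvement over V1; (3) drop patients without a
    valid V1 or without any valid home evaluation.  The operation is
    idempotent.
    """
    filtered: list[PatientRecord] = []
    log: list[Exclusion] = []
    for patient in cohort:
        v1_mmrc = None
        for ev in patient.evaluations:
            if ev.visit == "V1":
                v1_mmrc = ev.mmrc
        kept: list[EvaluationRecord] = []
        for ev in patient.evaluations:
            ok, detail = _evaluation_loss_ok(ev, loss_threshold)
            if not ok:
                log.append(Exclusion(patient.patient_id, ev.visit, "loss_rate", detail))
                continue
            if ev.visit != "V1" and v1_mmrc is not None:
                if v1_mmrc - ev.mmrc < MIN_MMRC_IMPROVEMENT:
                    log.append(
                        Exclusion(
                            patient.patient_id,
                            ev.visit,
                            "mmrc_no_improvement",
                            f"mMRC V1={v1_mmrc}, {ev.visit}={ev.mmrc}",
                        )
                    )
                    continue
            kept.append(ev)
        has_v1 = any(e.visit == "V1" for e in kept)
        has_home = any(e.visit != "V1" for e in kept)
        if not has_v1:
            log.append(
                Exclusion(patient.patient_id, "*", "no_valid_v1", "no valid decompensated evaluation")
            )
            continue
        if not has_home:
            log.append(
                Exclusion(patient.patient_id, "*", "no_home_visit", "no valid home evaluation")
            )
            continue
        filtered.append(replace(patient, evaluations=kept))
    return filtered, log


def write_exclusion_log(log: list[Exclusion], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "visit", "rule", "detail"])
        for e in log:
            w.writerow([e.patient_id, e.visit, e.rule, e.detail])


# ---------------------------------------------------------------------------
# Standardized HR - Ox difference
# ---------------------------------------------------------------------------

def _loc_scale(values: np.ndarray) -> tuple[float, float, bool]:
    """Mean and population standard deviation; flags zero dispersion."""
    mu = float(values.mean())
    sd = float(values.std(ddof=0))
    if sd <= 1e-12:
        return mu, 1.0, True
    return mu, sd, False


def standardized_difference(
    hr: PhaseSignal,
    ox: PhaseSignal,
    hr_stats: tuple[float, float] | None = None,
    ox_stats: tuple[float, float] | None = None,
) -> PhaseSignal:
    """Pointwise difference of z-scored HR and Ox for one phase.

    Each input is standardized to zero mean and unit (population) dispersion.
    The statistics default to this phase's observed samples; pass ``*_stats``
    fitted on the evaluation's concatenated walk+recovery samples to obtain
    the evaluation-scoped convention used by the pipeline.  Zero dispersion in
    either input yields an all-zero difference flagged ``degenerate``.
    """
    if hr.phase != ox.phase or len(hr) != len(ox):
        raise ValueError("hr and ox must share phase and length")
    degenerate = False
    if hr_stats is None:
        mu_h, sd_h, d = _loc_scale(hr.unmasked)
        degenerate |= d
    else:
        mu_h, sd_h = hr_stats
        degenerate |= sd_h <= 1e-12
        sd_h = sd_h if sd_h > 1e-12 else 1.0
    if ox_stats is None:
        mu_o, sd_o, d = _loc_scale(ox.unmasked)
        degenerate |= d
    else:
        mu_o, sd_o = ox_stats
        degenerate |= sd_o <= 1e-12
        sd_o = sd_o if sd_o > 1e-12 else 1.0
    mask = hr.missing_mask | ox.missing_mask
    if degenerate:
        diff = np.zeros(len(hr))
    else:
        diff = (hr.samples - mu_h) / sd_h - (ox.samples - mu_o) / sd_o
        diff = np.where(mask, 0.0, diff)
    return PhaseSignal("HRminusOx", hr.phase, diff, mask, degenerate=degenerate)


def evaluation_phase_signals(
    evaluation: EvaluationRecord,
) -> dict[tuple[str, str], PhaseSignal]:
    """All six (signal, phase) vectors of one evaluation.

    The HR-Ox standardization is fitted per evaluation over the concatenated
    walk+recovery observed samples, so the phase means of the difference stay
    informative (a per-phase fit would force them to zero).
    """
    hr_w, hr_r, ox_w, ox_r = split_phases(evaluation)
    hr_all = np.concatenate([hr_w.unmasked, hr_r.unmasked])
    ox_all = np.concatenate([ox_w.unmasked, ox_r.unmasked])
    mu_h, sd_h, dh = _loc_scale(hr_all)
    mu_o, sd_o, do = _loc_scale(ox_all)
    hr_stats = (mu_h, 0.0 if dh else sd_h)
    ox_stats = (mu_o, 0.0 if do else sd_o)
    diff_w = standardized_difference(hr_w, ox_w, hr_stats, ox_stats)
    diff_r = standardized_difference(hr_r, ox_r, hr_stats, ox_stats)
    return {
        ("HR", "walk"): hr_w,
        ("HR", "recovery"): hr_r,
        ("Ox", "walk"): ox_w,
        ("Ox", "recovery"): ox_r,
        ("HRminusOx", "walk"): diff_w,
        ("HRminusOx", "recovery"): diff_r,
    }
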