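"""Synthetic cohort generator for the walk-test decompensation pipeline.

Emulates the statistical structure the pipeline consumes: 1 Hz HR/SpO2
recordings over a walk (<= 6 min) + recovery (4 min) protocol, three visits
per patient (V1 decompensated in hospital, V2/V3 compensated at home),
decompensation effects of the magnitudes reported for these diseases (HR
raised by 5-7 bpm, SpO2 lowered by 1-2 percentage points, slowed HR recovery),
contiguous sensor-dropout gaps, and mMRC dyspnea scores that improve by at
least one point at home unless filter-violating patients are requested.

Signal model (per evaluation, time t in seconds):

    HR(t)   = baseline + day_jitter + shift*decomp + rise(t) + resp_osc(t) + noise
    SpO2(t) = baseline + day_jitter - drop*decomp - effort_dip(t) + osc(t) + noise

where ``rise`` is a logistic ramp toward the exercise plateau during the walk
and an exponential decay back to rest during recovery (slower time constant
when decompensated), ``resp_osc`` is a patient-specific respiratory sinusoid,
and SpO2 is clipped to [70, 100].  Patient-level traits (baselines, oscillation
amplitude/frequency/phase, rise amplitude, effect sizes) are drawn once per
patient so that, with noise and day-to-day jitter disabled, the planted V1-V2
differences are read back exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .records import (
    MAX_WALK_DURATION,
    RECOVERY_DURATION,
    EvaluationRecord,
    PatientRecord,
    PhaseSignal,
)

# Logistic exercise-onset ramp: midpoint and width (s) of the HR rise.
_RISE_MIDPOINT_S = 60.0
_RISE_WIDTH_S = 20.0
# Exponential time constant (s) of the effort-related SpO2 dip and its recovery.
_SPO2_DIP_TAU_S = 60.0

_Range = tuple[float, float]


def _as_range(value) -> _Range:
    """A scalar config value means a fixed draw; a pair means uniform in it."""
    if np.isscalar(value):
        return (float(value), float(value))
    lo, hi = value
    return (float(lo), float(hi))


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    Effect-size defaults follow the magnitudes reported in ambulatory
    monitoring of these diseases: an SpO2 decrease of 1-2 points and HR
    elevations of 5-7 bpm ahead of decompensation.  ``decomp_hr_shift`` and
    ``decomp_spo2_drop`` accept a scalar (fixed effect) or a (lo, hi) range
    sampled uniformly per patient.
    """

    n_patients: int = 60
    seed: int = 0
    # patient-trait distributions
    age_mean: float = 75.0
    age_sd: float = 9.0
    hr_walk_baseline_mean: float = 75.0
    hr_walk_baseline_sd: float = 8.0
    spo2_baseline_mean: float = 96.0
    spo2_baseline_sd: float = 1.2
    disease_mix: tuple[float, float, float] = (0.37, 0.42, 0.21)  # HF, COPD, both
    p_male: float = 0.6
    # planted decompensation effects
    decomp_hr_shift: float | _Range = (5.0, 7.0)
    decomp_spo2_drop: float | _Range = (1.0, 2.0)
    recovery_tau_compensated: float = 45.0
    recovery_tau_decompensated: float = 80.0
    # within-walk dynamics
    hr_rise_amp_range: _Range = (20.0, 35.0)
    spo2_dip_amp_range: _Range = (1.0, 3.0)
    resp_oscillation_amp_range: _Range = (0.5, 2.0)  # bpm
    resp_oscillation_freq_range: _Range = (0.15, 0.35)  # Hz
    spo2_oscillation_amp_range: _Range = (0.2, 0.6)  # percent
    spo2_oscillation_freq_range: _Range = (0.05, 0.15)  # Hz
    # noise and visit-to-visit variation
    noise_sd_hr: float = 2.0
    noise_sd_spo2: float = 0.8
    hr_day_sd: float = 1.5
    spo2_day_sd: float = 0.4
    # dropout and protocol timing
    dropout_loss_rate_range: _Range = (0.0, 0.12)
    walk_duration_mean: float = 355.0
    walk_duration_sd: float = 20.0
    recovery_duration: int = RECOVERY_DURATION
    # visit structure
    p_missing_home_visit: float = 0.15
    p_mmrc_violation: float = 0.0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in (
            "age_sd",
            "hr_walk_baseline_sd",
            "spo2_baseline_sd",
            "noise_sd_hr",
            "noise_sd_spo2",
            "hr_day_sd",
            "spo2_day_sd",
            "walk_duration_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_missing_home_visit", "p_mmrc_violation", "p_male"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("decomp_hr_shift", "decomp_spo2_drop"):
            lo, hi = _as_range(getattr(self, name))
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a nonnegative value or range")
        lo, hi = _as_range(self.dropout_loss_rate_range)
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("dropout_loss_rate_range must lie in [0, 1)")
        if self.walk_duration_mean <= 0 or self.recovery_duration <= 0:
            raise ValueError("durations must be positive")
        if (
            self.recovery_tau_compensated <= 0
            or self.recovery_tau_decompensated <= 0
        ):
            raise ValueError("recovery time constants must be positive")
        mix = np.asarray(self.disease_mix, dtype=float)
        if mix.size != 3 or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ValueError("disease_mix must be 3 nonnegative proportions summing to 1")


def inject_dropout(
    signal: PhaseSignal, loss_rate: float, rng: np.random.Generator
) -> PhaseSignal:
    """Mask ``loss_rate`` of the samples as contiguous sensor-detachment runs.

    The masked count is ``round(loss_rate * len)``; values under the mask are
    kept unaltered (flagged missing, not imputed).  Gaps are 1-3 contiguous
    runs placed uniformly at random.
    """
    if not 0.0 <= loss_rate < 1.0:
        raise ValueError("loss_rate must be in [0, 1)")
    n = len(signal)
    target = int(round(loss_rate * n))
    mask = signal.missing_mask.copy()
    if target > 0:
        k = int(rng.integers(1, min(3, target) + 1))
        # split `target` masked samples into k runs (each >= 1) and distribute
        # the n-target observed samples into the k+1 surrounding segments
        cuts = np.sort(rng.choice(np.arange(1, target), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        run_lengths = np.diff(np.concatenate(([0], cuts, [target])))
        free = rng.multinomial(n - target, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for seg, run in zip(free[:-1], run_lengths):
            pos += int(seg)
            mask[pos : pos + int(run)] = True
            pos += int(run)
    return PhaseSignal(signal.kind, signal.phase, signal.samples.copy(), mask)


def _truncated_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def _uniform(rng, rng_pair: _Range) -> float:
    lo, hi = rng_pair
    return lo if lo == hi else float(rng.uniform(lo, hi))


def generate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` patients, each with a V1 evaluation and
    V2/V3 each independently missing with ``p_missing_home_visit`` (never both).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort: list[PatientRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        traits = _draw_patient_traits(rng, config)
        visits = ["V1"]
        drop_v2 = rng.random() < config.p_missing_home_visit
        drop_v3 = rng.random() < config.p_missing_home_visit
        if drop_v2 and drop_v3:  # never both home visits absent
            if rng.random() < 0.5:
                drop_v2 = False
            else:
                drop_v3 = False
        if not drop_v2:
            visits.append("V2")
        if not drop_v3:
            visits.append("V3")
        mmrc_v1 = int(rng.integers(2, 5))
        violator = rng.random() < config.p_mmrc_violation
        evaluations = []
        for visit in visits:
            if visit == "V1":
                mmrc = mmrc_v1
            elif violator:
                mmrc = mmrc_v1  # no dyspnea improvement at home
            else:
                mmrc = max(mmrc_v1 - int(rng.integers(1, 3)), 0)
            nyha = int(rng.integers(2, 5)) if visit == "V1" else int(rng.integers(1, 4))
            evaluations.append(
                _generate_evaluation(rng, config, pid, visit, traits, mmrc, nyha)
            )
        cohort.append(
            PatientRecord(
                patient_id=pid,
                age=traits["age"],
                sex=traits["sex"],
                disease=traits["disease"],
                evaluations=evaluations,
            )
        )
    return cohort


def _draw_patient_traits(rng: np.random.Generator, c: SimulationConfig) -> dict:
    disease = ("HF", "COPD", "both")[
        int(rng.choice(3, p=np.asarray(c.disease_mix, dtype=float)))
    ]
    return {
        "age": round(_truncated_normal(rng, c.age_mean, c.age_sd, 55, 97), 1),
        "sex": "male" if rng.random() < c.p_male else "female",
        "disease": disease,
        "hr_baseline": _truncated_normal(
            rng, c.hr_walk_baseline_mean, c.hr_walk_baseline_sd, 45, 110
        ),
        "spo2_baseline": _truncated_normal(
            rng, c.spo2_baseline_mean, c.spo2_baseline_sd, 88, 99
        ),
        "hr_shift": _uniform(rng, _as_range(c.decomp_hr_shift)),
        "spo2_drop": _uniform(rng, _as_range(c.decomp_spo2_drop)),
        "rise_amp": _uniform(rng, c.hr_rise_amp_range),
        "dip_amp": _uniform(rng, c.spo2_dip_amp_range),
        "resp_amp": _uniform(rng, c.resp_oscillation_amp_range),
        "resp_freq": _uniform(rng, c.resp_oscillation_freq_range),
        "resp_phase": float(rng.uniform(0, 2 * np.pi)),
        "spo2_osc_amp": _uniform(rng, c.spo2_oscillation_amp_range),
        "spo2_osc_freq": _uniform(rng, c.spo2_oscillation_freq_range),
        "spo2_osc_phase": float(rng.uniform(0, 2 * np.pi)),
    }


def _generate_evaluation(
    rng: np.random.Generator,
    c: SimulationConfig,
    pid: str,
    visit: str,
    tr: dict,
    mmrc: int,
    nyha: int,
) -> EvaluationRecord:
    decomp = visit == "V1"
    # walk duration drawn per evaluation, truncated to the protocol range
    wd = int(
        round(
            _truncated_normal(
                rng, c.walk_duration_mean, c.walk_duration_sd, 180, MAX_WALK_DURATION
            )
        )
    )
    rd = c.recovery_duration
    n = wd + rd
    t = np.arange(n, dtype=float)

    hr_day = rng.normal(0.0, c.hr_day_sd) if c.hr_day_sd > 0 else 0.0
    spo2_day = rng.normal(0.0, c.spo2_day_sd) if c.spo2_day_sd > 0 else 0.0

    hr_level = tr["hr_baseline"] + hr_day + (tr["hr_shift"] if decomp else 0.0)
    rise_walk = tr["rise_amp"] / (
        1.0 + np.exp(-(t[:wd] - _RISE_MIDPOINT_S) / _RISE_WIDTH_S)
    )
    tau = c.recovery_tau_decompensated if decomp else c.recovery_tau_compensated
    rise_end = tr["rise_amp"] / (
        1.0 + np.exp(-(wd - _RISE_MIDPOINT_S) / _RISE_WIDTH_S)
    )
    rise_rec = rise_end * np.exp(-(t[wd:] - wd) / tau)
    rise = np.concatenate([rise_walk, rise_rec])
    resp = tr["resp_amp"] * np.sin(2 * np.pi * tr["resp_freq"] * t + tr["resp_phase"])
    hr = hr_level + rise + resp
    if c.noise_sd_hr > 0:
        hr = hr + rng.normal(0.0, c.noise_sd_hr, size=n)

    spo2_level = tr["spo2_baseline"] + spo2_day - (tr["spo2_drop"] if decomp else 0.0)
    dip_walk = tr["dip_amp"] * (1.0 - np.exp(-t[:wd] / _SPO2_DIP_TAU_S))
    dip_end = tr["dip_amp"] * (1.0 - np.exp(-wd / _SPO2_DIP_TAU_S))
    dip_rec = dip_end * np.exp(-(t[wd:] - wd) / _SPO2_DIP_TAU_S)
    dip = np.concatenate([dip_walk, dip_rec])
    osc = tr["spo2_osc_amp"] * np.sin(
        2 * np.pi * tr["spo2_osc_freq"] * t + tr["spo2_osc_phase"]
    )
    spo2 = spo2_level - dip + osc
    if c.noise_sd_spo2 > 0:
        spo2 = spo2 + rng.normal(0.0, c.noise_sd_spo2, size=n)
    spo2 = np.clip(spo2, 70.0, 100.0)

    hr_mask = np.zeros(n, dtype=bool)
    spo2_mask = np.zeros(n, dtype=bool)
    lo, hi = _as_range(c.dropout_loss_rate_range)
    if hi > 0:
        # one dropout severity per evaluation (sensor-contact quality), with
        # independently placed contiguous gaps per signal and phase
        rate = _uniform(rng, (lo, hi)) if hi > lo else hi
        for mask, kind in ((hr_mask, "HR"), (spo2_mask, "Ox")):
            for phase, sl in (("walk", slice(0, wd)), ("recovery", slice(wd, n))):
                seg = PhaseSignal(kind, phase, np.zeros(sl.stop - sl.start), mask[sl])
                mask[sl] = inject_dropout(seg, rate, rng).missing_mask

    return EvaluationRecord(
        patient_id=pid,
        visit=visit,
        state="decompensated" if decomp else "compensated",
        hr=hr,
        spo2=spo2,
        hr_mask=hr_mask,
        spo2_mask=spo2_mask,
        mmrc=mmrc,
        nyha=nyha,
        walk_duration=wd,
        recovery_duration=rd,
    )


# ---------------------------------------------------------------------------
# CSV / JSON persistence: one CSV per evaluation plus a cohort manifest.
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[PatientRecord], out_dir: str | Path) -> Path:
    """Write one CSV per evaluation (t_seconds, phase, hr_bpm, spo2_pct with
    missing samples as empty fields) and a cohort-level JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    for patient in cohort:
        entry = {
            "patient_id": patient.patient_id,
            "age": patient.age,
            "sex": patient.sex,
            "disease": patient.disease,
            "evaluations": [],
        }
        for ev in patient.evaluations:
            fname = f"{ev.patient_id}_{ev.visit}.csv"
            with open(out / fname, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["t_seconds", "phase", "hr_bpm", "spo2_pct"])
                for i in range(ev.n_samples):
                    phase = "walk" if i < ev.walk_duration else "recovery"
                    hr = "" if ev.hr_mask[i] else f"{ev.hr[i]:.6f}"
                    ox = "" if ev.spo2_mask[i] else f"{ev.spo2[i]:.6f}"
                    w.writerow([i, phase, hr, ox])
            entry["evaluations"].append(
                {
                    "visit": ev.visit,
                    "state": ev.state,
                    "mmrc": ev.mmrc,
                    "nyha": ev.nyha,
                    "walk_duration": ev.walk_duration,
                    "recovery_duration": ev.recovery_duration,
                    "file": fname,
                }
            )
        manifest["patients"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out / "manifest.json"


def read_cohort(cohort_dir: str | Path) -> list[PatientRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    cohort = []
    for entry in manifest["patients"]:
        evaluations = []
        for meta in entry["evaluations"]:
            n = meta["walk_duration"] + meta["recovery_duration"]
            hr = np.zeros(n)
            spo2 = np.zeros(n)
            hr_mask = np.zeros(n, dtype=bool)
            spo2_mask = np.zeros(n, dtype=bool)
            with open(cohort_dir / meta["file"], newline="") as fh:
                reader = csv.DictReader(fh)
                for row in reader:
                    i = int(row["t_seconds"])
                    if row["hr_bpm"] == "":
                        hr_mask[i] = True
                    else:
                        hr[i] = float(row["hr_bpm"])
                    if row["spo2_pct"] == "":
                        spo2_mask[i] = True
                    else:
                        spo2[i] = float(row["spo2_pct"])
            evaluations.append(
                EvaluationRecord(
                    patient_id=entry["patient_id"],
                    visit=meta["visit"],
                    state=meta["state"],
                    hr=hr,
                    spo2=spo2,
                    hr_mask=hr_mask,
                    spo2_mask=spo2_mask,
                    mmrc=meta["mmrc"],
                    nyha=meta["nyha"],
                    walk_duration=meta["walk_duration"],
                    recovery_duration=meta["recovery_duration"],
                )
            )
        cohort.append(
            PatientRecord(
                patient_id=entry["patient_id"],
                age=entry["age"],
                sex=entry["sex"],
                disease=entry["disease"],
                evaluations=evaluations,
            )
        )
    return cohort
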