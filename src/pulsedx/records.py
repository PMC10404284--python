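"""Core record types shared across the pipeline.

A patient contributes up to three evaluations: V1 recorded in hospital during
the decompensated phase, V2 and V3 recorded at home after recovery
(compensated phase).  Each evaluation is a continuous 1 Hz pulse-oximeter
recording of heart rate (HR, bpm) and oxygen saturation (Ox / SpO2, %) over a
walk phase (<= 6 min) followed by a seated recovery phase (4 min), with a
boolean missing-sample mask for sensor-dropout sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VISITS = ("V1", "V2", "V3")
SIGNAL_KINDS = ("HR", "Ox", "HRminusOx")
PHASES = ("walk", "recovery")

#: Protocol constants: walking at a normal pace for at most 6 minutes, then
#: seated recovery for 4 minutes, both sampled at 1 Hz.
MAX_WALK_DURATION = 360
RECOVERY_DURATION = 240
SAMPLE_RATE_HZ = 1.0


@dataclass
class PhaseSignal:
    """One (signal kind, phase) sample vector at 1 Hz with a missing mask.

    ``missing_mask[i]`` is True where sample ``i`` was lost (sensor dropout);
    the stored value under a masked index is a placeholder and must not enter
    temporal statistics.  ``degenerate`` flags the zero-dispersion path of the
    standardized HR-Ox difference.
    """

    kind: str
    phase: str
    samples: np.ndarray
    missing_mask: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.samples.shape != self.missing_mask.shape or self.samples.ndim != 1:
            raise ValueError("samples and missing_mask must be 1-D and equal length")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def unmasked(self) -> np.ndarray:
        """Values of the observed (non-missing) samples, in time order."""
        return self.samples[~self.missing_mask]

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())


@dataclass
class EvaluationRecord:
    """A single visit's continuous two-phase recording plus metadata.

    ``hr``/``spo2`` hold the full walk+recovery series (length
    ``walk_duration + recovery_duration``); ``hr_mask``/``spo2_mask`` flag
    missing samples.  Dyspnea severity is recorded on the mMRC (0-4) and NYHA
    (1-4) ordinal scales; the mMRC score drives the compensated-phase
    inclusion filter downstream.
    """

    patient_id: str
    visit: str
    state: str  # "decompensated" | "compensated"
    hr: np.ndarray
    spo2: np.ndarray
    hr_mask: np.ndarray
    spo2_mask: np.ndarray
    mmrc: int
    nyha: int
    walk_duration: int
    recovery_duration: int = RECOVERY_DURATION

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.hr_mask = np.asarray(self.hr_mask, dtype=bool)
        self.spo2_mask = np.asarray(self.spo2_mask, dtype=bool)
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit {self.visit!r}")
        expected_state = "decompensated" if self.visit == "V1" else "compensated"
        if self.state != expected_state:
            raise ValueError(
                f"visit {self.visit} must be {expected_state}, got {self.state!r}"
            )
        if not (0 < self.walk_duration <= MAX_WALK_DURATION):
            raise ValueError(f"walk_duration must be in (0, {MAX_WALK_DURATION}]")
        n = self.walk_duration + self.recovery_duration
        for name in ("hr", "spo2", "hr_mask", "spo2_mask"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")

    @property
    def n_samples(self) -> int:
        return self.walk_duration + self.recovery_duration

    @property
    def eval_id(self) -> str:
        return f"{self.patient_id}:{self.visit}"


@dataclass
class PatientRecord:
    """A patient with metadata and their available evaluations."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    disease: str  # "HF" | "COPD" | "both"
    evaluations: list[EvaluationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        visits = [e.visit for e in self.evaluations]
        if len(set(visits)) != len(visits):
            raise ValueError("evaluations must carry distinct visits")

    @property
    def visits(self) -> list[str]:
        return [e.visit for e in self.evaluations]

    def evaluation(self, visit: str) -> EvaluationRecord:
        for e in self.evaluations:
            if e.visit == visit:
                return e
        raise KeyError(f"patient {self.patient_id} has no visit {visit}")
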