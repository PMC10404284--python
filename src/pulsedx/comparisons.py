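"""Labeled ordered-pair comparative units.

The classifier's input is the feature-vector difference between an ordered
pair of a patient's evaluations: delta = features(destination) −
features(origin).  A unit is labeled 1 ("change to decompensation") exactly
when the destination is the decompensated visit V1, and 0 ("no
decompensation") otherwise — so a full three-visit patient contributes six
units (V1→V2, V1→V3, V2→V1, V2→V3, V3→V1, V3→V2) with a 2:4 positive:negative
ratio, and a two-visit patient contributes two units at 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import pandas as pd

from .records import VISITS, PatientRecord


def label_pair(origin: str, destination: str) -> int:
    """1 iff the transition ends in the decompensated visit V1."""
    if origin not in VISITS or destination not in VISITS:
        raise ValueError(f"unknown visit in pair ({origin!r}, {destination!r})")
    if origin == destination:
        raise ValueError("origin and destination must differ")
    return 1 if destination == "V1" else 0


@dataclass
class ComparativeUnit:
    patient_id: str
    origin_visit: str
    destination_visit: str
    delta: pd.Series  # named feature differences
    label: int
    covariates: dict = field(default_factory=dict)

    @property
    def unit_id(self) -> str:
        return f"{self.patient_id}:{self.origin_visit}->{self.destination_visit}"


def build_units(
    patient: PatientRecord, features_by_visit: dict[str, dict[str, float]]
) -> list[ComparativeUnit]:
    """All ordered pairs of distinct feature-bearing visits of one patient."""
    visits = [v for v in VISITS if v in features_by_visit]
    if len(visits) < 2:
        raise ValueError(
            f"patient {patient.patient_id} has {len(visits)} feature-bearing "
            "evaluations; need at least 2"
        )
    covariates = {
        "age": patient.age,
        "sex": patient.sex,
        "disease": patient.disease,
    }
    units = []
    for origin, destination in permutations(visits, 2):
        fo = pd.Series(features_by_visit[origin], dtype=float)
        fd = pd.Series(features_by_visit[destination], dtype=float)
        units.append(
            ComparativeUnit(
                patient_id=patient.patient_id,
                origin_visit=origin,
                destination_visit=destination,
                delta=fd - fo,
                label=label_pair(origin, destination),
                covariates=covariates,
            )
        )
    return units


def units_to_frame(units: list[ComparativeUnit]) -> pd.DataFrame:
    """Tabular view: metadata columns followed by the delta feature columns."""
    rows = []
    for u in units:
        row = {
            "patient_id": u.patient_id,
            "origin": u.origin_visit,
            "destination": u.destination_visit,
            "label": u.label,
        }
        row.update(u.delta.to_dict())
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.index = [u.unit_id for u in units]
    return frame


META_COLUMNS = ["patient_id", "origin", "destination", "label"]


def feature_columns(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c not in META_COLUMNS]
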