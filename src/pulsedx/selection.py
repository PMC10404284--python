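"""Predictor selection via tree-ensemble importance rankings.

Three classifiers (random forest, gradient boosting, LightGBM) are each fitted
on the comparative units; the union of their top-k (default 10) features by
native impurity-based importance forms the candidate set, from which
near-constant features (variance below ``var_threshold``) and redundant
features (|Pearson r| above ``corr_threshold``; the member with the lower
summed importance is dropped) are pruned.  Patient age, sex, and baseline
disease can be added as competing candidate predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .comparisons import META_COLUMNS, feature_columns
from .records import PatientRecord

SELECTION_TECHNIQUES = ("random_forest", "gradient_boosting", "lgbm")

DEFAULT_TOP_K = 10
DEFAULT_CORR_THRESHOLD = 0.95
DEFAULT_VAR_THRESHOLD = 1e-8

#: Frozen preset of the 19 predictor names a user may want to reuse verbatim.
SELECTED_19_PRESET = (
    "meanHRWalk",
    "meanHRRecovery",
    "meanOxWalk",
    "meanOxRecovery",
    "meanHRminusOxWalk",
    "meanHRminusOxRecovery",
    "stdHRminusOxWalk",
    "stdOxRecovery",
    "stdOxWalk",
    "frecFirstArmHRRecovery",
    "frecSecArmHRminusOxWalk",
    "frecSecArmHRminusOxRecovery",
    "frecSecArmHRWalk",
    "seconArmOxWalk",
    "sumAllArmHRminusOxRecovery",
    "sumAllArmOxWalk",
    "PC6-HRminusOx-Walk",
    "PC2-Ox-Recovery",
    "PC4-Ox-Recovery",
)


def _make_ranker(technique: str, seed: int):
    if technique == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    if technique == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    if technique == "lgbm":
        return LGBMClassifier(
            n_estimators=200,
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            importance_type="gain",
        )
    raise ValueError(f"unknown selection technique {technique!r}")


def rank_importance(
    units_frame: pd.DataFrame, technique: str, seed: int = 0
) -> pd.DataFrame:
    """All features ranked by the fitted model's internal importance.

    Returns a DataFrame (feature, importance, rank) sorted by descending
    importance, ties broken by feature order for determinism.
    """
    cols = feature_columns(units_frame)
    if len(units_frame) < 20:
        raise ValueError("need at least 20 units to rank importances")
    if len(np.unique(units_frame["label"])) < 2:
        raise ValueError("both labels must be present")
    # canonical row order so bootstrap-based importances ignore input order
    keys = [units_frame[c].to_numpy(dtype=float) for c in reversed(cols)]
    keys.append(units_frame["label"].to_numpy())
    keys.append(pd.factorize(units_frame["patient_id"], sort=True)[0])
    order = np.lexsort(keys)
    y = units_frame["label"].to_numpy()[order]
    X = units_frame[cols].to_numpy(dtype=float)[order]
    model = _make_ranker(technique, seed)
    model.fit(X, y)
    imp = np.asarray(model.feature_importances_, dtype=float)
    order = np.lexsort((np.arange(len(cols)), -imp))
    table = pd.DataFrame(
        {
            "feature": [cols[i] for i in order],
            "importance": imp[order],
        }
    )
    table["rank"] = np.arange(1, len(cols) + 1)
    return table


@dataclass
class SelectionResult:
    tables: dict[str, pd.DataFrame]
    union: list[str]
    selected: list[str]
    prune_log: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "union": self.union,
            "selected": self.selected,
            "prune_log": self.prune_log,
            "rankings": {
                t: tbl.to_dict(orient="records") for t, tbl in self.tables.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def select_features(
    units_frame: pd.DataFrame,
    top_k: int = DEFAULT_TOP_K,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    seed: int = 0,
) -> SelectionResult:
    """Union of the three per-technique top-k lists, then redundancy pruning."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    tables = {
        technique: rank_importance(units_frame, technique, seed=seed)
        for technique in SELECTION_TECHNIQUES
    }
    all_features = feature_columns(units_frame)
    union = [
        f
        for f in all_features  # keep canonical order for determinism
        if any(f in set(tbl.head(top_k)["feature"]) for tbl in tables.values())
    ]
    summed = {f: 0.0 for f in all_features}
    for tbl in tables.values():
        for _, row in tbl.iterrows():
            summed[row["feature"]] += float(row["importance"])

    prune_log: list[dict] = []
    selected = list(union)

    # near-constant features
    variances = units_frame[selected].var(ddof=0)
    for f in list(selected):
        if variances[f] < var_threshold:
            selected.remove(f)
            prune_log.append(
                {"feature": f, "rule": "low_variance", "detail": f"var={variances[f]:.3e}"}
            )

    # redundant (highly correlated) pairs: keep the higher summed importance
    if len(selected) > 1:
        corr = units_frame[selected].corr().abs()
        dropped = set()
        for i, fi in enumerate(selected):
            if fi in dropped:
                continue
            for fj in selected[i + 1 :]:
                if fj in dropped:
                    continue
                r = corr.loc[fi, fj]
                if np.isfinite(r) and r > corr_threshold:
                    loser = fj if summed[fi] >= summed[fj] else fi
                    keeper = fi if loser == fj else fj
                    dropped.add(loser)
                    prune_log.append(
                        {
                            "feature": loser,
                            "rule": "redundant",
                            "detail": f"|r|={r:.4f} with {keeper}",
                        }
                    )
                    if loser == fi:
                        break
        selected = [f for f in selected if f not in dropped]

    return SelectionResult(tables=tables, union=union, selected=selected, prune_log=prune_log)


_DISEASE_CODE = {"HF": 0, "COPD": 1, "both": 2}


def augment_covariates(
    units_frame: pd.DataFrame,
    patients: list[PatientRecord],
    enabled: bool = True,
) -> pd.DataFrame:
    """Add age, a male-sex indicator, and a disease code as candidate columns."""
    if not enabled:
        return units_frame
    meta = {p.patient_id: p for p in patients}
    missing = set(units_frame["patient_id"]) - set(meta)
    if missing:
        raise ValueError(f"missing covariates for patients {sorted(missing)}")
    out = units_frame.copy()
    out["age"] = [meta[p].age for p in out["patient_id"]]
    out["sex_male"] = [1.0 if meta[p].sex == "male" else 0.0 for p in out["patient_id"]]
    out["disease_code"] = [float(_DISEASE_CODE[meta[p].disease]) for p in out["patient_id"]]
    return out
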