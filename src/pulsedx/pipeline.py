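"""End-to-end pipeline: simulate -> filter -> extract -> compare -> select ->
tune -> LOPO-evaluate, with a resolved config, manifest, and logs written next
to every run's outputs.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn(...)`` in the fixed stage order
(simulate, select, model), so individual stages can be rerun in isolation and
reruns with an identical resolved config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparisons import build_units, units_to_frame
from .evaluation import lopo_evaluate, pooled_rates, report
from .features import FeatureExtractor
from .modeling import TECHNIQUES
from .preprocessing import apply_filters, write_exclusion_log
from .records import PatientRecord
from .selection import SELECTED_19_PRESET, select_features
from .synthetic import SimulationConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger("pulsedx")

_STAGES = ("simulate", "select", "model")


@dataclass
class PipelineConfig:
    output_dir: str = "runs/latest"
    cohort_dir: str | None = None  # read an existing cohort instead of simulating
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    loss_threshold: float = 0.10
    top_k: int = 10
    corr_threshold: float = 0.95
    var_threshold: float = 1e-8
    use_covariates: bool = False
    techniques: tuple[str, ...] = TECHNIQUES
    nested: bool = False
    refit_pca: bool = True
    frozen_feature_preset: tuple[str, ...] | None = None
    cv_folds: int = 5
    seed: int = 7

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("simulation", {}) or {}).items()
        })
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(simulation=sim, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        })
        return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect invariant violations; an empty list means the config is valid."""
    violations = []
    try:
        config.simulation.validate()
    except ValueError as exc:
        violations.append(f"simulation: {exc}")
    if not 0.0 <= config.loss_threshold < 1.0:
        violations.append("loss_threshold: must be in [0, 1)")
    if config.top_k <= 0:
        violations.append("selection.top_k: must be positive")
    if not 0.0 < config.corr_threshold <= 1.0:
        violations.append("selection.corr_threshold: must be in (0, 1]")
    if config.var_threshold < 0:
        violations.append("selection.var_threshold: must be >= 0")
    if config.cv_folds < 2:
        violations.append("cv_folds: must be >= 2")
    unknown = [t for t in config.techniques if t not in TECHNIQUES]
    if unknown:
        violations.append(f"techniques: unknown {unknown}")
    if config.frozen_feature_preset is not None and not config.frozen_feature_preset:
        violations.append("frozen_feature_preset: must be a non-empty name list")
    return violations


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Outputs: ``cohort/`` (CSV per evaluation + manifest), ``exclusions.csv``,
    ``features.csv``, ``units.csv``, ``selection.json``, ``report.csv`` /
    ``report.json``, ``resolved_config.yaml``, ``run_manifest.json`` and
    ``run.log``.  Any stage failure aborts with the stage name in the error.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = stage_seeds(config.seed)
    try:
        config.to_yaml(out / "resolved_config.yaml")

        # -- stage: simulate (or load) ----------------------------------
        stage = "simulate"
        if config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
            logger.info("loaded %d patients from %s", len(cohort), config.cohort_dir)
        else:
            sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
            cohort = generate_cohort(sim)
            logger.info("simulated %d patients (seed %d)", len(cohort), sim.seed)
        write_cohort(cohort, out / "cohort")

        # -- stage: filter ----------------------------------------------
        stage = "filter"
        filtered, exclusions = apply_filters(cohort, config.loss_threshold)
        write_exclusion_log(exclusions, out / "exclusions.csv")
        logger.info(
            "filters: %d/%d patients retained, %d exclusions logged",
            len(filtered),
            len(cohort),
            len(exclusions),
        )

        # -- stage: features + units ------------------------------------
        stage = "features"
        evaluations = [ev for p in filtered for ev in p.evaluations]
        extractor = FeatureExtractor(evaluations)
        pca = extractor.fit_pca([ev.eval_id for ev in evaluations])
        rows = []
        units = []
        for patient in filtered:
            feats = {
                ev.visit: extractor.features(ev.eval_id, pca)
                for ev in patient.evaluations
            }
            for ev in patient.evaluations:
                rows.append(
                    {"patient_id": ev.patient_id, "visit": ev.visit, "state": ev.state}
                    | feats[ev.visit]
                )
            if len(feats) >= 2:
                units.extend(build_units(patient, feats))
        pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
        units_frame = units_to_frame(units)
        units_frame.to_csv(out / "units.csv", index=False)
        n_pos = int(units_frame["label"].sum())
        logger.info(
            "units: %d total (%d positive / %d negative)",
            len(units_frame),
            n_pos,
            len(units_frame) - n_pos,
        )

        # -- stage: select ----------------------------------------------
        stage = "select"
        if config.frozen_feature_preset is not None:
            selected = list(config.frozen_feature_preset)
            logger.info("selection skipped; frozen preset of %d features", len(selected))
            with open(out / "selection.json", "w") as fh:
                json.dump({"selected": selected, "preset": True}, fh, indent=2)
        else:
            result = select_features(
                units_frame,
                top_k=config.top_k,
                corr_threshold=config.corr_threshold,
                var_threshold=config.var_threshold,
                seed=seeds["select"],
            )
            selected = result.selected
            result.to_json(out / "selection.json")
            for technique, table in result.tables.items():
                table.to_csv(out / f"importances_{technique}.csv", index=False)
            logger.info(
                "selection: union %d -> selected %d features", len(result.union), len(selected)
            )

        # -- stage: evaluate --------------------------------------------
        stage = "evaluate"
        results = lopo_evaluate(
            filtered,
            list(config.techniques),
            seed=seeds["model"],
            selected_features=selected,
            refit_pca=config.refit_pca,
            nested=config.nested,
            use_covariates=config.use_covariates,
            top_k=config.top_k,
            k=config.cv_folds,
        )
        table = report(results)
        table.to_csv(out / "report.csv", index=False)
        payload = {}
        for technique, res in results.items():
            s_pool, e_pool, a_pool = pooled_rates(res.cohort)
            payload[technique] = {
                "mean_sensitivity_pct": 100 * res.cohort.mean_sensitivity,
                "mean_specificity_pct": 100 * res.cohort.mean_specificity,
                "mean_accuracy_pct": 100 * res.cohort.mean_accuracy,
                "pooled": {
                    "TP": res.cohort.pooled_tp,
                    "FN": res.cohort.pooled_fn,
                    "TN": res.cohort.pooled_tn,
                    "FP": res.cohort.pooled_fp,
                    "sensitivity_pct": 100 * s_pool,
                    "specificity_pct": 100 * e_pool,
                    "accuracy_pct": 100 * a_pool,
                },
                "chosen_params": res.chosen_params,
                "n_patients": res.cohort.n_patients,
            }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        logger.info("evaluated %d techniques over %d patients", len(results), len(filtered))

        # -- manifest ----------------------------------------------------
        artifacts = [
            "resolved_config.yaml",
            "exclusions.csv",
            "features.csv",
            "units.csv",
            "selection.json",
            "report.csv",
            "report.json",
        ]
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "n_patients_simulated": len(cohort),
            "n_patients_retained": len(filtered),
            "n_units": len(units_frame),
            "n_positive_units": n_pos,
            "selected_features": selected,
            "artifact_sha256": {a: _sha256(out / a) for a in artifacts},
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
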