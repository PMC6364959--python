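"""One-command orchestration of the five pipeline stages.

simulate -> phenotype -> cohort -> outcomes -> predict, with a
provenance manifest (config hash, seed, package version). Reruns with
the same config and seed are byte-identical; no timestamps are written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import painpheno
from painpheno.cohort.features import build_feature_vectors, load_manifest
from painpheno.cohort.groups import build_cohort
from painpheno.nlp.pipeline import run_phenotype, write_phenotype_outputs
from painpheno.outcomes import compute_outcomes, table3_report, table4_report
from painpheno.predict import nested_cv, rank_coefficients, run_comparators
from painpheno.synthetic_ehr import GeneratorConfig, generate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "cohort", "outcomes", "predict")
TIME_POINTS = ("discharge", "3wk", "8wk")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    """Flat run configuration (see ``data/default_config.yaml``)."""

    seed: int = 0
    out_dir: str = "run"
    generator: dict = field(default_factory=dict)
    nlp: dict = field(default_factory=dict)
    predict: dict = field(default_factory=lambda: {"grid": [[0.3, 0.05]], "k_outer": 10, "comparators": False})
    stages: tuple[str, ...] = STAGES
    lexicon_paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for key, path in self.lexicon_paths.items():
            if not Path(path).exists():
                raise ValueError(f"configured {key} lexicon path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canonical = json.dumps(
            {
                "seed": self.seed,
                "generator": self.generator,
                "nlp": self.nlp,
                "predict": self.predict,
                "stages": list(self.stages),
            },
            sort_keys=True,
        )
        return hashlib.sha256(canonical.encode()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


@_stage("simulate")
def _run_simulate(config: RunConfig, out: Path):
    gen_cfg = GeneratorConfig.from_dict({**config.generator, "seed": config.seed})
    extract = generate_cohort(gen_cfg)
    extract.write(out / "extract")
    log.info("simulate: %d patients, %d notes", len(extract.patients), len(extract.notes))
    return extract


@_stage("phenotype")
def _run_phenotype(config: RunConfig, out: Path, extract):
    from painpheno.nlp.lexicon import load_lexicon

    lexicon = (
        load_lexicon(config.lexicon_paths["depression"])
        if "depression" in config.lexicon_paths
        else None
    )
    ssri_lexicon = (
        load_lexicon(config.lexicon_paths["ssri"]) if "ssri" in config.lexicon_paths else None
    )
    surgery_dates = dict(
        zip(extract.encounters["patient_id"].astype(str), extract.encounters["surgery_date"])
    )
    outputs = run_phenotype(
        extract.notes,
        surgery_dates,
        lexicon=lexicon,
        ssri_lexicon=ssri_lexicon,
        **config.nlp,
    )
    write_phenotype_outputs(outputs, out / "nlp")
    return outputs


@_stage("cohort")
def _run_cohort(config: RunConfig, out: Path, extract, nlp_outputs):
    tables = {
        name: getattr(extract, name)
        for name in ("patients", "encounters", "diagnoses", "medications", "vitals", "pain")
    }
    cohort, attrition = build_cohort(tables, nlp_outputs["patient_flags"])
    cohort_dir = out / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(cohort_dir / "cohort.csv", index=False)
    attrition.to_csv(cohort_dir / "attrition_log.csv", index=False)
    features = build_feature_vectors(cohort, extract.medications)
    features.to_csv(cohort_dir / "features.csv")
    log.info("cohort: %d patients kept, %d dropped", len(cohort), len(attrition))
    return cohort, features


@_stage("outcomes")
def _run_outcomes(config: RunConfig, out: Path, extract, cohort):
    outcomes = compute_outcomes(cohort, extract.pain)
    out_dir = out / "outcomes"
    out_dir.mkdir(parents=True, exist_ok=True)
    outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    table3_report(outcomes, cohort).to_csv(out_dir / "table3_report.csv", index=False)
    table4_report(outcomes, cohort).to_csv(out_dir / "table4_report.csv", index=False)
    return outcomes


@_stage("predict")
def _run_predict(config: RunConfig, out: Path, features: pd.DataFrame, outcomes: pd.DataFrame):
    pred_dir = out / "predict"
    pred_dir.mkdir(parents=True, exist_ok=True)
    grid = tuple(tuple(g) for g in config.predict.get("grid", [[0.3, 0.05]]))
    k_outer = int(config.predict.get("k_outer", 10))
    names = load_manifest()
    X_all = features[list(names)].to_numpy(dtype=float)
    cv_payload, roc_frames, coef_frames = {}, [], []
    for tp in TIME_POINTS:
        delta = outcomes[f"delta_{tp}"].to_numpy(dtype=float)
        mask = ~np.isnan(delta)
        if mask.sum() < k_outer:
            log.warning("predict: %s skipped (only %d complete deltas)", tp, mask.sum())
            continue
        result = nested_cv(
            X_all[mask], delta[mask], grid=grid, k_outer=k_outer,
            seed=config.seed, time_point=tp, feature_names=names,
        )
        cv_payload[tp] = result.as_dict()
        for i, roc in enumerate(result.fold_rocs):
            roc_frames.append(
                pd.DataFrame({"time_point": tp, "fold": i, "fpr": roc[:, 0], "tpr": roc[:, 1]})
            )
        roc_frames.append(
            pd.DataFrame(
                {
                    "time_point": tp,
                    "fold": "mean",
                    "fpr": result.mean_roc_points[:, 0],
                    "tpr": result.mean_roc_points[:, 1],
                }
            )
        )
        ranked = rank_coefficients(result)
        ranked.insert(0, "time_point", tp)
        coef_frames.append(ranked)
        if config.predict.get("comparators", False):
            report = run_comparators(
                X_all[mask], delta[mask], k_outer=k_outer, seed=config.seed, elastic_grid=grid
            )
            report.insert(0, "time_point", tp)
            report.to_csv(pred_dir / f"table5_{tp}.csv", index=False)
    with open(pred_dir / "cv_results.json", "w", encoding="utf-8") as fh:
        json.dump(cv_payload, fh, indent=1, sort_keys=True)
    if roc_frames:
        pd.concat(roc_frames, ignore_index=True).to_csv(pred_dir / "roc_points.csv", index=False)
    if coef_frames:
        pd.concat(coef_frames, ignore_index=True).to_csv(
            pred_dir / "coefficients.csv", index=False
        )
    return cv_payload


def run_all(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    extract = nlp_outputs = cohort = features = outcomes = None
    if "simulate" in config.stages:
        extract = _run_simulate(config, out)
    if "phenotype" in config.stages:
        nlp_outputs = _run_phenotype(config, out, extract)
    if "cohort" in config.stages:
        cohort, features = _run_cohort(config, out, extract, nlp_outputs)
    if "outcomes" in config.stages:
        outcomes = _run_outcomes(config, out, extract, cohort)
    if "predict" in config.stages:
        # align outcomes to the feature matrix row order
        aligned = outcomes.set_index("patient_id").loc[features.index.astype(str)].reset_index()
        _run_predict(config, out, features, aligned)
    manifest = {
        "package_version": painpheno.__version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "stages": list(config.stages),
    }
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
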