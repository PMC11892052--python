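"""End-to-end orchestration: simulate/ingest -> classify -> aggregate -> estimate.

A single :class:`PipelineConfig` drives the full run.  Each stage writes its
outputs and QC reports under ``out_dir`` and logs record counts at stage
boundaries, so prevalence-table Ns can be audited from the logs alone.  A
``manifest.json`` records the config hash, seeds, package version, input
file checksums and the output inventory; deterministic stages reproduce
identical outputs under an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .aggregate import (DEFAULT_GROUPERS, median_split_compare,
                        prevalence_table, therapeutic_class_rates)
from .classify import classify_all, person_exposures
from .errors import ConfigError
from .inference import (DML_DEFAULT_SEED, ModelSpec, build_analysis_table,
                        fit_dml_plr, fit_lpm, fit_probit, summarize_models)
from .knowledge_base import (build_knowledge_base, read_concept_map,
                             read_concept_pairs, read_drugs,
                             write_knowledge_base)
from .simulate import GeneratorConfig, generate
from .survey import read_survey

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger("offlabel")


class DmlSettings(BaseModel):
    learner: str = "random_forest"
    n_folds: int = 5
    seed: int = DML_DEFAULT_SEED
    learner_params: dict[str, Any] = Field(default_factory=dict)


class PipelineConfig(BaseModel):
    """Either a simulation config or a map of input file paths, plus the
    analysis settings."""

    out_dir: str
    simulate: GeneratorConfig | None = None
    inputs: dict[str, str] = Field(default_factory=dict)
    seed: int | None = None
    current_only: bool = True
    groupers: tuple[str, ...] = DEFAULT_GROUPERS
    outcomes: tuple[str, ...] = ("ANYLMT",)
    estimators: tuple[str, ...] = ("lpm",)
    dml: DmlSettings = Field(default_factory=DmlSettings)

    def resolved_seed(self) -> int:
        if self.seed is not None:
            return self.seed
        return self.simulate.seed if self.simulate is not None else 0


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    started: str
    finished: str = ""
    input_checksums: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON pipeline config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.resolved_seed()
    config_hash = hashlib.sha256(
        config.model_dump_json().encode()).hexdigest()[:16]
    manifest = RunManifest(config_hash=config_hash, seed=seed,
                           package_version=__version__, started=_now())

    def record(path: Path) -> Path:
        manifest.outputs.append(str(path))
        return path

    # ---- stage 0: acquire inputs ------------------------------------------
    if config.simulate is not None:
        sim_cfg = config.simulate
        if config.seed is not None:
            sim_cfg = sim_cfg.model_copy(update={"seed": config.seed})
        log.info("simulate: n_persons=%d seed=%d", sim_cfg.n_persons, sim_cfg.seed)
        sim = generate(sim_cfg, out_dir=out / "data")
        kb, ds = sim.kb, sim.dataset
        manifest.outputs.extend(str(p) for p in sorted(map(str, sim.paths.values())))
    else:
        required = ("drugs", "concept_pairs", "concept_map", "persons",
                    "conditions", "prescriptions", "links")
        missing = [k for k in required if k not in config.inputs]
        if missing:
            raise ConfigError(f"inputs missing entries: {missing}")
        absent = {k: v for k, v in config.inputs.items()
                  if not Path(v).exists()}
        if absent:
            raise ConfigError(f"input files do not exist: {absent}")
        manifest.input_checksums = {k: _sha256(Path(v))
                                    for k, v in sorted(config.inputs.items())}
        kb = build_knowledge_base(read_drugs(config.inputs["drugs"]),
                                  read_concept_pairs(config.inputs["concept_pairs"]),
                                  read_concept_map(config.inputs["concept_map"]))
        ds = read_survey(config.inputs)
    write_knowledge_base(kb, record(out / "knowledge_base_pairs.csv"),
                         record(out / "knowledge_base_qc.json"))
    log.info("knowledge base: %d drugs, %d indication pairs, %d "
             "contraindication pairs", len(kb.drugs), kb.n_indication_pairs,
             kb.n_contraindication_pairs)
    log.info("survey: %d persons, %d conditions, %d prescriptions, %d links",
             len(ds.persons), len(ds.conditions), len(ds.prescriptions),
             len(ds.links))

    # ---- stage 1: classification ------------------------------------------
    cls, qc = classify_all(kb, ds, current_only=config.current_only)
    cls.to_csv(record(out / "classifications.csv"), index=False)
    record(out / "classification_qc.json").write_text(
        json.dumps(qc, indent=2, sort_keys=True))
    log.info("classify: %d prescriptions, %d in scope", qc["n_prescriptions"],
             qc["n_in_scope"])

    # ---- stage 2: person exposures ----------------------------------------
    expo = person_exposures(cls, ds, kb)
    expo.to_csv(record(out / "person_exposures.csv"), index=False,
                float_format="%.10g")
    log.info("exposures: %d person-years with >=1 in-scope prescription",
             len(expo))

    # ---- stage 3: aggregation ---------------------------------------------
    prev = prevalence_table(cls, ds, groupers=config.groupers, kb=kb)
    prev.round(2).to_csv(record(out / "prevalence.csv"), index=False)
    classes = therapeutic_class_rates(cls, ds)
    classes.round(2).to_csv(record(out / "therapeutic_class_rates.csv"),
                            index=False)
    comparisons = pd.concat([
        median_split_compare(expo, ds.persons, split_var=v)
        for v in ("frac_indicated", "frac_contraindicated")
    ], ignore_index=True)
    comparisons.to_csv(record(out / "median_split_comparisons.csv"),
                       index=False, float_format="%.6g")
    log.info("aggregate: %d prevalence rows, %d classes, %d comparisons",
             len(prev), len(classes), len(comparisons))

    # ---- stage 4: estimation ----------------------------------------------
    table = build_analysis_table(expo, ds, current_only=config.current_only)
    results = []
    for outcome in config.outcomes:
        spec = ModelSpec(outcome=outcome)
        for estimator in config.estimators:
            if estimator == "lpm":
                results.extend(fit_lpm(spec, table))
            elif estimator == "probit":
                results.extend(fit_probit(spec, table))
            elif estimator == "dml":
                results.extend(fit_dml_plr(
                    spec, table, learner=config.dml.learner,
                    n_folds=config.dml.n_folds, seed=config.dml.seed,
                    learner_params=config.dml.learner_params or None))
            else:
                raise ConfigError(f"unknown estimator {estimator!r}")
    if results:
        summary = summarize_models(results)
        summary.to_csv(record(out / "estimates.csv"), index=False,
                       float_format="%.6g")
        record(out / "estimates.json").write_text(json.dumps(
            {"config_hash": config_hash, "seed": seed,
             "n": int(summary["n"].iloc[0]),
             "results": [r.__dict__ for r in results]},
            indent=2, sort_keys=True))
        log.info("estimate: %d results across %d outcomes", len(results),
                 len(config.outcomes))

    manifest.record_counts = {
        "persons": int(len(ds.persons)),
        "conditions": int(len(ds.conditions)),
        "prescriptions": int(len(ds.prescriptions)),
        "links": int(len(ds.links)),
        "in_scope_prescriptions": int(qc["n_in_scope"]),
        "analysis_person_years": int(len(expo)),
    }
    manifest.finished = _now()
    manifest.write(out / "manifest.json")
    manifest.outputs.append(str(out / "manifest.json"))
    return manifest
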