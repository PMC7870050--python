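"""End-to-end orchestration: generate → screen → TWIST → validate → map.

One global seed deterministically derives per-stage seeds (via
``numpy.random.SeedSequence`` spawning), so a stage can be re-executed in
isolation from the manifest.  Every artifact is listed in the manifest with
its SHA-256 checksum; re-running the same config reproduces the checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autocm import plot_map
from .cohort import (CohortTable, OUTCOME_COLUMN, VARIABLE_NAMES,
                     default_generator_spec, generate_cohort, plausible_correlation)
from .correlation import pointbiserial_screen
from .gend import GenDParams
from .mlp import MLPConfig
from .model import FractureRiskModel, SemanticMap

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_cohort_csv"]

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("cohort", "screen", "twist", "validate", "map")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 1
    cohort_csv: str | None = None      # if None, generate synthetically
    n_records: int = 172
    correlated: bool = False           # use the plausible within-site preset
    gend: GenDParams = field(default_factory=GenDParams)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    autocm_C: float | None = None
    autocm_epochs: int = 50
    similarity: str = "autocm"
    max_extra: int = 6
    render_figure: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gend = GenDParams(**raw.pop("gend", {}))
        mlp = MLPConfig(**raw.pop("mlp", {}))
        return cls(gend=gend, mlp=mlp, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seeds: dict
    artifacts: dict = field(default_factory=dict)   # name -> {path, sha256}
    stages: dict = field(default_factory=dict)      # name -> "ok" | error text

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_STAGE_NAMES, children)}


def load_cohort_csv(path) -> CohortTable:
    """Read and validate a cohort CSV (13 variables + outcome column).

    Header matching is case-insensitive and whitespace-tolerant; the outcome
    column must be named ``further_fracture`` and contain only 0/1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    frame = pd.read_csv(path)
    canonical = {n.strip().lower(): n for n in (*VARIABLE_NAMES, OUTCOME_COLUMN)}
    rename = {}
    for col in frame.columns:
        key = str(col).strip().lower()
        if key in canonical:
            rename[col] = canonical[key]
    frame = frame.rename(columns=rename)
    missing = [n for n in (*VARIABLE_NAMES, OUTCOME_COLUMN) if n not in frame.columns]
    extra = [c for c in frame.columns if c not in (*VARIABLE_NAMES, OUTCOME_COLUMN)]
    if missing or extra:
        raise ValueError(
            f"cohort schema mismatch: missing columns {missing}, unexpected {extra}"
        )
    for col in (*VARIABLE_NAMES,):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"non-numeric value in column {col!r}, row {row}")
        frame[col] = vals
    table = CohortTable.from_frame(frame[list((*VARIABLE_NAMES, OUTCOME_COLUMN))])
    logger.info("loaded cohort: %d records, %d fractured / %d not",
                table.n, int(table.y.sum()), int((1 - table.y).sum()))
    return table


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages, writing every artifact plus a checksummed manifest.

    Raises the originating exception after recording the failed stage in the
    manifest (written to ``manifest.json`` regardless of outcome).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           stage_seeds=seeds)
    manifest_path = out / "manifest.json"

    def record(name: str, path: Path) -> None:
        manifest.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        # --- cohort -----------------------------------------------------
        if config.cohort_csv is not None:
            table = load_cohort_csv(config.cohort_csv)
        else:
            corr = plausible_correlation() if config.correlated else None
            spec = default_generator_spec(correlation=corr)
            table = generate_cohort(spec, config.n_records, seed=seeds["cohort"])
        cohort_path = out / "cohort.csv"
        table.to_csv(cohort_path)
        record("cohort", cohort_path)
        manifest.stages["cohort"] = "ok"

        # --- correlation screen ----------------------------------------
        screen = pointbiserial_screen(table)
        screen_path = out / "correlations.csv"
        screen.to_csv(screen_path, index=False)
        record("correlations", screen_path)
        manifest.stages["screen"] = "ok"

        # --- TWIST + A-B/B-A validation --------------------------------
        gend = GenDParams(**{**config.gend.__dict__, "seed": seeds["twist"]})
        mlp = MLPConfig(**{**config.mlp.__dict__, "seed": seeds["validate"]})
        model = FractureRiskModel(table, gend_params=gend, mlp_config=mlp)
        results = model.fit()
        twist_path = out / "twist.json"
        results.twist.to_json(twist_path)
        record("twist", twist_path)
        manifest.stages["twist"] = "ok"
        logger.info("TWIST fitness trace: %s",
                    np.round(results.twist.fitness_history, 4).tolist())

        report_csv = out / "validation_report.csv"
        results.report.to_frame().to_csv(report_csv, index=False)
        record("validation_report_csv", report_csv)
        report_json = out / "validation_report.json"
        with open(report_json, "w") as fh:
            json.dump(results.report.to_dict(), fh, indent=2)
        record("validation_report_json", report_json)
        manifest.stages["validate"] = "ok"

        # --- semantic map ----------------------------------------------
        smap = SemanticMap(table, similarity=config.similarity, C=config.autocm_C,
                           epochs=config.autocm_epochs, max_extra=config.max_extra)
        map_results = smap.fit()
        graphml_path = out / "map.graphml"
        map_results.graph.to_graphml(graphml_path)
        record("map_graphml", graphml_path)
        map_report_path = out / "map_report.json"
        with open(map_report_path, "w") as fh:
            json.dump(map_results.outcome_report(), fh, indent=2)
        record("map_report", map_report_path)
        if config.render_figure:
            fig_path = out / "map.png"
            plot_map(map_results.graph, fig_path)
            record("map_figure", fig_path)
        manifest.stages["map"] = "ok"
    except Exception as e:
        for name in _STAGE_NAMES:
            manifest.stages.setdefault(name, "not run")
        failed = next((n for n in _STAGE_NAMES if manifest.stages[n] != "ok"), "?")
        manifest.stages[failed] = f"failed: {e}"
        manifest.to_json(manifest_path)
        raise

    manifest.to_json(manifest_path)
    record("manifest", manifest_path)
    return manifest
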