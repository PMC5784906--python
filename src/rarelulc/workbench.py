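"""End-to-end orchestration: configuration, seeding and file conventions.

`run_pipeline` chains simulate -> preprocess -> diagnose -> classify ->
evaluate on a synthetic scene and writes all tabular artifacts as CSV
plus a JSON manifest (seeds, config hashes, class counts), so a run is
reproducible byte-for-byte from its configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classes import BANDS, CLASS_NAMES
from .diagnostics import class_entropy, jmd_matrix, mi_profile
from .evaluation import (
    confusion,
    macro_metrics,
    patch_density,
    purity_summary,
    summarize_runs,
)
from .experiment import ExperimentConfig, results_to_frame, run_all
from .modis_preprocess import FilterConfig, preprocess_scene
from .resampling import SCENARIOS, SmoteConfig
from .synthetic_scene import SceneConfig, generate_scene, write_scene

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    scenarios: tuple[str, ...] = SCENARIOS
    master_seed: int = 0
    profile: str = "reduced"

    def __post_init__(self) -> None:
        if self.master_seed < 0:
            raise ValueError("seed must be non-negative")


def _coerce(cls, d: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**d), sorted(known - set(d))


def validate_config(raw: dict) -> tuple[RunConfig, dict]:
    """Build a RunConfig from a plain dict (e.g. parsed YAML).

    Returns the config plus a report listing defaulted fields and the
    resolved scenario list.  Raises on unknown fields, invalid scenario
    ids or out-of-range values.
    """
    raw = dict(raw or {})
    report: dict = {"defaulted": {}}
    scene_d = raw.pop("scene", {})
    if "proportions" in scene_d:
        scene_d["proportions"] = dict(scene_d["proportions"])
    if "dates" in scene_d:
        scene_d["dates"] = tuple(scene_d["dates"])
    filter_d = raw.pop("filter", {})
    exp_d = raw.pop("experiment", {})
    if "mtry_grid" in exp_d:
        exp_d["mtry_grid"] = tuple(exp_d["mtry_grid"])
    if "scenarios" in exp_d:
        exp_d["scenarios"] = tuple(exp_d["scenarios"])
    if "smote" in exp_d:
        smote, defaulted = _coerce(SmoteConfig, dict(exp_d["smote"]))
        exp_d["smote"] = smote
        report["defaulted"]["smote"] = defaulted
    scenarios = tuple(raw.pop("scenarios", SCENARIOS))
    for s in scenarios:
        if s not in SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}; valid: {SCENARIOS}")
    reps = exp_d.get("reps")
    if reps is not None and reps < 1:
        raise ValueError("reps must be positive")
    scene, d1 = _coerce(SceneConfig, scene_d)
    filt, d2 = _coerce(FilterConfig, filter_d)
    exp, d3 = _coerce(ExperimentConfig, exp_d)
    report["defaulted"].update(scene=d1, filter=d2, experiment=d3)
    cfg = RunConfig(
        scene=scene, filter=filt, experiment=exp, scenarios=scenarios,
        master_seed=int(raw.pop("master_seed", 0)),
        profile=raw.pop("profile", "reduced"),
    )
    if raw:
        raise ValueError(f"unknown top-level fields: {sorted(raw)}")
    report["scenarios"] = scenarios
    return cfg, report


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg, _ = validate_config(raw)
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages and write artifacts + manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": cfg.master_seed,
        "config_hash": _config_hash(cfg),
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)

    try:
        stage("simulate")
        scene = generate_scene(cfg.scene, cfg.master_seed)
        write_scene(scene, out / "scene")

        stage("preprocess")
        features, report = preprocess_scene(scene, cfg.filter)
        features.to_csv(out / "features.csv", index=False)
        report.to_csv(out / "pixel_report.csv", index=False)
        X = features.drop(columns=["pixel_id", "label"]).to_numpy()
        y = features["label"].to_numpy()
        pixel_ids = features["pixel_id"].to_numpy()

        stage("diagnose")
        jmds = pd.concat([jmd_matrix(X, y, b) for b in BANDS], ignore_index=True)
        jmds.to_csv(out / "separability.csv", index=False)
        mi_profile(X, y).to_csv(out / "mutual_information.csv", index=False)

        stage("classify")
        exp_cfg = dataclasses.replace(cfg.experiment, scenarios=cfg.scenarios)
        results = run_all(X, y, exp_cfg, cfg.master_seed, pixel_ids)
        preds = pd.DataFrame(
            [
                (int(pid), res.rep, res.scenario, int(t), int(p))
                for res in results
                for pid, t, p in zip(pixel_ids, y, res.predicted)
            ],
            columns=["pixel_id", "rep", "scenario", "true", "predicted"],
        )
        preds.to_csv(out / "predictions.csv", index=False)
        manifest["tuned_mtry"] = {
            f"{r.scenario}_rep{r.rep}": r.mtry_per_fold for r in results
        }
        manifest["class_counts_after"] = {
            f"{r.scenario}_rep{r.rep}": r.audits[0]["class_counts_after"] for r in results
        }
        needs_audit = {"S3", "S4"} & set(cfg.scenarios)
        if needs_audit:
            audit_rows = []
            for res in results:
                for audit in res.audits:
                    for rep_ in audit.get("smote", []):
                        for d in rep_["draws"]:
                            audit_rows.append(
                                (res.scenario, res.rep, audit["fold"], rep_["class_name"],
                                 d.seed_index, d.neighbor_index, d.sl_i, d.sl_n,
                                 d.a, d.b, d.delta_raw, d.delta, d.outcome)
                            )
            pd.DataFrame(
                audit_rows,
                columns=["scenario", "rep", "fold", "class", "seed_index",
                         "neighbor_index", "sl_i", "sl_n", "a", "b",
                         "delta_raw", "delta", "outcome"],
            ).to_csv(out / "resampling_audit.csv", index=False)

        stage("evaluate")
        metrics = results_to_frame(results, y)
        metrics.to_csv(out / "metrics.csv", index=False)
        summarize_runs(metrics).to_csv(out / "summary.csv", index=False)
        overall = pd.DataFrame(
            [
                {"scenario": r.scenario, "rep": r.rep,
                 **macro_metrics(confusion(y, r.predicted))}
                for r in results
            ]
        )
        overall.to_csv(out / "overall_metrics.csv", index=False)
        patches = pd.DataFrame(
            [patch_density(scene.labels, cid) | {"class": CLASS_NAMES[cid]}
             for cid in range(len(CLASS_NAMES))]
        )
        patches.to_csv(out / "patch_density.csv", index=False)
        purity_summary(scene).to_csv(out / "purity.csv", index=False)
        manifest["class_entropy_bits"] = class_entropy(scene.class_counts())
        manifest["n_pixels_kept"] = int(len(features))
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
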