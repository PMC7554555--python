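"""Run configuration, artifact I/O, and the end-to-end pipeline.

A run executes simulate -> preprocess -> classify (all configured tasks) ->
variance -> report, writing each stage's artifacts before the next starts
and recording checksums in a manifest so deterministic stages are
re-verifiable from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, InsufficientDataError, KinemidError
from .preprocess import FeatureMatrix, PreprocessConfig, preprocess_dataset
from .classify import ClassificationTask, GridSearchSpec, TaskResult, chance_accuracy, run_task
from .synthetic import GeneratorParams, ProtocolSpec, generate_dataset, write_dataset
from .variability import GROUPINGS, compare_cv_groups, cv_by_grouping

logger = logging.getLogger("kinemid.pipeline")

CONFIG_VERSION = 1

_GROUPING_FOR_KIND = {
    "participant": "inter_individual",
    "block": "block",
    "set": "set",
    "block_within_set": "block_within_set",
}


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskSpec:
    kind: str
    intensity: str = "K80"
    leg: str = "left"
    subject: int | None = None

    def to_task(self) -> ClassificationTask:
        return ClassificationTask(self.kind, self.intensity, self.leg, self.subject)


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    protocol: ProtocolSpec = ProtocolSpec()
    generator: GeneratorParams = GeneratorParams()
    preprocess: PreprocessConfig = PreprocessConfig()
    grid: GridSearchSpec = GridSearchSpec()
    tasks: tuple[TaskSpec, ...] = (TaskSpec("participant"),)
    cv_groupings: tuple[str, ...] = GROUPINGS
    seed: int = 0
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {self.version}; expected {CONFIG_VERSION}")
        for g in self.cv_groupings:
            if g not in GROUPINGS:
                raise ConfigError(f"unknown cv grouping {g!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = [asdict(t) for t in self.tasks]
        return d

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_json_default)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {o!r}")


def _build_section(cls, data: dict, name: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    # YAML gives lists where the dataclasses want tuples
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except TypeError as e:
        raise ConfigError(f"bad section {name!r}: {e}") from e


def config_from_dict(data: dict) -> RunConfig:
    """Strict-schema construction: unknown keys anywhere are rejected."""
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    known = {"protocol", "generator", "preprocess", "grid", "tasks", "cv_groupings",
             "seed", "version"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "protocol" in data:
        kwargs["protocol"] = _build_section(ProtocolSpec, data["protocol"], "protocol")
    if "generator" in data:
        kwargs["generator"] = _build_section(GeneratorParams, data["generator"], "generator")
    if "preprocess" in data:
        kwargs["preprocess"] = _build_section(PreprocessConfig, data["preprocess"], "preprocess")
    if "grid" in data:
        kwargs["grid"] = _build_section(GridSearchSpec, data["grid"], "grid")
    if "tasks" in data:
        kwargs["tasks"] = tuple(_build_section(TaskSpec, t, "tasks[]") for t in data["tasks"])
    if "cv_groupings" in data:
        kwargs["cv_groupings"] = tuple(data["cv_groupings"])
    for key in ("seed", "version"):
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(json.loads(config.canonical_json()), sort_keys=True))


# ---------------------------------------------------------------------------
# Feature matrix artifacts
# ---------------------------------------------------------------------------

def save_features(fm: FeatureMatrix, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values_path = out / "features.npy"
    np.save(values_path, fm.values)
    labels_path = out / "labels.csv"
    fm.labels.to_csv(labels_path, index=False)
    meta_path = out / "features.json"
    meta_path.write_text(json.dumps({
        "n_grid": fm.n_grid, "state": fm.state,
        "registry_version": fm.registry_version,
        "shape": list(fm.values.shape),
    }, indent=2))
    return {"values": values_path, "labels": labels_path, "meta": meta_path}


def load_features(in_dir: str | Path) -> FeatureMatrix:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "features.json").read_text())
    if meta["state"] != "raw":
        raise ConfigError("stored features must be raw; normalization happens per fold")
    values = np.load(in_dir / "features.npy")
    labels = pd.read_csv(in_dir / "labels.csv")
    return FeatureMatrix(values=values, labels=labels, n_grid=meta["n_grid"])


# ---------------------------------------------------------------------------
# Result artifacts
# ---------------------------------------------------------------------------

def save_task_result(result: TaskResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    metrics = result.metrics_summary.copy()
    metrics.index.name = "stat"
    paths["metrics"] = out / "metrics.csv"
    metrics.to_csv(paths["metrics"])
    paths["fold_metrics"] = out / "fold_metrics.csv"
    result.fold_metrics.to_csv(paths["fold_metrics"], index_label="fold")
    cm = pd.DataFrame(result.confusion,
                      index=[f"true_{c}" for c in result.classes],
                      columns=[f"pred_{c}" for c in result.classes])
    paths["confusion"] = out / "confusion.tsv"
    cm.to_csv(paths["confusion"], sep="\t")
    if result.profile is not None:
        paths["distances"] = out / "distances.csv"
        result.profile.to_csv(paths["distances"], index=False)
    paths["run"] = out / "run.json"
    paths["run"].write_text(json.dumps({
        "task": asdict(result.task), "n_classes": result.n_classes,
        "chance_accuracy": chance_accuracy(result.n_classes),
        "fold_costs": result.fold_costs, "seed": result.seed,
    }, indent=2, default=_json_default))
    return paths


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (display convention)."""
    factor = 10 ** decimals
    return np.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def write_report(
    results: list[TaskResult], cv_tables: dict[str, pd.DataFrame], out_path: str | Path | None = None
) -> pd.DataFrame:
    """One row per task run: the four metrics (mean/SD), class count, chance
    baseline, and the matching grouping's CV mean/SD."""
    if not results:
        raise KinemidError("write_report needs at least one TaskResult")
    rows = []
    for r in results:
        grouping = _GROUPING_FOR_KIND[r.task.kind]
        cv_mean = cv_sd = float("nan")
        table = cv_tables.get(grouping)
        if table is not None and len(table):
            sel = table[(table["leg"] == r.task.leg)]
            if r.task.kind == "participant":
                sel = sel[sel["intensity"] == r.task.intensity]
            elif r.task.subject is not None:
                sel = sel[sel["subject"] == r.task.subject]
            if len(sel):
                cv_mean = float(sel["cv_percent"].mean())
                cv_sd = float(sel["cv_percent"].std(ddof=1)) if len(sel) > 1 else float("nan")
        row = {"task": r.task.kind, "intensity": r.task.intensity, "leg": r.task.leg,
               "subject": r.task.subject if r.task.subject is not None else ""}
        for metric in ("accuracy", "f1", "precision", "recall"):
            row[f"{metric}_mean"] = float(r.metrics_summary.loc["mean", metric])
            row[f"{metric}_sd"] = float(r.metrics_summary.loc["sd", metric])
        row["n_classes"] = r.n_classes
        row["chance_accuracy"] = round_half_up(chance_accuracy(r.n_classes), 1)
        row["cv_mean"] = cv_mean
        row["cv_sd"] = cv_sd
        rows.append(row)
    report = pd.DataFrame(rows)
    if out_path is not None:
        report.to_csv(out_path, index=False)
    return report


def regenerate_report(run_dir: str | Path, out_path: str | Path | None = None) -> pd.DataFrame:
    """Rebuild report.csv from the stored classify/variance artifacts.

    Deterministic: regeneration from unchanged artifacts is byte-identical
    to the original report.
    """
    run_dir = Path(run_dir)
    classify_dir = run_dir / "classify"
    if not classify_dir.is_dir():
        raise KinemidError(f"no classify artifacts under {run_dir}")
    rows = []
    for task_dir in sorted(classify_dir.iterdir()):
        run_meta = json.loads((task_dir / "run.json").read_text())
        metrics = pd.read_csv(task_dir / "metrics.csv", index_col="stat", float_precision="round_trip")
        task = run_meta["task"]
        grouping = _GROUPING_FOR_KIND[task["kind"]]
        cv_mean = cv_sd = float("nan")
        cv_path = run_dir / "variance" / f"cv_{grouping}.csv"
        if cv_path.exists():
            table = pd.read_csv(cv_path, float_precision="round_trip")
            sel = table[table["leg"] == task["leg"]]
            if task["kind"] == "participant":
                sel = sel[sel["intensity"] == task["intensity"]]
            elif task.get("subject") is not None:
                sel = sel[sel["subject"] == task["subject"]]
            if len(sel):
                cv_mean = float(sel["cv_percent"].mean())
                cv_sd = float(sel["cv_percent"].std(ddof=1)) if len(sel) > 1 else float("nan")
        row = {"task": task["kind"], "intensity": task["intensity"], "leg": task["leg"],
               "subject": task["subject"] if task.get("subject") is not None else ""}
        for metric in ("accuracy", "f1", "precision", "recall"):
            row[f"{metric}_mean"] = float(metrics.loc["mean", metric])
            row[f"{metric}_sd"] = float(metrics.loc["sd", metric])
        row["n_classes"] = int(run_meta["n_classes"])
        row["chance_accuracy"] = round_half_up(run_meta["chance_accuracy"], 1)
        row["cv_mean"] = cv_mean
        row["cv_sd"] = cv_sd
        rows.append(row)
    report = pd.DataFrame(rows)
    if out_path is not None:
        report.to_csv(out_path, index=False)
    return report


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_json_default)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _record_stage(manifest: RunManifest, name: str, outputs: dict[str, Path], t0: float) -> None:
    manifest.stages.append({
        "stage": name,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs.values()},
        "elapsed_s": round(time.time() - t0, 3),
    })


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute simulate -> preprocess -> classify -> variance -> report.

    Each stage's outputs are written before the next stage starts; a failing
    stage leaves a ``<stage>.partial`` marker and re-raises with the stage
    named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(),
                           package_version=__version__, seed=config.seed)
    save_config(config, out / "config.yaml")

    generator = dataclasses.replace(config.generator, seed=config.seed)
    stage = "simulate"
    try:
        t0 = time.time()
        dataset = generate_dataset(config.protocol, generator)
        paths = write_dataset(dataset, out / "dataset")
        _record_stage(manifest, stage, paths, t0)

        stage = "preprocess"
        t0 = time.time()
        features = preprocess_dataset(dataset, config.preprocess)
        paths = save_features(features, out / "features")
        _record_stage(manifest, stage, paths, t0)

        stage = "classify"
        t0 = time.time()
        results: list[TaskResult] = []
        classify_paths: dict[str, Path] = {}
        for i, spec in enumerate(config.tasks):
            task = spec.to_task()
            result = run_task(features, task, grid=config.grid,
                              normalize_scope=config.preprocess.normalize_scope,
                              blocks_per_set=config.protocol.blocks_per_set,
                              seed=config.seed)
            results.append(result)
            task_dir = out / "classify" / f"task_{i:02d}_{task.kind}_{task.intensity}_{task.leg}"
            classify_paths.update({f"{i}:{k}": p for k, p in save_task_result(result, task_dir).items()})
        _record_stage(manifest, stage, classify_paths, t0)

        stage = "variance"
        t0 = time.time()
        var_dir = out / "variance"
        var_dir.mkdir(parents=True, exist_ok=True)
        cv_tables: dict[str, pd.DataFrame] = {}
        var_paths: dict[str, Path] = {}
        for grouping in config.cv_groupings:
            table = cv_by_grouping(features, grouping)
            cv_tables[grouping] = table
            p = var_dir / f"cv_{grouping}.csv"
            table.to_csv(p, index=False)
            var_paths[grouping] = p
            if grouping != "inter_individual" and len(table):
                for leg in sorted(table["leg"].unique()):
                    sub = table[table["leg"] == leg]
                    try:
                        report = compare_cv_groups(sub, grouping)
                    except InsufficientDataError as e:
                        logger.warning("variance stats skipped for %s/%s: %s", grouping, leg, e)
                        continue
                    sp = var_dir / f"stats_{grouping}_{leg}.json"
                    sp.write_text(json.dumps({
                        "design": report.design, "route": report.route,
                        "n_subjects": report.n_subjects, "n_levels": report.n_levels,
                        "omnibus": report.omnibus,
                        "n_significant_posthoc": (int(report.posthoc["significant"].sum())
                                                  if report.posthoc is not None else 0),
                    }, indent=2, default=_json_default))
                    var_paths[f"stats_{grouping}_{leg}"] = sp
                    if report.posthoc is not None:
                        pp = var_dir / f"posthoc_{grouping}_{leg}.csv"
                        report.posthoc.to_csv(pp, index=False)
                        var_paths[f"posthoc_{grouping}_{leg}"] = pp
        _record_stage(manifest, stage, var_paths, t0)

        stage = "report"
        t0 = time.time()
        report_path = out / "report.csv"
        write_report(results, cv_tables, report_path)
        _record_stage(manifest, stage, {"report": report_path}, t0)
    except Exception:
        (out / f"{stage}.partial").touch()
        logger.error("pipeline failed during stage %r; partial outputs retained", stage)
        raise
    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline complete: %d stages, outputs in %s", len(manifest.stages), out)
    return manifest
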