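"""End-to-end orchestration: simulate/ingest -> features -> stats -> classify.

One YAML config drives every stage; all randomness funnels through a single
root seed so a run is reproducible from its manifest.  Outputs are CSV/JSON
only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .classify import assign_valence_labels, cross_validated_classify
from .dataset import (
    Dataset,
    LabelMergeSpec,
    build_dataset,
    impute_column_means,
    make_relative,
    merge_pad_labels,
    standardize,
)
from .features import FeatureConfig
from .keylog_io import read_event_log, write_event_log
from .segmentation import SegmentationConfig
from .stats import benjamini_hochberg, evaluate_features_paired, mutual_information
from .synthgen import EffectSpec, generate_study

logger = logging.getLogger("keydyn")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"n_users": 49, "n_keystrokes_mean": 250, "effect": {}},
    "segmentation": {"idle_threshold_ms": 3000, "gap_mode": "release_press"},
    "features": {"caps_mode": "capital_ratio", "speed_mode": "elapsed"},
    "dataset": {
        "variant": "relative",
        "scaled": False,
        "var_threshold": 1e-10,
        "corr_threshold": 0.95,
    },
    "stats": {"q": 0.05, "mi_neighbors": 3},
    "classify": {"task": "valence", "labeling": "L1", "model": "svm", "k_folds": 10},
}


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config: dict[str, Any]
    seed: int
    package_version: str
    input_hashes: dict[str, str]
    row_counts: dict[str, int]
    outputs: dict[str, str]
    stage_seconds: dict[str, float]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict[str, Any]:
    """Merge defaults <- YAML file <- explicit overrides (shallow per stage)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for source in (yaml.safe_load(Path(path).read_text()) if path else None, overrides):
        if not source:
            continue
        for key, val in source.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _feature_config(cfg: dict) -> FeatureConfig:
    return FeatureConfig(
        caps_mode=cfg["features"]["caps_mode"],
        speed_mode=cfg["features"]["speed_mode"],
        segmentation=SegmentationConfig(
            idle_threshold_ms=cfg["segmentation"]["idle_threshold_ms"],
            gap_mode=cfg["segmentation"]["gap_mode"],
        ),
    )


def _effect_spec(cfg: dict) -> EffectSpec:
    return EffectSpec(**cfg["simulate"].get("effect", {}))


def simulate_stage(cfg: dict, out_dir: Path, seed: int) -> list:
    sessions = generate_study(
        n_users=cfg["simulate"]["n_users"],
        effect=_effect_spec(cfg),
        seed=seed,
        n_keystrokes_mean=cfg["simulate"]["n_keystrokes_mean"],
    )
    raw = out_dir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        write_event_log(s, raw / f"{s.user_id}.csv", raw / f"{s.user_id}.json")
    return sessions


def ingest_stage(data_dir: str | Path) -> list:
    data_dir = Path(data_dir)
    sessions = []
    for csv_path in sorted(data_dir.glob("*.csv")):
        sidecar = csv_path.with_suffix(".json")
        sessions.append(read_event_log(csv_path, sidecar if sidecar.exists() else None))
    if not sessions:
        raise ValueError(f"no event logs found under {data_dir}")
    return sessions


def dataset_stage(cfg: dict, sessions: list) -> Dataset:
    dataset, baselines = build_dataset(sessions, _feature_config(cfg))
    if cfg["dataset"]["variant"] == "relative":
        dataset = make_relative(dataset, baselines)
    if cfg["dataset"]["scaled"]:
        dataset = standardize(dataset)
    return dataset


def stats_stage(cfg: dict, dataset: Dataset, out_dir: Path, seed: int) -> pd.DataFrame:
    q = cfg["stats"]["q"]
    results = evaluate_features_paired(dataset.X, dataset.meta)
    testable = results["p_value"].dropna()
    bh = benjamini_hochberg(testable.to_numpy(), q=q)
    selected = set(testable.index[bh.selected])
    results[f"bh_selected(q={q})"] = [f in selected for f in results.index]

    Xi, _ = impute_column_means(dataset.X)
    labels = assign_valence_labels(dataset)
    mi = mutual_information(Xi, labels, n_neighbors=cfg["stats"]["mi_neighbors"], seed=seed)
    results["mutual_information"] = mi.values

    results.to_csv(out_dir / "feature_stats.csv")
    return results


def classify_stage(cfg: dict, dataset: Dataset, out_dir: Path, seed: int) -> dict:
    task = cfg["classify"]["task"]
    if task == "valence":
        X, y = dataset.X, assign_valence_labels(dataset)
        average = "macro"
    elif task in ("pleasure", "arousal"):
        spec = LabelMergeSpec(procedure=cfg["classify"]["labeling"], dimension=task)
        labels, kept = merge_pad_labels(dataset.meta[task].to_numpy(), spec)
        X, y = dataset.X[kept].reset_index(drop=True), labels[kept]
        average = "weighted"
    else:
        raise ValueError(f"unknown task {task!r}")

    report = cross_validated_classify(
        X,
        y,
        model=cfg["classify"]["model"],
        k_folds=cfg["classify"]["k_folds"],
        seed=seed,
        scale=cfg["dataset"]["scaled"],
        var_threshold=cfg["dataset"]["var_threshold"],
        corr_threshold=cfg["dataset"]["corr_threshold"],
    )
    doc = report.to_dict()
    doc["task"] = task
    doc["reported_average"] = average
    (out_dir / "classification_report.json").write_text(json.dumps(doc, indent=1))
    pd.DataFrame(
        report.confusion, index=report.classes, columns=report.classes
    ).to_csv(out_dir / "confusion_matrix.csv")
    return doc


def run_pipeline(
    config: dict[str, Any] | str | Path,
    out_dir: str | Path,
    data_dir: str | Path | None = None,
) -> RunManifest:
    """Execute simulate/ingest -> featurize -> stats -> classify.

    With ``data_dir`` set, recorded sessions are ingested instead of
    simulated.  Returns (and writes) the run manifest.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else load_config(None, config)
    seed = int(cfg["seed"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    counts: dict[str, int] = {}
    stage_seconds: dict[str, float] = {}
    hashes: dict[str, str] = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        result = fn(*args)
        stage_seconds[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: %.3f s", name, stage_seconds[name])
        return result

    if data_dir is not None:
        for p in sorted(Path(data_dir).glob("*")):
            if p.is_file():
                hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        sessions = timed("ingest", ingest_stage, data_dir)
    else:
        sessions = timed("simulate", simulate_stage, cfg, out_dir, seed)
    counts["sessions"] = len(sessions)
    counts["events"] = int(sum(len(s.events) for s in sessions))

    dataset = timed("features", dataset_stage, cfg, sessions)
    counts["samples"] = dataset.n_samples
    counts["features"] = dataset.X.shape[1]
    features_csv = out_dir / "features.csv"
    pd.concat([dataset.meta, dataset.X], axis=1).to_csv(features_csv, index=False)

    stats_df = timed("stats", stats_stage, cfg, dataset, out_dir, seed)
    counts["features_tested"] = int(stats_df["p_value"].notna().sum())

    report = timed("classify", classify_stage, cfg, dataset, out_dir, seed)
    counts["classified"] = int(report["n"])

    manifest = RunManifest(
        config=cfg,
        seed=seed,
        package_version=__version__,
        input_hashes=hashes,
        row_counts=counts,
        outputs={
            "features": str(features_csv),
            "feature_stats": str(out_dir / "feature_stats.csv"),
            "classification_report": str(out_dir / "classification_report.json"),
            "confusion_matrix": str(out_dir / "confusion_matrix.csv"),
        },
        stage_seconds=stage_seconds,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
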