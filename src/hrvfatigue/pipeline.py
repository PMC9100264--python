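"""Pipeline configuration and stage orchestration.

One flat config object carries every tunable constant (sampling rate,
window length, band edges, selection thresholds, model settings, seeds);
its defaults are the pipeline's reference operating point. Every result
artifact embeds the exact config used, so reruns under the same config and
inputs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import selection as sel
from .features import FEATURE_NAMES, extract_feature_table
from .preprocess import NNSeries, StageLabel, load_nn, segment_nn

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sampling_rate: float = 200.0  # Hz
    window_s: float = 300.0  # 5-min analysis windows
    chunk_s: float = 60.0  # SDANN/SDNNi chunking
    histogram_bin_s: float = 1.0 / 128.0  # geometric-feature bins
    vlf_band: tuple = (0.0033, 0.04)  # Hz
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.4)
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    dfa_box_min: int = 4
    dfa_box_split: int = 16
    dfa_box_max: int = 64
    min_beats_per_segment: int = 100
    r1: float = 0.0  # null-importance score threshold (%)
    r2: float = 0.9  # redundancy correlation threshold
    n_permutations: int = 100  # label permutations T
    rf_params: dict = field(default_factory=dict)
    model: str = "gbt"
    model_params: dict = field(default_factory=dict)
    k_folds: int = 10
    seed: int = 7

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a flat TOML file."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_sessions(sessions_dir: str | Path):
    """Read the on-disk session layout written by the simulator/CLI:
    ``labels.csv`` plus one ``<session>.nn.csv`` per session."""
    sessions_dir = Path(sessions_dir)
    labels_path = sessions_dir / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"labels file not found: {labels_path}")
    lab = pd.read_csv(labels_path)
    out = []
    for (sid, ses), grp in lab.groupby(["subject_id", "session_id"], sort=True):
        nn_path = sessions_dir / f"{ses}.nn.csv"
        nn = load_nn(nn_path, subject_id=str(sid), session_id=str(ses))
        stage_labels = [
            StageLabel(stage=str(r.stage), start_s=float(r.start_s),
                       end_s=float(r.end_s),
                       rpe=None if pd.isna(r.rpe) else int(r.rpe))
            for r in grp.itertuples()]
        out.append((nn, stage_labels))
    return out


def save_sessions(sessions: dict, out_dir: str | Path) -> None:
    """Inverse of :func:`load_sessions` for simulator output."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (sid, ses), (nn, labels) in sorted(sessions.items()):
        nn.to_frame().to_csv(out_dir / f"{ses}.nn.csv", index=False)
        for lab in labels:
            rows.append(dict(subject_id=sid, session_id=ses, stage=lab.stage,
                             start_s=lab.start_s, end_s=lab.end_s,
                             rpe=lab.rpe))
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)


def extract_stage(sessions, config: PipelineConfig) -> pd.DataFrame:
    segments = []
    for nn, labels in sessions:
        segments.extend(segment_nn(nn, window_s=config.window_s,
                                   labels=labels,
                                   min_beats=config.min_beats_per_segment))
    return extract_feature_table(segments)


def select_stage(features: pd.DataFrame, config: PipelineConfig,
                 label_col: str = "class") -> sel.SelectionResult:
    X = features[FEATURE_NAMES]
    y = features[label_col].to_numpy()
    # The selector requires complete rows; NaN feature values are
    # median-imputed over the table for the selection step only.
    X = X.fillna(X.median(numeric_only=True))
    return sel.select_features(
        X, y, r1=config.r1, r2=config.r2,
        n_permutations=config.n_permutations,
        rf_params=config.rf_params or None, seed=config.seed)


def evaluate_stage(features: pd.DataFrame, selected: list,
                   config: PipelineConfig,
                   label_col: str = "class") -> ev.CVResult:
    X = features[selected].to_numpy(dtype=float)
    y = features[label_col].to_numpy()
    groups = features["subject_id"].to_numpy()
    return ev.cross_validate(
        X, y, groups, model_kind=config.model, k=config.k_folds,
        seed=config.seed, model_params=config.model_params or None)


def run_pipeline(config: PipelineConfig, sessions_dir: str | Path,
                 out_dir: str | Path, resume: bool = True) -> dict:
    """Run extract -> select -> evaluate over a session directory.

    Writes ``features.csv``, ``selection.json`` and ``cv.json`` under
    ``out_dir``; with ``resume`` each stage is skipped when its artifact
    already exists. Stage failures abort with the failing stage named.
    Returns the artifact paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    logger.info("pipeline config: %s", json.dumps(cfg, sort_keys=True))

    features_path = out_dir / "features.csv"
    selection_path = out_dir / "selection.json"
    cv_path = out_dir / "cv.json"

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if resume and features_path.exists():
        features = pd.read_csv(features_path)
    else:
        sessions = _stage("extract", lambda: load_sessions(sessions_dir))
        features = _stage("extract", lambda: extract_stage(sessions, config))
        features.to_csv(features_path, index=False)

    if resume and selection_path.exists():
        selected = json.loads(selection_path.read_text())["selected"]
    else:
        if features["class"].isna().any():
            raise RuntimeError(
                "pipeline stage 'select' failed: unlabeled segments present")
        result = _stage("select", lambda: select_stage(features, config))
        _write_json(selection_path, {**result.to_dict(), "config": cfg})
        selected = result.selected

    if not (resume and cv_path.exists()):
        cv = _stage("evaluate", lambda: evaluate_stage(features, selected, config))
        _write_json(cv_path, {
            "model": cv.model_kind,
            "mean": cv.mean,
            "std": cv.std,
            "per_fold": [dataclasses.asdict(m) for m in cv.per_fold],
            "pooled_confusion": {
                "labels": list(cv.pooled_confusion.index),
                "rows_true_cols_predicted":
                    cv.pooled_confusion.to_numpy().tolist(),
            },
            "fold_assignment": cv.fold_assignment,
            "selected_features": list(selected),
            "config": cfg,
        })
    return {"features": features_path, "selection": selection_path,
            "cv": cv_path}
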