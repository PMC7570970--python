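"""File formats, configuration, and the end-to-end weighing pipeline.

Traces are delimited text with a header (``time_s``, ``weight_kg``,
optional ``animal_id``), one passage per file by default; feature tables
carry ``animal_id, R, sigma, PAR, FF, v[, label]``.  All times are in
seconds and all weights in kilograms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import SvmModel, predict_grade
from .estimators import EstimatorConfig, estimate_weight
from .features import FEATURE_NAMES, apply_minmax, compute_features
from .preprocess import WeightTrace, extract_valid_segment

__all__ = ["PipelineConfig", "TraceParseError", "read_trace", "write_trace",
           "read_feature_table", "write_feature_table", "write_report",
           "run_pipeline", "load_config", "save_config"]

log = logging.getLogger("walkweigh")


class TraceParseError(ValueError):
    """A trace file is malformed."""


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the end-to-end pipeline, serialisable to YAML/JSON."""

    eta: float = 0.8
    platform_length_m: float = 2.5
    sampling_interval_s: float = 0.1
    n_modes: int = 3
    gamma: float | None = None
    filter_length: int | None = None
    c_grid: list | None = None
    g_grid: list | None = None
    cv_folds: int = 5
    smote_k: int = 5
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if self.platform_length_m <= 0 or self.sampling_interval_s <= 0:
            raise ValueError("platform length and sampling interval must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")

    def estimator_config(self) -> EstimatorConfig:
        return EstimatorConfig(n_modes=self.n_modes, gamma=self.gamma,
                               filter_length=self.filter_length)


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def read_trace(path) -> WeightTrace:
    """Read one trace from delimited text (columns time_s, weight_kg)."""
    df = pd.read_csv(path)
    for col in ("time_s", "weight_kg"):
        if col not in df.columns:
            raise TraceParseError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise TraceParseError(f"{path}: no data rows")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 3:
        dt = np.diff(t)
        bad = np.flatnonzero(np.abs(dt - dt[0]) > 1e-6 * abs(dt[0]))
        if bad.size:
            raise TraceParseError(
                f"{path}: non-uniform sampling interval at data row {bad[0] + 2}")
    else:
        raise TraceParseError(f"{path}: a trace needs at least 3 samples")
    animal_id = None
    if "animal_id" in df.columns:
        ids = df["animal_id"].unique()
        if len(ids) > 1:
            raise TraceParseError(f"{path}: multiple animal_id values in one trace")
        animal_id = str(ids[0])
    return WeightTrace(times=t, weights=df["weight_kg"].to_numpy(dtype=float),
                       sampling_interval_s=float(t[1] - t[0]), animal_id=animal_id)


def write_trace(trace: WeightTrace, path, manifest: dict | None = None) -> None:
    """Write a trace as delimited text; optional JSON sidecar manifest."""
    df = pd.DataFrame({"time_s": trace.times, "weight_kg": trace.weights})
    if trace.animal_id is not None:
        df["animal_id"] = trace.animal_id
    df.to_csv(path, index=False, float_format="%.12g")
    if manifest is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing feature columns {missing}")
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def write_report(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(df.to_json(orient="index", indent=2))
    else:
        df.to_csv(path, float_format="%.10g")


def run_pipeline(traces, model: SvmModel | None = None,
                 grade_override: int | None = None,
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """Segment, featurise, classify and weigh a batch of traces.

    ``traces`` is an iterable of WeightTrace (or paths).  Either a
    trained ``model`` (with its normalisation stats attached) or a
    ``grade_override`` must be supplied.  Per-trace failures are logged
    and recorded in the ``error`` column; the batch continues.
    """
    config = config or PipelineConfig()
    if model is None and grade_override is None:
        raise ValueError("need a trained model or a grade override")
    rows = []
    for i, item in enumerate(traces):
        trace = read_trace(item) if not isinstance(item, WeightTrace) else item
        animal = trace.animal_id or f"trace-{i:04d}"
        try:
            segment = extract_valid_segment(trace, eta=config.eta)
            fv = compute_features(segment, platform_length_m=config.platform_length_m)
            if grade_override is not None:
                grade = int(grade_override)
            else:
                if model.norm_stats is None:
                    raise ValueError("model has no normalisation stats attached")
                x = apply_minmax(fv.as_array()[None, :], model.norm_stats)
                grade = int(predict_grade(model, x[0]))
            est = estimate_weight(segment, grade, config.estimator_config())
            rows.append({"animal_id": animal, "grade": grade,
                         "method": est.method, "mc_kg": est.mc_kg, "error": ""})
            log.info("weighed %s: grade=%d method=%s mc=%.2f kg",
                     animal, grade, est.method, est.mc_kg)
        except Exception as exc:  # isolate per-trace failures
            log.warning("trace %s failed: %s", animal, exc)
            rows.append({"animal_id": animal, "grade": None, "method": None,
                         "mc_kg": None, "error": str(exc)})
    return pd.DataFrame(rows)
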