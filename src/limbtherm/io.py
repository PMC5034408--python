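"""Readers and writers: trace CSV files and portable GP model files.

Trace CSV dialect: UTF-8, decimal point, header ``time_s,<chan>,...``,
one row per sample, uniform time step.  GP models are stored as a
single versioned JSON document (hyperparameters, training data, mean
offset) — no binary pickles, so files are auditable and portable.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ModelFormatError, TraceFormatError, ValidationError
from .gp import GPHyperparams, GPModel, _build_model
from .thermal import TemperatureTrace

__all__ = ["read_trace", "write_trace", "read_model", "write_model"]

MODEL_SCHEMA_VERSION = 1


def read_trace(path: str | Path) -> TemperatureTrace:
    """Read and validate a trace CSV (header ``time_s,<channel>,...``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise TraceFormatError(f"{path}: missing required column 'time_s'")
    if len(df.columns) < 2:
        raise TraceFormatError(f"{path}: no temperature channels beside time_s")
    bad = df.columns[df.isna().any() | ~df.apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        rows = df.index[df[bad].isna().any(axis=1) | df[bad].apply(
            lambda c: pd.to_numeric(c, errors="coerce").isna()).any(axis=1)]
        lines = [int(r) + 2 for r in rows[:5]]  # +2: header + 1-based
        raise TraceFormatError(
            f"{path}: non-numeric or missing values in column(s) "
            f"{list(bad)} (lines {lines})"
        )
    time_s = df["time_s"].to_numpy(dtype=float)
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"}
    if time_s.size < 2:
        raise TraceFormatError(f"{path}: need at least 2 samples")
    dt = np.diff(time_s)
    rate = 1.0 / dt[0] if dt[0] > 0 else 0.0
    try:
        return TemperatureTrace(time_s, channels, rate, {"source": str(path)})
    except ValidationError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


def write_trace(trace: TemperatureTrace, path: str | Path) -> None:
    """Write a trace as CSV; round-trips through :func:`read_trace`."""
    df = pd.DataFrame({"time_s": trace.time_s, **trace.channels})
    df.to_csv(path, index=False, float_format="%.17g")


def write_model(model: GPModel, path: str | Path) -> None:
    """Serialize a fitted GP to a versioned JSON document."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": "limbtherm-gp",
        "hyperparams": {
            "theta1": model.hyper.theta1,
            "length_scale": model.hyper.length_scale,
            "noise_var": model.hyper.noise_var,
        },
        "mean_offset": model.mean_offset,
        "log_marginal_likelihood": model.log_marginal_likelihood,
        "train_x": model.train_x.tolist(),
        "train_y": model.train_y.tolist(),
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_model(path: str | Path) -> GPModel:
    """Load a GP model file; rebuilds the covariance factorization.

    The factorization is recomputed deterministically from the stored
    data, so predictions from a round-tripped model match the original
    to floating-point reproduction of the stored decimals.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("kind") != "limbtherm-gp":
        raise ModelFormatError(f"{path}: not a limbtherm GP model file")
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelFormatError(
            f"{path}: schema version {version!r} is not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        hyper = GPHyperparams(**doc["hyperparams"])
        x = np.asarray(doc["train_x"], dtype=float)
        y = np.asarray(doc["train_y"], dtype=float)
    except (KeyError, TypeError, ValidationError) as exc:
        raise ModelFormatError(f"{path}: malformed model document: {exc}") from exc
    if x.size != y.size or x.size < 2:
        raise ModelFormatError(f"{path}: inconsistent training data lengths")
    return _build_model(x, y, hyper)
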