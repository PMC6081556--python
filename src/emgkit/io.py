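"""Shared file I/O: recordings, feature tables, models, graphs, command logs.

Recordings travel as CSV (``t_ms,ch1..chK,label``, one row per sample) with a
JSON sidecar (same stem, ``.json`` extension) holding the sampling rate and
channel names.  Models are JSON.  All writes go through this layer so that
round-trips are lossless at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .control import Calibration, Edge, Module, ModuleGraph
from .features import FeatureWindow
from .mlp import MlpModel
from .synth import EmgRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_features",
    "load_features",
    "save_model",
    "load_model",
    "load_graph",
    "save_command_log",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_recording(recording: EmgRecording, path) -> None:
    path = Path(path)
    t_ms = np.arange(recording.n_samples) / recording.sampling_rate * 1000.0
    df = pd.DataFrame(recording.samples, columns=recording.channel_names)
    df.insert(0, "t_ms", t_ms)
    df["label"] = recording.labels
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "sampling_rate": recording.sampling_rate,
        "channel_names": list(recording.channel_names),
        "n_samples": recording.n_samples,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_recording(path) -> EmgRecording:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty; not a recording") from None
    if df.empty:
        raise ValueError(f"{path} contains a header but no samples")
    for col in ("t_ms", "label"):
        if col not in df.columns:
            raise ValueError(f"{path} is missing required column {col!r}")
    channel_cols = [c for c in df.columns if c not in ("t_ms", "label")]
    if not channel_cols:
        raise ValueError(f"{path} has no channel columns")
    for col in channel_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))].index
            row = int(bad[0]) if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} (row {row})"
            )

    sampling_rate = 1000.0
    names = channel_cols
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sampling_rate = float(meta.get("sampling_rate", sampling_rate))
        names = meta.get("channel_names", names)
        if len(names) != len(channel_cols):
            raise ValueError(
                f"{sidecar} declares {len(names)} channels but {path} "
                f"has {len(channel_cols)}"
            )
    return EmgRecording(
        samples=df[channel_cols].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
        labels=df["label"].to_numpy(dtype=int),
        channel_names=list(names),
    )


def save_features(
    windows: list[FeatureWindow], path, sampling_rate: float = 1000.0
) -> None:
    path = Path(path)
    k = windows[0].rms.size if windows else 0
    rows = {
        "t_end_ms": [w.t_end / sampling_rate * 1000.0 for w in windows],
        **{
            f"rms_{i + 1}": [float(w.rms[i]) for w in windows] for i in range(k)
        },
        "mav": [w.mav for w in windows],
        "label": [w.label for w in windows],
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_features(path, sampling_rate: float = 1000.0) -> list[FeatureWindow]:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty; not a feature table") from None
    rms_cols = sorted(
        (c for c in df.columns if c.startswith("rms_")),
        key=lambda c: int(c.split("_")[1]),
    )
    for col in ("t_end_ms", "mav", "label"):
        if col not in df.columns:
            raise ValueError(f"{path} is missing required column {col!r}")
    if not rms_cols:
        raise ValueError(f"{path} has no rms_* columns")
    return [
        FeatureWindow(
            t_end=int(round(row["t_end_ms"] * sampling_rate / 1000.0)),
            rms=row[rms_cols].to_numpy(dtype=float),
            mav=float(row["mav"]),
            label=int(row["label"]),
        )
        for _, row in df.iterrows()
    ]


def save_model(model: MlpModel, path) -> None:
    path = Path(path)
    doc = {
        "layer_sizes": model.layer_sizes,
        "bias": model.bias,
        "weights": [w.tolist() for w in model.weights],
        "norm_lo": None if model.norm_lo is None else model.norm_lo.tolist(),
        "norm_hi": None if model.norm_hi is None else model.norm_hi.tolist(),
        "classes": None if model.classes is None else model.classes.tolist(),
        "meta": model.meta,
    }
    path.write_text(json.dumps(doc, indent=2))


def load_model(path) -> MlpModel:
    doc = json.loads(Path(path).read_text())
    return MlpModel(
        layer_sizes=[int(s) for s in doc["layer_sizes"]],
        weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
        bias=bool(doc.get("bias", True)),
        norm_lo=None if doc["norm_lo"] is None else np.asarray(doc["norm_lo"]),
        norm_hi=None if doc["norm_hi"] is None else np.asarray(doc["norm_hi"]),
        classes=None if doc["classes"] is None else np.asarray(doc["classes"]),
        meta=doc.get("meta", {}),
    )


def load_graph(path) -> tuple[ModuleGraph, dict, Calibration | None]:
    """Read a translator-graph config.

    JSON layout::

        {"modules": [{"name": ..., "kind": ..., "params": {...}}, ...],
         "edges": [["src", "dst"] or ["src", "dst", "slot"], ...],
         "library": {"0": "go-forward", "1": ["rotate-A", "rotate-B"], ...},
         "calibration": {"mav_rest": 0.02, "mav_max": 0.8}}

    Returns the graph, the pattern->command library (as pairs, validated by
    the control layer), and the calibration if present.
    """
    doc = json.loads(Path(path).read_text())
    modules = [
        Module(name=m["name"], kind=m["kind"], params=m.get("params", {}))
        for m in doc.get("modules", [])
    ]
    edges = [Edge(*e) for e in doc.get("edges", [])]
    library = doc.get("library", {})
    calib = None
    if "calibration" in doc:
        c = doc["calibration"]
        calib = Calibration(mav_rest=float(c["mav_rest"]), mav_max=float(c["mav_max"]))
    return ModuleGraph(modules=modules, edges=edges), library, calib


def save_command_log(events, path) -> None:
    pd.DataFrame(
        {
            "t_ms": [e.t_ms for e in events],
            "command": [e.command for e in events],
            "speed_pct": [e.speed_pct for e in events],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
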