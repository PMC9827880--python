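"""Readers and writers for point tables, parameters, curves and envelopes.

Point patterns travel as delimited text with one row per point and columns
``group, subject, sample, type, tree_id, x, y, z``; the window of each
sample lives in a JSON sidecar (``<name>.window.json``) holding the keys
``xmax``, ``ymax``, ``zmax`` (and optionally ``xmin``/``ymin``).  Summary
functions and envelopes serialise to CSV, parameter sets to YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .envelopes import Envelope
from .markov import MarkovZParams
from .pattern import PointPattern3D
from .planar import PlanarModelParams
from .summaries import SummaryFunction
from .window import BoxWindow

__all__ = [
    "read_pattern", "write_pattern", "read_window", "write_window",
    "read_summary", "write_summary", "write_envelope",
    "read_params", "write_params",
]

_COLUMNS = ["group", "subject", "sample", "type", "tree_id", "x", "y", "z"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".window.json")


def write_window(window: BoxWindow, path) -> None:
    meta = {"xmin": window.xmin, "xmax": window.xmax,
            "ymin": window.ymin, "ymax": window.ymax, "zmax": window.zmax}
    Path(path).write_text(json.dumps(meta, indent=1))


def read_window(source) -> BoxWindow:
    """Window from a JSON/YAML file path or a plain mapping."""
    if isinstance(source, BoxWindow):
        return source
    if isinstance(source, (str, Path)):
        source = yaml.safe_load(Path(source).read_text())
    if not isinstance(source, dict) or "zmax" not in source:
        raise ValueError("window metadata must provide at least xmax, ymax, zmax")
    return BoxWindow(
        float(source.get("xmin", 0.0)), float(source["xmax"]),
        float(source.get("ymin", 0.0)), float(source["ymax"]),
        float(source["zmax"]),
    )


def write_pattern(pattern: PointPattern3D, path) -> None:
    """Write the point table plus the window sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "group": pattern.labels.get("group", ""),
        "subject": pattern.labels.get("subject", ""),
        "sample": pattern.labels.get("sample", ""),
        "type": pattern.types,
        "tree_id": pattern.tree_ids,
        "x": pattern.coords[:, 0],
        "y": pattern.coords[:, 1],
        "z": pattern.coords[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.17g")
    write_window(pattern.window, _sidecar(path))


def read_pattern(path, window_meta=None) -> PointPattern3D:
    """Read and validate a point table.

    ``window_meta`` may be a BoxWindow, a mapping, or a metadata file path;
    when omitted the ``<name>.window.json`` sidecar is used.  Raises
    descriptive errors naming the offending rows for duplicate or
    out-of-window points.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty") from None
    if df.empty:
        raise ValueError(f"{path} contains no points")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns {missing}")
    for col in ("x", "y", "z"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: unparseable {col} at rows {bad.tolist()}")

    if window_meta is None:
        window_meta = _sidecar(path)
        if not Path(window_meta).exists():
            raise FileNotFoundError(
                f"no window metadata: pass window_meta or provide {window_meta}"
            )
    window = read_window(window_meta)

    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    inside = window.contains(coords)
    if not inside.all():
        rows = np.flatnonzero(~inside)
        raise ValueError(f"{path}: points outside the window at rows {rows.tolist()}")
    _, inverse, counts = np.unique(coords, axis=0, return_inverse=True,
                                   return_counts=True)
    if np.any(counts > 1):
        dup_rows = np.flatnonzero(counts[inverse] > 1)
        raise ValueError(f"{path}: duplicate coordinates at rows {dup_rows.tolist()}")

    labels = {}
    for key in ("group", "subject", "sample"):
        vals = df[key].astype(str).unique()
        if len(vals) == 1 and vals[0] not in ("", "nan"):
            labels[key] = vals[0]
    tree_ids = pd.to_numeric(df["tree_id"], errors="coerce").fillna(-1).astype(int)
    return PointPattern3D(coords, df["type"].to_numpy(dtype=object),
                          tree_ids.to_numpy(), window, labels=labels)


def write_summary(summary: SummaryFunction, path) -> None:
    df = pd.DataFrame({"r": summary.r, "value": summary.values})
    df["kind"] = summary.kind
    df["direction"] = summary.direction or "none"
    df["half_width"] = np.nan if summary.half_width is None else summary.half_width
    df["weight"] = summary.weight
    for k, v in summary.labels.items():
        df[k] = v
    df.to_csv(path, index=False)


def read_summary(path) -> SummaryFunction:
    df = pd.read_csv(path)
    direction = df["direction"].iloc[0]
    hw = df["half_width"].iloc[0]
    labels = {k: str(df[k].iloc[0]) for k in ("group", "subject", "sample")
              if k in df.columns}
    return SummaryFunction(
        df["r"].to_numpy(float), df["value"].to_numpy(float),
        None if direction in ("none", "nan") or pd.isna(direction) else direction,
        None if pd.isna(hw) else float(hw),
        weight=float(df["weight"].iloc[0]),
        kind=str(df["kind"].iloc[0]),
        labels=labels,
    )


def write_envelope(env: Envelope, path) -> None:
    pd.DataFrame({
        "r": env.r, "lower": env.lower, "upper": env.upper,
        "observed": env.observed,
    }).to_csv(path, index=False)


_PARAM_TYPES = {"planar": PlanarModelParams, "markov": MarkovZParams}


def write_params(params, path, extra: dict | None = None) -> None:
    """Serialise a parameter set (planar or Markov) as flat YAML."""
    kind = "planar" if isinstance(params, PlanarModelParams) else "markov"
    doc = {"model": kind, **params.to_dict()}
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_params(path):
    doc = yaml.safe_load(Path(path).read_text())
    kind = doc.pop("model", None)
    if kind not in _PARAM_TYPES:
        raise ValueError(f"{path}: unknown or missing model kind {kind!r}")
    cls = _PARAM_TYPES[kind]
    fields = cls.from_dict  # both classes expose from_dict over their own keys
    return fields(doc)
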