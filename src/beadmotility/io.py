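"""File formats: the plain-text trace format, fit/config JSON, TIFF stacks.

Traces are stored as tab-separated columns (t [s], x [nm], optional f [pN])
under a structured ``#``-prefixed header holding the record id, sample rate,
metadata and the append-only processing history. Round-trips are lossless
(floats written with 17 significant digits).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinetics import DistFit
from .trace import Trace, TraceError

__all__ = [
    "read_trace",
    "write_trace",
    "read_segments",
    "write_segments",
    "fit_to_dict",
    "write_fit",
    "read_frames",
    "write_frames",
]

_FORMAT_TAG = "beadmotility-trace v1"


def write_trace(trace: Trace, path) -> Path:
    path = Path(path)
    cols = ["t", "x"] + (["f"] if trace.f is not None else [])
    with open(path, "w") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write(f"# record_id: {trace.meta.get('record_id', '')}\n")
        fh.write(f"# sample_rate_hz: {trace.sample_rate!r}\n")
        fh.write(f"# substrate: {trace.meta.get('substrate', '')}\n")
        fh.write(f"# construct: {trace.meta.get('construct', '')}\n")
        fh.write(f"# temperature_c: {trace.meta.get('temperature_c', '')}\n")
        fh.write(f"# history: {json.dumps(trace.history)}\n")
        fh.write(f"# columns: {' '.join(cols)}\n")
        data = [trace.t, trace.x] + ([trace.f] if trace.f is not None else [])
        np.savetxt(fh, np.column_stack(data), fmt="%.17g", delimiter="\t")
    return path


def read_trace(path) -> Trace:
    path = Path(path)
    header = {}
    n_header = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if body == _FORMAT_TAG:
                continue
            if ":" not in body:
                raise TraceError(f"{path}:{lineno}: malformed header line {body!r}")
            key, value = body.split(":", 1)
            header[key.strip()] = value.strip()
    for required in ("sample_rate_hz", "columns"):
        if required not in header:
            raise TraceError(f"{path}: missing required header field {required!r}")
    cols = header["columns"].split()
    try:
        data = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise TraceError(f"{path}: could not parse data columns: {exc}") from exc
    if data.shape[1] != len(cols):
        raise TraceError(
            f"{path}:{n_header + 1}: expected {len(cols)} columns, found {data.shape[1]}"
        )
    column = {name: data[:, i] for i, name in enumerate(cols)}
    meta = {
        "record_id": header.get("record_id", ""),
        "substrate": header.get("substrate", ""),
        "construct": header.get("construct", ""),
    }
    if header.get("temperature_c"):
        meta["temperature_c"] = float(header["temperature_c"])
    history = json.loads(header["history"]) if header.get("history") else []
    return Trace(
        t=column["t"],
        x=column["x"],
        f=column.get("f"),
        sample_rate=float(header["sample_rate_hz"]),
        meta=meta,
        history=history,
    )


def write_segments(segments: pd.DataFrame, path) -> Path:
    path = Path(path)
    segments.to_csv(path, sep="\t", index=False)
    return path


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def fit_to_dict(fit: DistFit) -> dict:
    d = dataclasses.asdict(fit)
    d["ci95"] = {k: list(v) for k, v in d["ci95"].items()}
    return d


def write_fit(fit, path) -> Path:
    """Serialize one DistFit (or a dict of them) as JSON."""
    path = Path(path)
    if isinstance(fit, DistFit):
        payload = fit_to_dict(fit)
    else:
        payload = {k: (fit_to_dict(v) if isinstance(v, DistFit) else v) for k, v in fit.items()}
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_frames(frames: np.ndarray, path) -> Path:
    """Write a fiducial-marker stack as multi-page 16-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint16), photometric="minisblack")
    return path


def read_frames(path) -> np.ndarray:
    return tifffile.imread(Path(path))
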