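"""Lightweight persistence: raw traces, interval tables, feature matrices."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cfc import FeatureSet
from .preprocess import Trace

__all__ = ["write_trace", "read_trace", "read_csv_trace",
           "write_intervals", "read_intervals",
           "write_features", "read_features"]


def write_trace(trace: Trace, path) -> None:
    """Single-channel binary float32 with a JSON sidecar (.json)."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    meta = {"sampling_rate": trace.sampling_rate, "units": trace.units,
            "t0": trace.t0, "dtype": "<f4", "n_samples": trace.n_samples}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_trace(path) -> Trace:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    x = np.fromfile(path, dtype=meta.get("dtype", "<f4")).astype(float)
    return Trace(x, meta["sampling_rate"], units=meta.get("units", "mV"),
                 t0=meta.get("t0", 0.0))


def read_csv_trace(path, sampling_rate: float | None = None,
                   units: str = "mV") -> Trace:
    """Plain (time, value) CSV; the rate is inferred from the time column
    unless given."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    if sampling_rate is None:
        dt = np.median(np.diff(t))
        sampling_rate = 1.0 / dt
    return Trace(v, sampling_rate, units=units, t0=float(t[0]))


def write_intervals(intervals, path) -> None:
    """BED-like TSV of labelled intervals: (start_s, end_s, label[, ...])."""
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tlabel\n")
        for row in intervals:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_intervals(path) -> list:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append((float(parts[0]), float(parts[1]), *parts[2:]))
    return out


def write_features(features: FeatureSet, path) -> None:
    """TSV matrix with a YAML comment header recording provenance."""
    header = yaml.safe_dump({
        "phase_edges": list(features.phase_edges),
        "amp_edges": list(features.amp_edges),
        "phase_bands": [list(b) for b in features.phase_bands],
        "amp_bands": [list(b) for b in features.amp_bands],
        "n_base": features.n_base,
    }, default_flow_style=True)
    with open(path, "w") as fh:
        for line in header.strip().splitlines():
            fh.write(f"# {line}\n")
        fh.write("window_s\t" +
                 "\t".join(f"f{i}" for i in range(features.matrix.shape[0])) +
                 "\n")
        for w in range(features.n_windows):
            fh.write(f"{features.window_times[w]:.6f}\t" +
                     "\t".join(f"{v:.8g}" for v in features.matrix[:, w]) +
                     "\n")


def read_features(path) -> FeatureSet:
    head_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                head_lines.append(line[2:])
            else:
                break
    meta = yaml.safe_load("".join(head_lines))
    df = pd.read_csv(path, sep="\t", comment="#")
    times = df["window_s"].to_numpy(float)
    mat = df.drop(columns="window_s").to_numpy(float).T
    return FeatureSet(
        matrix=mat,
        row_norm_bounds=np.tile([[0.0, 1.0]], (mat.shape[0], 1)),
        window_times=times,
        phase_bands=[tuple(b) for b in meta["phase_bands"]],
        amp_bands=[tuple(b) for b in meta["amp_bands"]],
        phase_edges=tuple(meta["phase_edges"]),
        amp_edges=tuple(meta["amp_edges"]),
    )
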