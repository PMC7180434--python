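"""File formats and atomic writes.

Formats are deliberately plain: trace CSV (time_s, dod_690, dod_850,
label), per-trial feature CSV (trial_id, hbo2, hb, label), model and
metrics JSON. All writes go through a write-then-rename so an interrupted
run never leaves a truncated file behind.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .optics import DEFAULT_WAVELENGTHS, MeasurementGeometry
from .rbfnn import RBFNetwork
from .synthetic import LabeledTrace, TISSUE_CLASSES

__all__ = [
    "atomic_write",
    "write_json",
    "read_json",
    "write_trace_csv",
    "read_trace_csv",
    "write_features_csv",
    "read_features_csv",
    "read_geometry_json",
    "save_model",
    "load_model",
]


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def write_json(obj, path) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_trace_csv(trace: LabeledTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "dod_690": trace.dod_690,
            "dod_850": trace.dod_850,
            "label": trace.label,
        }
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def read_trace_csv(path) -> LabeledTrace:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: {exc}") from exc
    required = {"time_s", "dod_690", "dod_850"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    label = str(df["label"].iloc[0]) if "label" in df.columns else "unknown"
    t = df["time_s"].to_numpy(dtype=float)
    duration = float(t[-1] - t[0]) + (float(t[1] - t[0]) if t.size > 1 else 0.0)
    return LabeledTrace(
        time=t,
        dod_690=df["dod_690"].to_numpy(dtype=float),
        dod_850=df["dod_850"].to_numpy(dtype=float),
        label=label,
        duration=duration,
    )


def write_features_csv(features: np.ndarray, labels, path) -> None:
    with atomic_write(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "hbo2", "hb", "label"])
        for i, (row, lab) in enumerate(zip(features, labels)):
            writer.writerow([i, repr(float(row[0])), repr(float(row[1])), lab])


def read_features_csv(path) -> tuple[np.ndarray, list[str]]:
    feats, labels = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"hbo2", "hb", "label"} <= set(reader.fieldnames):
            raise ParseError(f"{path}: expected columns trial_id, hbo2, hb, label")
        for lineno, row in enumerate(reader, start=2):
            try:
                feats.append([float(row["hbo2"]), float(row["hb"])])
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad feature value ({exc})") from exc
            lab = row["label"]
            if lab not in TISSUE_CLASSES and lab not in {"vessel", "other"}:
                raise ParseError(f"{path}:{lineno}: unknown label {lab!r}")
            labels.append(lab)
    if not feats:
        raise ParseError(f"{path}: no data rows")
    return np.array(feats), labels


def read_geometry_json(path) -> tuple[MeasurementGeometry, tuple[float, ...]]:
    """Probe geometry config: JSON with keys path_length_cm (default 1.0),
    dpf (wavelength -> B, e.g. {"690": 1.2}), and wavelengths."""
    raw = read_json(path)
    try:
        geom = MeasurementGeometry(
            path_length_cm=float(raw.get("path_length_cm", 1.0)),
            dpf={float(k): float(v) for k, v in raw.get("dpf", {}).items()},
        )
        wavelengths = tuple(float(w) for w in raw.get("wavelengths", DEFAULT_WAVELENGTHS))
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return geom, wavelengths


def save_model(net: RBFNetwork, path) -> None:
    with atomic_write(path) as fh:
        fh.write(net.to_json())
        fh.write("\n")


def load_model(path) -> RBFNetwork:
    with open(path) as fh:
        return RBFNetwork.from_json(fh.read())
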