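"""Delimited-text recording I/O.

Each recording is a pair of files: ``<patient>_<phase>.csv`` holding the
sampled signals (one column per channel, header row with channel
labels, comma-separated, '.' decimal) and a JSON sidecar
``<patient>_<phase>.json`` with the metadata (patient id, phase, PVI
completion, sampling rate, simulation ground truth where present).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .records import ALL_CHANNELS, Recording

logger = logging.getLogger(__name__)

__all__ = ["write_recording", "read_recording", "write_cohort", "read_cohort"]

def write_recording(rec: Recording, out_dir: str | Path, digest: str = "") -> Path:
    """Write one recording as CSV + JSON sidecar; returns the CSV path.

    Samples are written with shortest-round-trip float formatting, so a
    read-back recording is bit-identical to the original.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.patient_id}_{rec.phase}"
    csv_path = out_dir / f"{stem}.csv"
    df = pd.DataFrame({lab: rec.signals[lab] for lab in rec.channel_labels})
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "patient_id": rec.patient_id,
        "phase": rec.phase,
        "pvi_completion": rec.pvi_completion,
        "fs": rec.fs,
        "beat_times_ms": None if rec.beat_times_ms is None
        else [float(t) for t in rec.beat_times_ms],
        "meta": rec.meta,
        "config_digest": digest,
    }
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
    return csv_path


def read_recording(path: str | Path) -> Recording:
    """Read a CSV recording (with its JSON sidecar if present).

    The CSV must carry a header row of known channel labels; unknown
    labels raise an error listing the expected names. A missing sidecar
    falls back to defaults with a warning (fs = 1000 Hz, metadata
    unknown).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    labels = list(df.columns)
    bad = [c for c in labels if c not in ALL_CHANNELS]
    if bad:
        raise ValueError(
            f"{path.name}: unknown channel labels {bad}; the header row must "
            f"name channels from {list(ALL_CHANNELS)}"
        )

    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            side = json.load(fh)
    else:
        logger.warning("%s: no JSON sidecar; using default metadata", path.name)
        stem = path.stem
        phase = "post" if stem.endswith("_post") else "pre"
        side = {"patient_id": stem.rsplit("_", 1)[0], "phase": phase,
                "pvi_completion": None, "fs": 1000.0, "beat_times_ms": None,
                "meta": {}}
    beats = side.get("beat_times_ms")
    return Recording(
        signals={lab: df[lab].to_numpy(dtype=float) for lab in labels},
        fs=float(side["fs"]),
        patient_id=str(side["patient_id"]),
        phase=str(side["phase"]),
        pvi_completion=side.get("pvi_completion"),
        beat_times_ms=None if beats is None else np.asarray(beats, dtype=float),
        meta=side.get("meta", {}),
    )


def write_cohort(patients, out_dir: str | Path, digest: str = "") -> list[Path]:
    """Write every recording of an iterable of synthetic patients."""
    paths = []
    for patient in patients:
        for rec in patient.recordings:
            paths.append(write_recording(rec, out_dir, digest=digest))
    return paths


def read_cohort(in_dir: str | Path) -> list[Recording]:
    """Read every ``*.csv`` recording under a directory (sorted order)."""
    in_dir = Path(in_dir)
    return [read_recording(p) for p in sorted(in_dir.glob("*.csv"))]
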