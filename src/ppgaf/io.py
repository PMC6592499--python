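"""Plain-text persistence for records, cohorts and window datasets.

A record is stored as a delimited-text signal file (one sample per line,
with a ``# fs: <Hz>`` header line) plus a JSON sidecar carrying the
annotations; a cohort directory holds one pair of files per record and a
``manifest.json`` listing them. Window datasets are a directory of window
signal files plus a ``windows.csv`` manifest table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PPGRecord, WindowSample
from .errors import InputError

MANIFEST_NAME = "manifest.json"
WINDOW_MANIFEST_NAME = "windows.csv"


def _record_stem(record: PPGRecord) -> str:
    return f"{record.patient_id}_{record.phase}"


def write_record(record: PPGRecord, directory: str | Path) -> dict:
    """Write one record; returns its manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = _record_stem(record)
    sig_path = directory / f"{stem}.txt"
    meta_path = directory / f"{stem}.json"
    with open(sig_path, "w") as fh:
        fh.write(f"# fs: {record.fs:g}\n")
        np.savetxt(fh, record.samples, fmt="%.6f")
    meta = {
        "patient_id": record.patient_id,
        "phase": record.phase,
        "label": record.label,
        "fs": record.fs,
        "beat_times": None
        if record.beat_times is None
        else [round(float(t), 6) for t in record.beat_times],
        "pac_flags": None
        if record.pac_flags is None
        else [bool(b) for b in record.pac_flags],
    }
    meta_path.write_text(json.dumps(meta))
    return {
        "signal": sig_path.name,
        "sidecar": meta_path.name,
        "patient_id": record.patient_id,
        "phase": record.phase,
        "label": record.label,
    }


def read_record(signal_path: str | Path, sidecar_path: str | Path | None = None) -> PPGRecord:
    """Read one record from its signal file and JSON sidecar."""
    signal_path = Path(signal_path)
    if sidecar_path is None:
        sidecar_path = signal_path.with_suffix(".json")
    with open(signal_path) as fh:
        header = fh.readline()
        if not header.startswith("#") or "fs" not in header:
            raise InputError(f"{signal_path}: missing '# fs:' header line")
        fs = float(header.split(":", 1)[1])
        samples = np.loadtxt(fh)
    meta = json.loads(Path(sidecar_path).read_text())
    if float(meta["fs"]) != fs:
        raise InputError(f"{signal_path}: header fs and sidecar fs disagree")
    return PPGRecord(
        samples=samples,
        fs=fs,
        patient_id=meta["patient_id"],
        phase=meta["phase"],
        label=meta["label"],
        beat_times=None if meta["beat_times"] is None else np.asarray(meta["beat_times"]),
        pac_flags=None if meta["pac_flags"] is None else np.asarray(meta["pac_flags"]),
    )


def write_cohort(records: list[PPGRecord], directory: str | Path) -> Path:
    """Write all records plus a cohort manifest; returns the manifest path."""
    directory = Path(directory)
    entries = [write_record(r, directory) for r in records]
    manifest = directory / MANIFEST_NAME
    manifest.write_text(json.dumps({"records": entries}, indent=1))
    return manifest


def read_cohort(directory: str | Path) -> list[PPGRecord]:
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    return [
        read_record(directory / e["signal"], directory / e["sidecar"])
        for e in manifest["records"]
    ]


def write_windows(windows: list[WindowSample], directory: str | Path) -> Path:
    """Persist preprocessed windows plus a CSV manifest table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for w in windows:
        name = f"{w.patient_id}_{w.label}_{w.window_index:04d}.txt"
        with open(directory / name, "w") as fh:
            fh.write(f"# fs: {w.fs:g}\n")
            np.savetxt(fh, w.samples, fmt="%.6f")
        rows.append(
            {
                "patient_id": w.patient_id,
                "window_index": w.window_index,
                "label": w.label,
                "start_time": w.start_time,
                "burden": w.burden if w.burden is not None else np.nan,
                "file": name,
            }
        )
    path = directory / WINDOW_MANIFEST_NAME
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_windows(directory: str | Path) -> list[WindowSample]:
    directory = Path(directory)
    table = pd.read_csv(directory / WINDOW_MANIFEST_NAME)
    out = []
    for row in table.itertuples(index=False):
        with open(directory / row.file) as fh:
            fs = float(fh.readline().split(":", 1)[1])
            samples = np.loadtxt(fh)
        out.append(
            WindowSample(
                samples=samples,
                fs=fs,
                start_time=float(row.start_time),
                label=row.label,
                patient_id=row.patient_id,
                window_index=int(row.window_index),
                burden=None if np.isnan(row.burden) else float(row.burden),
            )
        )
    return out
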