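"""Record I/O and pre-onset windowing.

Two on-disk dialects are supported:

* WFDB records (``.hea`` + ``.dat`` + ``.atr``), with beats and the
  VF-onset marker read from the annotation file;
* a plain-text CSV dialect (columns ``time_s,voltage_uV``) with a JSON
  sidecar (``<stem>.json``) carrying ``fs``, ``beat_indices``,
  ``onset_time``, ``label`` and ``record_id``.

The analysis consumes a fixed 120-s window per record: for VF records the
interval from 150 s to 30 s before onset (the last 30 s before onset — the
forecast gap — is never used for features); for controls a 120-s window
starting at a configurable offset (default 0, i.e. the first 120 s).
"""

from __future__ import annotations

import csv
import json
import os
from typing import List, Optional

import numpy as np
import pandas as pd

from . import _wfdb
from .errors import FormatError, InsufficientDataError, RecordExcludedError
from .types import (ALL_FEATURE_NAMES, CONTROL, VF, ECGRecord, RRSeries)

#: Pre-onset analysis geometry (seconds).
REQUIRED_WINDOW_S = 120.0
FORECAST_GAP_S = 30.0
PRE_ONSET_SPAN_S = REQUIRED_WINDOW_S + FORECAST_GAP_S  # 150


def write_csv_record(record: ECGRecord, stem: str) -> str:
    """Write a record as ``<stem>.csv`` + ``<stem>.json``; returns the CSV path."""
    csv_path = f"{stem}.csv"
    t = np.arange(record.samples.size) / record.fs
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "voltage_uV"])
        for ti, vi in zip(t, record.samples):
            w.writerow([f"{ti:.6f}", f"{vi:.4f}"])
    sidecar = {
        "fs": record.fs,
        "beat_indices": [int(b) for b in record.beat_indices],
        "onset_time": record.onset_time,
        "label": record.label,
        "record_id": record.record_id or os.path.basename(stem),
    }
    with open(f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh)
    return csv_path


def _read_csv_record(csv_path: str) -> ECGRecord:
    stem = csv_path[:-4]
    sidecar_path = f"{stem}.json"
    if not os.path.exists(sidecar_path):
        raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    df = pd.read_csv(csv_path)
    if not {"time_s", "voltage_uV"} <= set(df.columns):
        raise FormatError(f"{csv_path}: expected columns time_s,voltage_uV")
    samples = df["voltage_uV"].to_numpy(dtype=float)
    beats = np.asarray(meta.get("beat_indices", []), dtype=np.int64)
    if beats.size and beats[-1] >= samples.size:
        raise FormatError(f"{csv_path}: beat index beyond signal length")
    return ECGRecord(samples=samples, fs=float(meta["fs"]), beat_indices=beats,
                     onset_time=meta.get("onset_time"),
                     label=meta.get("label", CONTROL),
                     record_id=meta.get("record_id", os.path.basename(stem)))


def _read_wfdb_record(hea_path: str) -> ECGRecord:
    header = _wfdb.read_header(hea_path)
    directory = os.path.dirname(hea_path) or "."
    samples = _wfdb.read_signal(header, directory, channel=0)
    atr_path = os.path.join(directory, f"{header.record_name}.atr")
    beats, onset_idx = _wfdb.read_annotations(atr_path)
    onset = onset_idx / header.fs if onset_idx is not None else None
    label = VF if onset is not None else CONTROL
    return ECGRecord(samples=samples, fs=header.fs, beat_indices=beats,
                     onset_time=onset, label=label,
                     record_id=header.record_name)


def read_record(path: str) -> ECGRecord:
    """Read an ECG record from a WFDB header path or a CSV dialect path.

    Accepts ``name.hea``, ``name.csv``, or a bare ``name`` for which
    ``name.hea`` or ``name.csv`` exists.
    """
    if path.endswith(".csv"):
        return _read_csv_record(path)
    if path.endswith(".hea"):
        return _read_wfdb_record(path)
    if os.path.exists(f"{path}.hea"):
        return _read_wfdb_record(f"{path}.hea")
    if os.path.exists(f"{path}.csv"):
        return _read_csv_record(f"{path}.csv")
    raise FileNotFoundError(f"no .hea or .csv record found for {path!r}")


def write_wfdb_record(record: ECGRecord, directory: str,
                      record_name: Optional[str] = None) -> str:
    """Write a record in the WFDB dialect; returns the header path."""
    name = record_name or record.record_id or "record"
    onset_idx = (int(round(record.onset_time * record.fs))
                 if record.onset_time is not None else None)
    return _wfdb.write_record(directory, name, record.samples, record.fs,
                              record.beat_indices, onset_index=onset_idx)


def required_window(record: ECGRecord, control_offset_s: float = 0.0) -> ECGRecord:
    """Cut the 120-s analysis window out of a record.

    VF records (onset marker present) yield ``[onset-150 s, onset-30 s)``;
    records without an onset yield the 120 s starting at
    ``control_offset_s``. Beats are re-indexed to the window; a beat at
    exactly the window end is excluded (half-open convention). Raises
    :class:`RecordExcludedError` when the record is too short, mirroring
    the study-design exclusion of short recordings.
    """
    fs = record.fs
    if record.onset_time is not None:
        if record.onset_time < PRE_ONSET_SPAN_S:
            raise RecordExcludedError(
                record.record_id,
                f"onset at {record.onset_time:.1f} s leaves no "
                f"{PRE_ONSET_SPAN_S:.0f}-s pre-onset span")
        start_s = record.onset_time - PRE_ONSET_SPAN_S
    else:
        if record.duration < control_offset_s + REQUIRED_WINDOW_S:
            raise RecordExcludedError(
                record.record_id,
                f"duration {record.duration:.1f} s shorter than the "
                f"{REQUIRED_WINDOW_S:.0f}-s window")
        start_s = control_offset_s
    start = int(round(start_s * fs))
    end = start + int(round(REQUIRED_WINDOW_S * fs))
    if end > record.samples.size:
        raise RecordExcludedError(record.record_id,
                                  "analysis window extends past end of record")
    beats = record.beat_indices
    keep = beats[(beats >= start) & (beats < end)] - start
    return ECGRecord(samples=record.samples[start:end], fs=fs,
                     beat_indices=keep, onset_time=None,
                     label=record.label, record_id=record.record_id)


def rr_from_beats(record: ECGRecord) -> RRSeries:
    """Derive the RR series (ms) from a record's beat annotations."""
    if record.beat_indices.size < 3:
        raise InsufficientDataError(
            f"record {record.record_id!r} has {record.beat_indices.size} "
            "annotated beats; need at least 3")
    times = record.beat_times
    return RRSeries(rr=np.diff(times) * 1000.0, t=times[1:])


def feature_table_to_csv(table: pd.DataFrame, path: str) -> None:
    """Write a feature table (record_id, label, features) as CSV."""
    cols = ["record_id", "label"] + [c for c in ALL_FEATURE_NAMES if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False)


def load_records_dir(directory: str) -> List[ECGRecord]:
    """Load every record (WFDB or CSV dialect) found in a directory."""
    records = []
    for entry in sorted(os.listdir(directory)):
        if entry.endswith(".hea"):
            records.append(_read_wfdb_record(os.path.join(directory, entry)))
        elif entry.endswith(".csv") and os.path.exists(
                os.path.join(directory, entry[:-4] + ".json")):
            records.append(_read_csv_record(os.path.join(directory, entry)))
    return records
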