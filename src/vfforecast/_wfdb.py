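"""Minimal WFDB record I/O: header + signal (formats 16 and 212) + MIT annotations.

Supports the subset of the WFDB conventions this package needs: single- or
multi-signal headers, int16 (format 16) and packed 12-bit (format 212)
signal files, and annotation files holding beat labels plus an optional
ventricular-fibrillation-onset marker (the standard VFON code, 32).
Physical units are converted to uV on read via ``(adu - baseline) / gain``
with gain in adu/mV.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import FormatError

# MIT annotation type codes treated as beats (NORMAL..various beat types).
_BEAT_CODES = frozenset(range(1, 14)) | {25, 34, 35, 38}
_VFON = 32          # start of ventricular flutter/fibrillation
_SKIP = 59
_NUM, _SUB, _CHN, _AUX = 60, 61, 62, 63
_NORMAL = 1


@dataclass
class SignalSpec:
    file_name: str
    fmt: int
    gain: float       # adu per mV
    baseline: int     # adu at 0 physical
    name: str


@dataclass
class WFDBHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: List[SignalSpec]


def read_header(path: str) -> WFDBHeader:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty header file {path}")
    top = lines[0].split()
    if len(top) < 4:
        raise FormatError(f"malformed header line: {lines[0]!r}")
    name, n_sig = top[0], int(top[1])
    fs = float(top[2].split("/")[0])
    n_samples = int(top[3])
    signals = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 3:
            raise FormatError(f"malformed signal line: {ln!r}")
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        m = re.match(r"(-?[\d.]+)(?:\((-?\d+)\))?(?:/(\S+))?", parts[2])
        if not m:
            raise FormatError(f"malformed gain field: {parts[2]!r}")
        gain = float(m.group(1)) or 200.0   # 0 means the WFDB default
        baseline = int(m.group(2)) if m.group(2) else (
            int(parts[4]) if len(parts) > 4 else 0)
        signals.append(SignalSpec(file_name=parts[0], fmt=fmt, gain=gain,
                                  baseline=baseline,
                                  name=parts[-1] if len(parts) > 8 else f"sig{len(signals)}"))
    if len(signals) != n_sig:
        raise FormatError(f"header declares {n_sig} signals, found {len(signals)}")
    return WFDBHeader(record_name=name, n_sig=n_sig, fs=fs,
                      n_samples=n_samples, signals=signals)


def _read_fmt16(path: str, n_sig: int) -> np.ndarray:
    raw = np.fromfile(path, dtype="<i2")
    if n_sig > 1:
        raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)
    else:
        raw = raw.reshape(-1, 1)
    return raw.astype(np.int64)


def _read_fmt212(path: str, n_sig: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    raw = raw[: (raw.size // 3) * 3].reshape(-1, 3)
    first = raw[:, 0].astype(np.int64) | ((raw[:, 1].astype(np.int64) & 0x0F) << 8)
    second = raw[:, 2].astype(np.int64) | ((raw[:, 1].astype(np.int64) & 0xF0) << 4)
    first[first > 2047] -= 4096
    second[second > 2047] -= 4096
    flat = np.empty(first.size * 2, dtype=np.int64)
    flat[0::2], flat[1::2] = first, second
    if n_sig > 1:
        flat = flat[: (flat.size // n_sig) * n_sig].reshape(-1, n_sig)
    else:
        flat = flat.reshape(-1, 1)
    return flat


def read_signal(header: WFDBHeader, directory: str, channel: int = 0) -> np.ndarray:
    """Read one channel and return voltages in uV."""
    spec = header.signals[channel]
    dat_path = os.path.join(directory, spec.file_name)
    if not os.path.exists(dat_path):
        raise FileNotFoundError(f"signal file not found: {dat_path}")
    if spec.fmt == 16:
        adus = _read_fmt16(dat_path, header.n_sig)
    elif spec.fmt == 212:
        adus = _read_fmt212(dat_path, header.n_sig)
    else:
        raise FormatError(f"unsupported WFDB signal format {spec.fmt}")
    if header.n_samples and abs(adus.shape[0] - header.n_samples) > 1:
        raise FormatError(
            f"signal file holds {adus.shape[0]} samples, header says {header.n_samples}")
    col = adus[:, channel]
    return (col - spec.baseline) / spec.gain * 1000.0  # adu/mV -> uV


def read_annotations(path: str) -> Tuple[np.ndarray, Optional[int]]:
    """Read beat sample indices and the VF-onset sample (or None)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"annotation file not found: {path}")
    words = np.fromfile(path, dtype="<u2")
    beats: List[int] = []
    onset: Optional[int] = None
    t = 0
    i = 0
    while i < words.size:
        w = int(words[i])
        code, delta = w >> 10, w & 0x3FF
        i += 1
        if w == 0:
            break  # EOF marker
        if code == _SKIP:
            if i + 1 >= words.size:
                raise FormatError("truncated SKIP annotation")
            high, low = int(words[i]), int(words[i + 1])
            interval = (high << 16) | low
            if interval & 0x80000000:
                interval -= 1 << 32
            t += interval
            i += 2
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += (delta + 1) // 2  # aux string padded to even length
            continue
        t += delta
        if code in _BEAT_CODES:
            beats.append(t)
        elif code == _VFON and onset is None:
            onset = t
    return np.asarray(beats, dtype=np.int64), onset


def write_record(directory: str, record_name: str, samples_uv: np.ndarray,
                 fs: float, beat_indices: np.ndarray,
                 onset_index: Optional[int] = None,
                 gain: float = 1000.0) -> str:
    """Write a single-signal WFDB record (format 16) plus annotations.

    With the default gain of 1000 adu/mV one adu is 1 uV. Returns the
    header path.
    """
    os.makedirs(directory, exist_ok=True)
    adus = np.round(np.asarray(samples_uv) / 1000.0 * gain).astype("<i2")
    if np.any(np.abs(np.asarray(samples_uv) / 1000.0 * gain) > 32767):
        raise FormatError("signal exceeds int16 range at this gain")
    dat_name = f"{record_name}.dat"
    adus.tofile(os.path.join(directory, dat_name))
    init = int(adus[0]) if adus.size else 0
    checksum = int(np.sum(adus.astype(np.int64)) & 0xFFFF)
    hea_path = os.path.join(directory, f"{record_name}.hea")
    with open(hea_path, "w") as fh:
        fh.write(f"{record_name} 1 {fs:g} {adus.size}\n")
        fh.write(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {init} {checksum} 0 ECG\n")

    events: List[Tuple[int, int]] = [(int(b), _NORMAL) for b in beat_indices]
    if onset_index is not None:
        events.append((int(onset_index), _VFON))
    events.sort()
    words: List[int] = []
    t = 0
    for idx, code in events:
        delta = idx - t
        if delta > 1023 or delta < 0:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
        t = idx
    words.append(0)  # EOF
    np.asarray(words, dtype="<u2").tofile(os.path.join(directory, f"{record_name}.atr"))
    return hea_path
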