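"""QRS detection, windowing, and shape features (signed area, R amplitude).

The four shape features summarize beat-to-beat QRS morphology over the
analysis window: the mean and standard deviation of the absolute QRS
signed area (baseline-corrected sum of samples between the PQ junction
and the J point) and of the R-peak amplitude (maximum baseline-corrected
sample in that window). The absolute value applies to areas only; the
amplitude statistics keep the sign. All means/SDs use the population
(1/N) form.

Areas are reported in uV*samples by default; ``area_in_uv_ms=True``
converts to uV*ms (multiplying by 1000/fs), which is comparable across
sampling rates.
"""

from __future__ import annotations

import logging
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError
from .types import ECGRecord, QRSFeatures, QRSWindow

log = logging.getLogger(__name__)

# Boundary-search constants (ms): scan outward from R for a slope minimum
# within +-SEARCH_MS; fall back to fixed +-FALLBACK_MS offsets; baseline is
# the mean of the BASELINE_MS segment ending at the PQ junction.
SEARCH_MS = 120.0
FALLBACK_MS = 60.0
BASELINE_MS = 40.0
SLOPE_THRESHOLD_FRAC = 0.05  # of the window's peak slope magnitude


def detect_r_peaks(record: ECGRecord, use_annotations: bool = True) -> np.ndarray:
    """Locate R peaks; annotated records return their annotations verbatim.

    Detection follows the classic band-pass -> differentiate -> square ->
    moving-window-integrate recipe with an adaptive threshold, then
    refines each detection to the local absolute-amplitude extremum of the
    raw signal within +-100 ms.
    """
    if use_annotations and record.beat_indices.size:
        return record.beat_indices.copy()
    x = record.samples
    fs = record.fs
    if x.size < 2 * fs:
        raise InsufficientDataError("record shorter than 2 s")
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(15.0, 0.9 * nyq) / nyq], btype="band")
    filtered = sps.filtfilt(b, a, x)
    squared = np.diff(filtered, prepend=filtered[0]) ** 2
    win = max(1, int(0.15 * fs))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    threshold = 0.2 * np.max(integrated)
    if threshold <= 0:
        warnings.warn("flat signal: no R peaks detected", stacklevel=2)
        return np.array([], dtype=np.int64)
    refractory = int(0.25 * fs)
    peaks, _ = sps.find_peaks(integrated, height=threshold, distance=refractory)
    if peaks.size == 0:
        warnings.warn("no peaks above adaptive threshold", stacklevel=2)
        return np.array([], dtype=np.int64)

    half = int(0.1 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    return np.unique(np.asarray(refined, dtype=np.int64))


def qrs_window(record: ECGRecord, r_index: int) -> Optional[QRSWindow]:
    """Find one beat's PQ-junction-to-J-point window around ``r_index``.

    Boundaries are the nearest points, scanning outward from R, where the
    slope magnitude drops below a fraction of the local maximum slope
    (the waveform has flattened out); when no such point exists within
    +-120 ms the fixed +-60 ms fallback is used. Returns ``None`` (with a
    log entry) when the window would cross the record edge.
    """
    fs = record.fs
    x = record.samples
    search = int(round(SEARCH_MS / 1000.0 * fs))
    fallback = int(round(FALLBACK_MS / 1000.0 * fs))
    base_len = max(1, int(round(BASELINE_MS / 1000.0 * fs)))
    lo, hi = r_index - search, r_index + search
    if lo - base_len < 0 or hi >= x.size:
        log.info("beat at sample %d skipped: too close to record edge", r_index)
        return None

    slope = np.abs(np.diff(x[lo:hi + 1]))
    peak_slope = float(np.max(slope)) if slope.size else 0.0
    thr = SLOPE_THRESHOLD_FRAC * peak_slope
    r_rel = r_index - lo

    pq_rel = None
    # Left of R the slope first rises through the QRS upstroke; accept a
    # boundary only after the scan has passed that high-slope region.
    seen_steep = False
    for k in range(r_rel - 1, -1, -1):
        if slope[k] > thr:
            seen_steep = True
        elif seen_steep:
            pq_rel = k
            break
    j_rel = None
    seen_steep = False
    for k in range(r_rel, slope.size):
        if slope[k] > thr:
            seen_steep = True
        elif seen_steep:
            j_rel = k
            break
    pq = lo + pq_rel if pq_rel is not None else r_index - fallback
    j = lo + j_rel if j_rel is not None else r_index + fallback
    if pq >= r_index or j <= r_index:
        pq, j = r_index - fallback, r_index + fallback
    if pq - base_len < 0 or j >= x.size:
        log.info("beat at sample %d skipped: window crosses record edge", r_index)
        return None
    baseline = float(np.mean(x[pq - base_len:pq]))
    return QRSWindow(pq_index=int(pq), j_index=int(j), r_index=int(r_index),
                     baseline=baseline)


def signed_area(record: ECGRecord, w: QRSWindow,
                weights: Optional[np.ndarray] = None) -> float:
    """Baseline-corrected (weighted) sum of samples in ``[pq, j]``, uV*samples.

    Uniform weights by default; ``weights`` (length ``j - pq + 1``) hooks in
    alternative kernels. The sign is preserved: net-downward complexes give
    negative areas.
    """
    seg = record.samples[w.pq_index:w.j_index + 1] - w.baseline
    if weights is not None:
        if weights.size != seg.size:
            raise ValueError("weights length must match the window length")
        seg = seg * weights
    return float(np.sum(seg))


def r_amplitude(record: ECGRecord, w: QRSWindow) -> float:
    """Maximum baseline-corrected sample in the QRS window, uV."""
    seg = record.samples[w.pq_index:w.j_index + 1] - w.baseline
    return float(np.max(seg))


def qrs_shape_features(areas: Sequence[float], amps: Sequence[float]
                       ) -> QRSFeatures:
    """Aggregate per-beat areas/amplitudes into the four shape features.

    ``QRSaM``/``QRSaSD`` are the population mean/SD of the *absolute*
    signed areas; ``RPampM``/``RPampSD`` of the raw amplitudes.
    """
    areas = np.asarray(areas, dtype=float)
    amps = np.asarray(amps, dtype=float)
    if areas.size < 2 or amps.size < 2:
        raise InsufficientDataError("need at least 2 beats for QRS shape features")
    abs_areas = np.abs(areas)
    qrsam = float(np.mean(abs_areas))
    qrsasd = float(np.sqrt(np.mean((abs_areas - qrsam) ** 2)))
    rpampm = float(np.mean(amps))
    rpampsd = float(np.sqrt(np.mean((amps - rpampm) ** 2)))
    return QRSFeatures(qrsam=qrsam, qrsasd=qrsasd, rpampm=rpampm, rpampsd=rpampsd)


def per_beat_measures(record: ECGRecord, use_annotations: bool = True
                      ) -> Tuple[np.ndarray, np.ndarray, List[QRSWindow]]:
    """Per-beat signed areas and R amplitudes for a whole record."""
    r_peaks = detect_r_peaks(record, use_annotations=use_annotations)
    areas: List[float] = []
    amps: List[float] = []
    windows: List[QRSWindow] = []
    for r in r_peaks:
        w = qrs_window(record, int(r))
        if w is None:
            continue
        areas.append(signed_area(record, w))
        amps.append(r_amplitude(record, w))
        windows.append(w)
    return np.asarray(areas), np.asarray(amps), windows


def qrs_features(record: ECGRecord, use_annotations: bool = True,
                 area_in_uv_ms: bool = False) -> QRSFeatures:
    """Compute the four QRS-shape features for one record."""
    areas, amps, _ = per_beat_measures(record, use_annotations=use_annotations)
    if area_in_uv_ms:
        areas = areas * (1000.0 / record.fs)
    return qrs_shape_features(areas, amps)
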