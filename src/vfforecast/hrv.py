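"""Heart-rate-variability features: time domain, Welch band powers, Poincare.

Definitions
-----------
Time domain (RR intervals in ms, ``N`` intervals, ``D`` the ``N-1``
successive differences):

* ``MeanNN = mean(RR)``
* ``SDNN = sqrt(mean((RR - MeanNN)^2))`` (population form, 1/N)
* ``RMSSD = sqrt(mean(D^2))`` (averaged over the N-1 differences)
* ``pNN50 = 100 * #{|D| > 50 ms} / N`` — note the denominator is the
  total number of RR *intervals*, not differences; a ``per_differences``
  switch selects the more common N-1 convention.

Frequency domain: the RR tachogram is cubic-spline resampled at 4 Hz,
linearly detrended, and fed to Welch's periodogram with 256-point Hann
windows at 50% overlap; band powers are PSD bin sums (in ms^2) over
VLF (0, 0.04], LF (0.04, 0.15] and HF (0.15, 0.4] Hz. With 4-Hz
resampling one 256-point window spans 64 s, so a 120-s analysis window
provides two overlapping segments. The DC bin is excluded (detrending
removes the mean), so "0-0.04 Hz" is effectively (0, 0.04].

Poincare: ``SD1 = sqrt(Var(RR_i - RR_{i+1}) / 2)`` (population variance)
is the dispersion perpendicular to the line of identity; ``SD2`` follows
from the identity ``SD2^2 = 2*SDNN^2 - SD1^2`` (clamped at 0 against
floating-point underflow), so ``SD1^2 + SD2^2 = 2*SDNN^2`` holds exactly.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import interpolate, signal

from .errors import InsufficientDataError
from .types import HRVFeatures, RRSeries

RESAMPLE_FS = 4.0      # Hz, conventional HRV tachogram rate
WELCH_NPERSEG = 256    # samples -> 64 s at 4 Hz
VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
PNN_THRESHOLD_MS = 50.0
POWER_FLOOR_MS2 = 1e-9  # below this, a band power is numerically zero


def time_domain(rr: RRSeries, per_differences: bool = False
                ) -> Tuple[float, float, float, float]:
    """Return ``(mean_nn, sdnn, rmssd, pnn50)``.

    ``per_differences=True`` divides the pNN50 count by the number of
    successive differences (N-1) instead of the number of intervals (N).
    """
    x = rr.rr
    n = x.size
    if n < 2:
        raise InsufficientDataError("need at least 2 RR intervals")
    mean_nn = float(np.mean(x))
    sdnn = float(np.sqrt(np.mean((x - mean_nn) ** 2)))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    denom = d.size if per_differences else n
    pnn50 = float(100.0 * np.count_nonzero(np.abs(d) > PNN_THRESHOLD_MS) / denom)
    return mean_nn, sdnn, rmssd, pnn50


def resample_tachogram(rr: RRSeries, fs: float = RESAMPLE_FS
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resample RR(t) onto an even grid; returns (t_grid, rr_grid)."""
    if len(rr) < 4:
        raise InsufficientDataError("need at least 4 RR intervals to resample")
    t_grid = np.arange(rr.t[0], rr.t[-1], 1.0 / fs)
    spline = interpolate.CubicSpline(rr.t, rr.rr)
    return t_grid, spline(t_grid)


def frequency_domain(rr: RRSeries) -> Tuple[float, float, float, float]:
    """Return ``(vlf, lf, hf, lf_hf)`` band powers in ms^2.

    ``lf_hf`` is NaN when the HF power is zero (flagged, never infinite).
    Requires the series to span at least 64 s so one Welch window fits.
    """
    t_grid, x = resample_tachogram(rr)
    if x.size < WELCH_NPERSEG:
        raise InsufficientDataError(
            f"tachogram spans {x.size / RESAMPLE_FS:.0f} s; need at least "
            f"{WELCH_NPERSEG / RESAMPLE_FS:.0f} s for one Welch window")
    x = signal.detrend(x, type="linear")
    freqs, psd = signal.welch(x, fs=RESAMPLE_FS, window="hann",
                              nperseg=WELCH_NPERSEG,
                              noverlap=WELCH_NPERSEG // 2, detrend=False)
    df = freqs[1] - freqs[0]

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs > lo) & (freqs <= hi)
        return float(np.sum(psd[mask]) * df)

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    lf_hf = lf / hf if hf > POWER_FLOOR_MS2 else float("nan")
    return vlf, lf, hf, lf_hf


def poincare(rr: RRSeries) -> Tuple[float, float, float]:
    """Return ``(sd1, sd2, sd1_sd2)``; the ratio is NaN when SD2 is 0."""
    x = rr.rr
    if x.size < 3:
        raise InsufficientDataError("need at least 3 RR intervals")
    d = x[:-1] - x[1:]
    sd1 = float(np.sqrt(np.var(d) / 2.0))
    sdnn = float(np.sqrt(np.mean((x - np.mean(x)) ** 2)))
    sd2_sq = 2.0 * sdnn ** 2 - sd1 ** 2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    sd1_sd2 = sd1 / sd2 if sd2 > 0 else float("nan")
    return sd1, sd2, sd1_sd2


def hrv_features(rr: RRSeries, per_differences: bool = False) -> HRVFeatures:
    """Compute all 11 HRV features from one RR series."""
    mean_nn, sdnn, rmssd, pnn50 = time_domain(rr, per_differences=per_differences)
    vlf, lf, hf, lf_hf = frequency_domain(rr)
    sd1, sd2, sd1_sd2 = poincare(rr)
    return HRVFeatures(mean_nn=mean_nn, sdnn=sdnn, rmssd=rmssd, pnn50=pnn50,
                       vlf=vlf, lf=lf, hf=hf, lf_hf=lf_hf,
                       sd1=sd1, sd2=sd2, sd1_sd2=sd1_sd2)
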