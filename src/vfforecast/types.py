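"""Core domain containers: ECG records, RR series, feature bundles.

Conventions used throughout the package:

* voltages are in microvolts (uV), sampling rates in Hz;
* RR intervals are in milliseconds, beat times in seconds;
* windows are half-open ``[start, end)`` with 0-based sample indices;
* the positive class is the VF-prone group (label ``"VF"``), the negative
  class is ``"control"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidParameterError

VF = "VF"
CONTROL = "control"

#: Feature names in canonical report order (11 HRV + 4 QRS-shape).
HRV_FEATURE_NAMES = (
    "Mean NN", "SDNN", "RMSSD", "pNN50",
    "VLF", "LF", "HF", "LF/HF",
    "SD1", "SD2", "SD1/SD2",
)
QRS_FEATURE_NAMES = ("QRSaM", "QRSaSD", "RPampM", "RPampSD")
ALL_FEATURE_NAMES = HRV_FEATURE_NAMES + QRS_FEATURE_NAMES


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead ECG with beat annotations.

    Parameters
    ----------
    samples : ndarray
        Voltage trace in uV.
    fs : float
        Sampling rate in Hz.
    beat_indices : ndarray of int
        Sample positions of annotated R peaks, strictly increasing.
    onset_time : float or None
        VF onset in seconds from record start; ``None`` for controls.
    label : str
        ``"VF"`` or ``"control"``.
    record_id : str
        Identifier used in reports and error messages.
    """

    samples: np.ndarray
    fs: float
    beat_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    onset_time: Optional[float] = None
    label: str = CONTROL
    record_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.beat_indices = np.asarray(self.beat_indices, dtype=np.int64)
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if self.beat_indices.size:
            if np.any(np.diff(self.beat_indices) <= 0):
                raise InvalidParameterError("beat_indices must be strictly increasing")
            if self.beat_indices[0] < 0 or self.beat_indices[-1] >= self.samples.size:
                raise InvalidParameterError("beat_indices out of record range")
        if self.onset_time is not None and self.onset_time > self.duration:
            raise InvalidParameterError("onset_time beyond record duration")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def beat_times(self) -> np.ndarray:
        """Annotated beat times in seconds."""
        return self.beat_indices / self.fs

    def copy_with(self, **kw) -> "ECGRecord":
        return replace(self, **kw)


@dataclass
class RRSeries:
    """Ordered R-peak-to-R-peak intervals.

    ``rr[i]`` is the interval in ms ending at time ``t[i]`` (seconds).
    """

    rr: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        self.rr = np.asarray(self.rr, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.rr.shape != self.t.shape:
            raise InvalidParameterError("rr and t must have the same length")
        if np.any(self.rr <= 0):
            raise InvalidParameterError("all RR intervals must be positive")

    def __len__(self) -> int:
        return self.rr.size


@dataclass
class GroupParams:
    """Generative parameters for one study group's synthetic records.

    The RR tachogram is a mean plus one low-frequency (sympathetic-band)
    and one high-frequency (respiratory-band) sinusoidal modulation plus
    white noise; the ECG is a per-beat P-QRS-T Gaussian-wave template with
    slow R-amplitude modulation and beat-to-beat QRS-width jitter.

    ``subject_cv_rr`` / ``subject_cv_qrs`` are between-subject lognormal
    coefficients of variation applied per record when a cohort is drawn,
    so that group feature distributions overlap realistically instead of
    collapsing onto a point.
    """

    mean_rr: float = 800.0          # ms
    lf_mod_amp: float = 15.0        # ms
    lf_mod_freq: float = 0.1        # Hz
    hf_mod_amp: float = 10.0        # ms
    hf_mod_freq: float = 0.25       # Hz
    rr_noise_sd: float = 25.0       # ms
    r_amp_base: float = 1000.0      # uV
    r_amp_mod_depth: float = 0.05   # fraction of r_amp_base
    qrs_width: float = 80.0         # ms
    area_jitter_sd: float = 0.05    # fractional QRS width jitter
    ecg_noise_sd: float = 10.0      # uV
    label: str = CONTROL
    subject_cv_rr: float = 0.0
    subject_cv_qrs: float = 0.0

    def __post_init__(self):
        if self.mean_rr <= 0:
            raise InvalidParameterError("mean_rr must be positive")
        if self.qrs_width <= 0:
            raise InvalidParameterError("qrs_width must be positive")
        for name in ("lf_mod_amp", "hf_mod_amp", "rr_noise_sd", "area_jitter_sd",
                     "ecg_noise_sd", "subject_cv_rr", "subject_cv_qrs"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if not 0 <= self.r_amp_mod_depth < 1:
            raise InvalidParameterError("r_amp_mod_depth must lie in [0, 1)")
        if self.lf_mod_amp > 0 and not 0.04 < self.lf_mod_freq < 0.15:
            raise InvalidParameterError("lf_mod_freq must lie in the LF band (0.04, 0.15) Hz")
        if self.hf_mod_amp > 0 and not 0.15 < self.hf_mod_freq < 0.4:
            raise InvalidParameterError("hf_mod_freq must lie in the HF band (0.15, 0.4) Hz")

    def copy_with(self, **kw) -> "GroupParams":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a synthetic record."""

    beat_times: np.ndarray                 # s
    rr_true: np.ndarray                    # ms, len(beat_times) - 1
    r_amp_true: Optional[np.ndarray] = None      # uV per beat
    qrs_area_true: Optional[np.ndarray] = None   # uV*samples per beat
    onset_time: Optional[float] = None

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_true = np.asarray(self.rr_true, dtype=float)
        if np.any(np.diff(self.beat_times) <= 0):
            raise InvalidParameterError("truth beat_times must be strictly increasing")


@dataclass
class QRSWindow:
    """One beat's QRS integration window (sample indices, inclusive)."""

    pq_index: int
    j_index: int
    r_index: int
    baseline: float  # uV

    def __post_init__(self):
        if not self.pq_index < self.r_index < self.j_index:
            raise InvalidParameterError("require pq_index < r_index < j_index")


@dataclass
class HRVFeatures:
    """The 11 heart-rate-variability features."""

    mean_nn: float   # ms
    sdnn: float      # ms
    rmssd: float     # ms
    pnn50: float     # %
    vlf: float       # ms^2
    lf: float        # ms^2
    hf: float        # ms^2
    lf_hf: float     # ratio; NaN when HF power is 0
    sd1: float       # ms
    sd2: float       # ms
    sd1_sd2: float   # ratio; NaN when SD2 is 0

    def to_dict(self) -> dict:
        return dict(zip(HRV_FEATURE_NAMES, (
            self.mean_nn, self.sdnn, self.rmssd, self.pnn50,
            self.vlf, self.lf, self.hf, self.lf_hf,
            self.sd1, self.sd2, self.sd1_sd2,
        )))


@dataclass
class QRSFeatures:
    """Mean/SD of per-beat |signed area| and R-peak amplitude."""

    qrsam: float    # uV*samples
    qrsasd: float   # uV*samples
    rpampm: float   # uV
    rpampsd: float  # uV

    def to_dict(self) -> dict:
        return dict(zip(QRS_FEATURE_NAMES,
                        (self.qrsam, self.qrsasd, self.rpampm, self.rpampsd)))
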