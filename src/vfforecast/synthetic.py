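"""Synthetic two-group ECG/RR generator with full ground truth.

Emulates the statistical structure the pre-VF analysis assumes: a VF-prone
group and a control group whose 120-s pre-onset windows differ in RR
variability (higher SDNN/RMSSD/pNN50/SD1/SD2 in the VF group) and in
QRS-shape statistics (higher signed-area SD and R-amplitude mean/SD).

The RR tachogram is ``mean + LF sinusoid + HF sinusoid + white noise``;
the ECG places a P-QRS-T sum-of-Gaussians template at every beat, with a
slow sinusoidal R-amplitude modulation (the mechanism the signed-area /
R-amplitude features pick up) and beat-to-beat QRS-width jitter. The
waveform is deliberately simple: the pipeline only consumes the RR series
and QRS-window statistics, so a full dynamical ECG model would add nothing
testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import InvalidParameterError
from .types import CONTROL, VF, ECGRecord, GroupParams, RRSeries, SyntheticTruth

# P-QRS-T template geometry. QRS wave offsets/widths scale with the per-beat
# QRS width w; P and T are fixed-width and sit outside the QRS window.
_P_AMP_FRAC = 0.12      # of r_amp_base (not beat-modulated)
_P_OFFSET = -0.19       # s before R
_P_SIGMA = 0.022        # s
_Q_AMP_FRAC = -0.10     # of per-beat R amplitude
_Q_OFFSET_FRAC = -0.22  # of w
_S_AMP_FRAC = -0.18
_S_OFFSET_FRAC = 0.22
_QS_SIGMA_FRAC = 0.08   # of w
_R_SIGMA_FRAC = 1 / 6   # of w, so +-3 sigma spans the QRS width
_T_AMP_FRAC = 0.28      # of r_amp_base
_T_OFFSET = 0.30        # s after R
_T_SIGMA = 0.050        # s

#: Earliest allowed VF onset (s); leaves room for the 150-to-30-s pre-onset window.
MIN_ONSET_TIME = 150.0


def generate_rr(params: GroupParams, duration: float, seed: int
                ) -> Tuple[RRSeries, SyntheticTruth]:
    """Generate an RR interval series covering at least ``duration`` seconds.

    Each interval is the group mean plus LF and HF sinusoidal modulation
    (evaluated at the beat time) plus i.i.d. Gaussian noise. Intervals are
    floored at 200 ms so pathological noise draws cannot produce
    non-physical non-positive intervals.

    Returns the series together with a :class:`SyntheticTruth` carrying the
    exact beat times and intervals.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = np.random.default_rng(seed)
    beat_times = [0.0]
    rr_ms: List[float] = []
    t = 0.0
    while t < duration:
        rr = (params.mean_rr
              + params.lf_mod_amp * np.sin(2 * np.pi * params.lf_mod_freq * t)
              + params.hf_mod_amp * np.sin(2 * np.pi * params.hf_mod_freq * t))
        if params.rr_noise_sd > 0:
            rr += rng.normal(0.0, params.rr_noise_sd)
        rr = max(float(rr), 200.0)
        t += rr / 1000.0
        beat_times.append(t)
        rr_ms.append(rr)
    beat_times = np.asarray(beat_times)
    rr_ms = np.asarray(rr_ms)
    series = RRSeries(rr=rr_ms, t=beat_times[1:])
    truth = SyntheticTruth(beat_times=beat_times, rr_true=rr_ms)
    return series, truth


def _gauss(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def synthesize_ecg(rr: RRSeries, params: GroupParams, fs: float, seed: int,
                   truth: Optional[SyntheticTruth] = None,
                   onset_time: Optional[float] = None,
                   record_id: str = "") -> Tuple[ECGRecord, SyntheticTruth]:
    """Render an ECG waveform from an RR series.

    Per-beat R amplitude is ``r_amp_base * (1 + r_amp_mod_depth *
    sin(2*pi*lf_mod_freq*t_i))``; per-beat QRS width is scaled by
    ``(1 + jitter)`` with ``jitter ~ N(0, area_jitter_sd^2)``; white
    measurement noise of SD ``ecg_noise_sd`` is added to every sample.

    The returned truth carries the analytic per-beat R amplitude and the
    discrete signed area of the QRS component (Q+R+S Gaussians summed over
    the samples within +-0.6 widths of the R peak), in uV*samples.
    """
    if fs < 100:
        raise InvalidParameterError("fs must be at least 100 Hz")
    if len(rr) == 0:
        raise InvalidParameterError("RR series is empty")
    rng = np.random.default_rng(seed)

    beat_times = (truth.beat_times if truth is not None
                  else np.concatenate([[rr.t[0] - rr.rr[0] / 1000.0], rr.t]))
    w0 = params.qrs_width / 1000.0
    n_samples = int(np.ceil((beat_times[-1] + 2 * _T_OFFSET) * fs))
    if n_samples < int(w0 * fs) + 1:
        raise InvalidParameterError("RR series shorter than one beat template")
    signal = np.zeros(n_samples)
    tgrid = np.arange(n_samples) / fs

    n_beats = beat_times.size
    amp_true = params.r_amp_base * (
        1.0 + params.r_amp_mod_depth
        * np.sin(2 * np.pi * params.lf_mod_freq * beat_times))
    jitter = rng.normal(0.0, params.area_jitter_sd, size=n_beats) \
        if params.area_jitter_sd > 0 else np.zeros(n_beats)
    widths = np.clip(w0 * (1.0 + jitter), 0.3 * w0, 3.0 * w0)

    area_true = np.zeros(n_beats)
    for i, (tc, a, w) in enumerate(zip(beat_times, amp_true, widths)):
        lo = max(0, int(np.floor((tc - 0.45) * fs)))
        hi = min(n_samples, int(np.ceil((tc + 0.55) * fs)))
        if hi <= lo:
            continue
        tt = tgrid[lo:hi]
        qrs = (_gauss(tt, tc + _Q_OFFSET_FRAC * w, _QS_SIGMA_FRAC * w, _Q_AMP_FRAC * a)
               + _gauss(tt, tc, _R_SIGMA_FRAC * w, a)
               + _gauss(tt, tc + _S_OFFSET_FRAC * w, _QS_SIGMA_FRAC * w, _S_AMP_FRAC * a))
        signal[lo:hi] += (
            qrs
            + _gauss(tt, tc + _P_OFFSET, _P_SIGMA, _P_AMP_FRAC * params.r_amp_base)
            + _gauss(tt, tc + _T_OFFSET, _T_SIGMA, _T_AMP_FRAC * params.r_amp_base))
        in_qrs = (tt >= tc - 0.6 * w) & (tt <= tc + 0.6 * w)
        area_true[i] = float(np.sum(qrs[in_qrs]))

    if params.ecg_noise_sd > 0:
        signal += rng.normal(0.0, params.ecg_noise_sd, size=n_samples)

    beat_indices = np.round(beat_times * fs).astype(np.int64)
    beat_indices = np.clip(beat_indices, 0, n_samples - 1)
    record = ECGRecord(samples=signal, fs=fs, beat_indices=beat_indices,
                       onset_time=onset_time, label=params.label,
                       record_id=record_id)
    out_truth = SyntheticTruth(
        beat_times=beat_times,
        rr_true=np.diff(beat_times) * 1000.0,
        r_amp_true=amp_true,
        qrs_area_true=area_true,
        onset_time=onset_time)
    return record, out_truth


def generate_record(params: GroupParams, duration: float, fs: float, seed: int,
                    onset_time: Optional[float] = None,
                    record_id: str = "") -> Tuple[ECGRecord, SyntheticTruth]:
    """Generate one labeled record end to end (RR series then waveform)."""
    rr, truth = generate_rr(params, duration, seed)
    return synthesize_ecg(rr, params, fs, seed=seed + 1, truth=truth,
                          onset_time=onset_time, record_id=record_id)


def _subject_params(params: GroupParams, rng: np.random.Generator) -> GroupParams:
    """Draw one subject's parameters around the group values.

    Lognormal multipliers (median 1) with coefficient of variation
    ``subject_cv_rr`` on the RR-variability parameters (a third of it on the
    mean interval) and ``subject_cv_qrs`` on the QRS-shape parameters.
    """
    kw = {}
    if params.subject_cv_rr > 0:
        s = float(np.sqrt(np.log1p(params.subject_cv_rr ** 2)))
        kw["lf_mod_amp"] = params.lf_mod_amp * float(np.exp(rng.normal(0, s)))
        kw["hf_mod_amp"] = params.hf_mod_amp * float(np.exp(rng.normal(0, s)))
        kw["rr_noise_sd"] = params.rr_noise_sd * float(np.exp(rng.normal(0, s)))
        kw["mean_rr"] = params.mean_rr * float(np.exp(rng.normal(0, s / 3)))
    if params.subject_cv_qrs > 0:
        s = float(np.sqrt(np.log1p(params.subject_cv_qrs ** 2)))
        kw["r_amp_base"] = params.r_amp_base * float(np.exp(rng.normal(0, s)))
        kw["r_amp_mod_depth"] = min(
            params.r_amp_mod_depth * float(np.exp(rng.normal(0, s))), 0.95)
        kw["area_jitter_sd"] = params.area_jitter_sd * float(np.exp(rng.normal(0, s)))
    return params.copy_with(**kw) if kw else params


@dataclass
class CohortRecord:
    """One generated record together with its ground truth."""

    record: ECGRecord
    truth: SyntheticTruth
    params: GroupParams  # the per-subject parameters actually used


def generate_cohort(n_vf: int, n_control: int,
                    vf_params: Optional[GroupParams] = None,
                    control_params: Optional[GroupParams] = None,
                    seed: int = 0, fs: float = 128.0,
                    duration: float = 170.0) -> List[CohortRecord]:
    """Generate a labeled two-group cohort of ECG records.

    VF-group records carry a VF-onset marker placed uniformly in
    ``[150 s, duration - 1 s]`` so the 120-s pre-onset analysis window
    always exists. The master seed fans out to independent per-record
    child seeds, so cohorts are bit-reproducible and records independent.
    """
    if n_vf < 1 or n_control < 1:
        raise InvalidParameterError("need at least one record per group")
    if duration < MIN_ONSET_TIME + 1.0:
        raise InvalidParameterError(
            f"duration must be at least {MIN_ONSET_TIME + 1.0:.0f} s so the "
            "pre-onset analysis window fits")
    if vf_params is None or control_params is None:
        preset_vf, preset_ctrl = preset_params("table2")
        vf_params = vf_params or preset_vf
        control_params = control_params or preset_ctrl

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_vf + n_control)
    out: List[CohortRecord] = []
    for i, child in enumerate(children):
        is_vf = i < n_vf
        group = vf_params if is_vf else control_params
        rng = np.random.default_rng(child)
        subj = _subject_params(group, rng)
        onset = float(rng.uniform(MIN_ONSET_TIME, duration - 1.0)) if is_vf else None
        rec_seed = int(rng.integers(0, 2 ** 31 - 1))
        label = VF if is_vf else CONTROL
        rid = f"{'vf' if is_vf else 'ctl'}{(i if is_vf else i - n_vf):03d}"
        record, truth = generate_record(
            subj.copy_with(label=label), duration=duration, fs=fs,
            seed=rec_seed, onset_time=onset, record_id=rid)
        out.append(CohortRecord(record=record, truth=truth, params=subj))
    return out


def preset_params(name: str) -> Tuple[GroupParams, GroupParams]:
    """Return ``(vf_params, control_params)`` for a named preset.

    ``table2``
        The default study conditions: VF-group RR variability roughly
        2-2.5x the control's, QRS amplitude/modulation roughly 2-4x, with
        between-subject scatter large on the HRV side (overlapping
        distributions) and modest on the QRS side (clearly separable).
    ``separable``
        Same group contrasts with little between-subject scatter; both
        feature families become nearly noise-free class separators.
    ``null``
        Both groups drawn from the control distribution (VF records still
        carry an onset marker); any detected group difference is spurious.
    """
    control = GroupParams(
        mean_rr=760.0, lf_mod_amp=12.0, lf_mod_freq=0.095,
        hf_mod_amp=10.0, hf_mod_freq=0.25, rr_noise_sd=20.0,
        r_amp_base=800.0, r_amp_mod_depth=0.05, qrs_width=80.0,
        area_jitter_sd=0.03, ecg_noise_sd=10.0, label=CONTROL,
        subject_cv_rr=0.45, subject_cv_qrs=0.15)
    vf = GroupParams(
        mean_rr=800.0, lf_mod_amp=28.0, lf_mod_freq=0.10,
        hf_mod_amp=22.0, hf_mod_freq=0.26, rr_noise_sd=48.0,
        r_amp_base=1600.0, r_amp_mod_depth=0.22, qrs_width=85.0,
        area_jitter_sd=0.12, ecg_noise_sd=10.0, label=VF,
        subject_cv_rr=0.45, subject_cv_qrs=0.15)
    if name == "table2":
        return vf, control
    if name == "separable":
        return (vf.copy_with(subject_cv_rr=0.10, subject_cv_qrs=0.05),
                control.copy_with(subject_cv_rr=0.10, subject_cv_qrs=0.05))
    if name == "null":
        return control.copy_with(label=VF), control
    raise InvalidParameterError(f"unknown preset {name!r}; "
                                "choose from table2, separable, null")


PRESET_NAMES = ("table2", "separable", "null")
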