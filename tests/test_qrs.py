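"""QRS detection, windowing, signed area and amplitude features."""

import numpy as np
import pytest

import vfforecast as vf
from vfforecast.qrs import (detect_r_peaks, per_beat_measures, qrs_shape_features,
                            qrs_window, r_amplitude, signed_area)
from vfforecast.types import QRSWindow

from oracles import naive_qrs_stats


def triangle_record(height=1000.0, base=20, fs=250.0, invert=False):
    """A flat record with one symmetric triangular pulse at its center."""
    n = int(4 * fs)
    x = np.zeros(n)
    center = n // 2
    half = base // 2
    for k in range(-half, half + 1):
        x[center + k] = height * (1 - abs(k) / half)
    if invert:
        x = -x
    return vf.ECGRecord(samples=x, fs=fs,
                        beat_indices=np.array([center])), center


class TestSignedArea:
    def test_triangle_matches_analytic_area(self):
        rec, center = triangle_record()
        w = QRSWindow(pq_index=center - 15, j_index=center + 15,
                      r_index=center, baseline=0.0)
        # analytic area of the triangle: h*w/2 = 1000*20/2
        assert signed_area(rec, w) == pytest.approx(10000.0, rel=0.02)

    def test_inverted_triangle_flips_the_sign(self):
        rec, center = triangle_record(invert=True)
        w = QRSWindow(pq_index=center - 15, j_index=center + 15,
                      r_index=center, baseline=0.0)
        assert signed_area(rec, w) == pytest.approx(-10000.0, rel=0.02)

    def test_all_baseline_window_is_zero(self):
        rec, _ = triangle_record()
        w = QRSWindow(pq_index=10, j_index=40, r_index=20, baseline=0.0)
        assert signed_area(rec, w) == 0.0

    def test_weight_kernel_hook(self):
        rec, center = triangle_record()
        w = QRSWindow(pq_index=center - 15, j_index=center + 15,
                      r_index=center, baseline=0.0)
        weights = np.zeros(31)
        assert signed_area(rec, w, weights=weights) == 0.0
        with pytest.raises(ValueError):
            signed_area(rec, w, weights=np.ones(5))


class TestRAmplitude:
    def test_triangle_peak(self):
        rec, center = triangle_record()
        w = QRSWindow(pq_index=center - 15, j_index=center + 15,
                      r_index=center, baseline=0.0)
        assert r_amplitude(rec, w) == pytest.approx(1000.0)

    def test_pure_baseline_window_is_zero(self):
        rec, _ = triangle_record()
        w = QRSWindow(pq_index=10, j_index=40, r_index=20, baseline=0.0)
        assert r_amplitude(rec, w) == 0.0

    def test_modulated_record_matches_truth(self):
        params = vf.GroupParams(r_amp_base=1000, r_amp_mod_depth=0.2,
                                ecg_noise_sd=0, area_jitter_sd=0,
                                rr_noise_sd=10)
        record, truth = vf.generate_record(params, 60, 250, seed=8)
        _, amps, windows = per_beat_measures(record)
        # match measured beats to truth beats by R index
        truth_by_idx = dict(zip(np.round(truth.beat_times * 250).astype(int),
                                truth.r_amp_true))
        pairs = [(a, truth_by_idx[w.r_index]) for a, w in zip(amps, windows)
                 if w.r_index in truth_by_idx]
        assert len(pairs) > 50
        got, want = map(np.asarray, zip(*pairs))
        rms = np.sqrt(np.mean((got - want) ** 2)) / np.mean(want)
        assert rms < 0.02


class TestShapeFeatures:
    def test_hand_computed_aggregates(self):
        f = qrs_shape_features([-100.0, 100.0], [500.0, 700.0])
        assert (f.qrsam, f.qrsasd) == (100.0, 0.0)
        assert (f.rpampm, f.rpampsd) == (600.0, 100.0)

    def test_identical_beats_have_zero_sd(self):
        f = qrs_shape_features([50.0] * 5, [900.0] * 5)
        assert f.qrsasd == 0.0 and f.rpampsd == 0.0

    def test_single_beat_rejected(self):
        with pytest.raises(vf.InsufficientDataError):
            qrs_shape_features([1.0], [1.0])

    def test_matches_naive_oracle_on_random_beats(self, rng):
        for _ in range(100):
            areas = rng.normal(0, 5000, size=100)
            amps = rng.normal(900, 150, size=100)
            f = qrs_shape_features(areas, amps)
            want = naive_qrs_stats(list(areas), list(amps))
            assert np.allclose((f.qrsam, f.qrsasd, f.rpampm, f.rpampsd),
                               want, rtol=1e-9)

    def test_scaling_record_scales_all_features(self):
        params = vf.GroupParams(ecg_noise_sd=0, rr_noise_sd=10)
        record, _ = vf.generate_record(params, 40, 250, seed=3)
        f1 = vf.qrs_features(record)
        f3 = vf.qrs_features(record.copy_with(samples=record.samples * 3.0))
        for a, b in zip(f1.to_dict().values(), f3.to_dict().values()):
            assert b == pytest.approx(3.0 * a, rel=1e-9)

    def test_polarity_flip_preserves_area_mean_not_amplitude_mean(self):
        params = vf.GroupParams(ecg_noise_sd=0, rr_noise_sd=10)
        record, _ = vf.generate_record(params, 40, 250, seed=3)
        flipped = record.copy_with(samples=-record.samples)
        f = vf.qrs_features(record)
        g = vf.qrs_features(flipped)
        assert g.qrsam == pytest.approx(f.qrsam, rel=0.05)
        assert g.rpampm < 0.5 * f.rpampm


class TestDetection:
    def test_annotated_records_return_annotations_verbatim(self, clean_record):
        record, _ = clean_record
        assert np.array_equal(detect_r_peaks(record), record.beat_indices)

    def test_noise_free_detection_within_one_sample(self):
        params = vf.GroupParams(mean_rr=800, rr_noise_sd=20, ecg_noise_sd=0,
                                r_amp_base=1000)
        record, truth = vf.generate_record(params, 130, 250, seed=5)
        record = record.copy_with(beat_indices=np.array([], dtype=np.int64),
                                  onset_time=None)
        detected = detect_r_peaks(record, use_annotations=False)
        true_idx = np.round(truth.beat_times * 250).astype(int)
        interior = true_idx[(true_idx > 250) & (true_idx < record.samples.size - 250)]
        hits = sum(np.min(np.abs(detected - t)) <= 1 for t in interior)
        assert interior.size >= 150
        assert hits / interior.size >= 0.99

    def test_flat_signal_warns_and_returns_empty(self):
        rec = vf.ECGRecord(samples=np.zeros(2000), fs=250.0)
        with pytest.warns(UserWarning):
            out = detect_r_peaks(rec, use_annotations=False)
        assert out.size == 0


class TestWindowing:
    def test_gaussian_qrs_window_width(self, clean_record):
        record, _ = clean_record
        fs = record.fs
        for b in record.beat_indices[2:-2]:
            w = qrs_window(record, int(b))
            width_ms = (w.j_index - w.pq_index) / fs * 1000.0
            assert 60.0 <= width_ms <= 160.0

    def test_edge_beat_skipped(self, clean_record):
        record, _ = clean_record
        rec = record.copy_with(
            beat_indices=np.array([2], dtype=np.int64))
        assert qrs_window(rec, 2) is None

    def test_fallback_offsets_when_no_slope_structure(self):
        # a perfectly flat record has no steep-then-flat transition, so the
        # boundary search fails and the fixed +-60 ms fallback applies
        fs = 250.0
        rec = vf.ECGRecord(samples=np.zeros(2000), fs=fs,
                           beat_indices=np.array([1000]))
        w = qrs_window(rec, 1000)
        assert w.pq_index == 1000 - 15 and w.j_index == 1000 + 15  # 60 ms = 15 samples

    def test_square_pulse_window_brackets_the_pulse(self):
        fs = 250.0
        x = np.zeros(2000)
        x[990:1010] = 1000.0
        rec = vf.ECGRecord(samples=x, fs=fs, beat_indices=np.array([1000]))
        w = qrs_window(rec, 1000)
        assert w.pq_index <= 990 and w.j_index >= 1009
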