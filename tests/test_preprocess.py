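"""Preprocessing: QRS detection accuracy on seeded fixtures, window
segmentation arithmetic, Fourier resampling identities, normalization."""

import numpy as np
import pytest

from beatbench.core import Beat, BeatSet, RawRecord
from beatbench.preprocess import (
    detect_r_peaks,
    normalize_beats,
    resample_beat,
    resample_beatset,
    segment_beats,
)
from beatbench.simulate import get_preset, synth_record


def _match(detected, truth, fs, tol_s=0.05):
    tol = int(round(tol_s * fs))
    hits = sum(1 for t in truth if any(abs(d - t) <= tol for d in detected))
    return hits


class TestDetectRPeaks:
    def test_low_noise_record_all_peaks_within_50ms(self):
        rec = synth_record(get_preset("normal_v1"), 10, 360.0, 0.8, 0.0, seed=3, noise_sd=0.01)
        det = detect_r_peaks(rec)
        assert len(det) == 10
        assert _match(det, rec.true_r_peaks, 360.0) == 10
        assert all(b - a >= int(0.2 * 360) for a, b in zip(det, det[1:]))

    def test_zero_signal_returns_empty(self):
        rec = RawRecord(np.zeros(3600), 360.0)
        assert detect_r_peaks(rec) == []

    def test_short_signal_raises_with_required_length(self):
        rec = RawRecord(np.random.default_rng(0).standard_normal(100), 360.0)
        with pytest.raises(ValueError, match="720"):
            detect_r_peaks(rec)

    def test_moderate_noise_30_beats_at_72_bpm(self):
        rec = synth_record(get_preset("normal_v1"), 30, 360.0, 60 / 72, 0.03,
                           seed=5, noise_sd=0.05)
        det = detect_r_peaks(rec)
        hits = _match(det, rec.true_r_peaks, 360.0)
        assert hits >= 28
        assert len(det) - hits <= 1  # at most one false positive

    @pytest.mark.parametrize("seed", [11, 17, 23])
    def test_recall_and_precision_above_090_on_seeded_records(self, seed):
        rec = synth_record(get_preset("normal_v1"), 20, 360.0, 0.85, 0.02,
                           seed=seed, noise_sd=0.05)
        det = detect_r_peaks(rec)
        hits = _match(det, rec.true_r_peaks, 360.0)
        assert hits / len(rec.true_r_peaks) >= 0.9
        assert hits / max(len(det), 1) >= 0.9


class TestSegmentBeats:
    def test_edge_peaks_are_dropped(self):
        rec = RawRecord(np.arange(2000, dtype=float), 360.0)
        # peak 1900 would end at 2040 (right edge); peak 100 would start at
        # -40 (left edge); only the centered peak survives
        got = segment_beats(rec, [100, 500, 1900], (140, 140))
        assert got.count == 1
        got = segment_beats(rec, [200, 500, 1900], (140, 140))
        assert got.count == 2

    def test_single_centered_peak_gives_280_samples(self):
        rec = RawRecord(np.ones(1000), 360.0)
        got = segment_beats(rec, [500], (140, 140))
        assert got.count == 1 and got.beat_len == 280

    def test_peak_at_origin_window_exits_left(self):
        rec = RawRecord(np.ones(1000), 360.0)
        assert segment_beats(rec, [0], (140, 140)).count == 0

    def test_empty_peaks_and_oversized_window(self):
        rec = RawRecord(np.ones(300), 360.0)
        assert segment_beats(rec, [], (140, 140)).count == 0
        with pytest.raises(ValueError):
            segment_beats(rec, [150], (200, 200))

    def test_beats_carry_annotation_labels(self):
        rec = RawRecord(np.ones(1000), 360.0, annotations=[(300, "N"), (600, "L")])
        got = segment_beats(rec, [302, 598], (140, 140))
        assert got.labels == ["N", "L"]

    def test_windows_are_half_open(self):
        sig = np.arange(600, dtype=float)
        rec = RawRecord(sig, 360.0)
        got = segment_beats(rec, [300], (2, 3))
        np.testing.assert_array_equal(got.data[0], [298, 299, 300, 301, 302])


class TestResample:
    def test_constant_beat_is_preserved(self):
        out = resample_beat(Beat(np.full(280, 0.7)), 256)
        assert len(out) == 256
        np.testing.assert_allclose(out.samples, 0.7, atol=1e-9)

    def test_full_period_sinusoid_matches_analytic_form(self):
        x = np.sin(2 * np.pi * np.arange(280) / 280)
        out = resample_beat(Beat(x), 256)
        expected = np.sin(2 * np.pi * np.arange(256) / 256)
        assert np.max(np.abs(out.samples - expected)) < 1e-6

    def test_same_length_is_identity(self):
        x = np.random.default_rng(1).standard_normal(256)
        out = resample_beat(Beat(x), 256)
        np.testing.assert_array_equal(out.samples, x)

    def test_linearity(self, rng):
        x, y = rng.standard_normal(280), rng.standard_normal(280)
        a, b = 2.5, -1.25
        lhs = resample_beat(Beat(a * x + b * y), 256).samples
        rhs = a * resample_beat(Beat(x), 256).samples + b * resample_beat(Beat(y), 256).samples
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_polyphase_option_matches_length(self):
        x = np.random.default_rng(2).standard_normal(280)
        assert len(resample_beat(Beat(x), 256, method="polyphase")) == 256

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            resample_beat(Beat(np.ones(10)), 1)
        with pytest.raises(ValueError):
            Beat(np.array([np.inf, 1.0]))


class TestNormalize:
    def test_per_beat_affine_map(self):
        got = normalize_beats(BeatSet(np.array([[-2.0, 0.0, 2.0]])), "per_beat_minmax")
        np.testing.assert_allclose(got.data[0], [-1, 0, 1])

    def test_global_affine_map(self):
        got = normalize_beats(BeatSet(np.array([[0.0, 1.0], [0.0, 4.0]])), "global_minmax")
        np.testing.assert_allclose(got.data, [[-1.0, -0.5], [-1.0, 1.0]])

    def test_already_normalized_beat_unchanged(self):
        data = np.array([[-1.0, 0.25, 1.0]])
        got = normalize_beats(BeatSet(data), "per_beat_minmax")
        np.testing.assert_allclose(got.data, data, atol=1e-15)

    @pytest.mark.parametrize("mode", ["per_beat_minmax", "global_minmax"])
    def test_idempotence(self, mode, rng):
        beats = BeatSet(rng.standard_normal((5, 30)))
        once = normalize_beats(beats, mode)
        twice = normalize_beats(once, mode)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_constant_beat_error_names_index(self):
        data = np.vstack([np.arange(4.0), np.full(4, 3.0)])
        with pytest.raises(ValueError, match="index 1"):
            normalize_beats(BeatSet(data), "per_beat_minmax")


def test_segment_resample_pipeline_yields_uniform_finite_beats():
    rec = synth_record(get_preset("normal_v1"), 12, 360.0, 0.8, 0.02, seed=9)
    beats = segment_beats(rec, detect_r_peaks(rec), (140, 140))
    out = resample_beatset(beats, 256)
    assert out.count >= 10
    assert out.beat_len == 256
    assert np.all(np.isfinite(out.data))
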