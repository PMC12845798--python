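"""Filtering, resampling, R-peak labelling, windowing and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcgfusion.preprocessing import (PreprocessConfig, bandpass,
                                     detect_r_peaks, exclude_outliers,
                                     hr_from_window, interpolate_missing,
                                     preprocess_record, r_peak_times,
                                     resample_to_target, segment_windows,
                                     zscore)
from bcgfusion.records import SignalRecord, WindowedSample
from bcgfusion.simulate import NoiseSpec, generate_beat_times, synthesize_record


class TestBandpass:
    def test_dc_removed(self):
        x = np.full(2000, 3.7)
        y = bandpass(x, 100.0, 0.3, 24.0)
        assert np.max(np.abs(y[200:-200])) < 1e-3

    def test_in_band_sine_preserved(self):
        # oracle: FFT amplitude at 5 Hz before/after
        fs, f0 = 100.0, 5.0
        t = np.arange(4000) / fs
        y = bandpass(np.sin(2 * np.pi * f0 * t), fs, 0.3, 24.0)
        spec = np.abs(np.fft.rfft(y)) / (len(y) / 2)
        amp = spec[int(f0 * len(y) / fs)]
        assert abs(amp - 1.0) < 0.05

    def test_out_of_band_sine_attenuated_20db(self):
        fs, f0 = 100.0, 40.0
        t = np.arange(4000) / fs
        y = bandpass(np.sin(2 * np.pi * f0 * t), fs, 0.3, 24.0)
        spec = np.abs(np.fft.rfft(y)) / (len(y) / 2)
        amp = spec[int(f0 * len(y) / fs)]
        assert 20 * np.log10(amp / 1.0) < -20

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 100.0, 0.3, 60.0)


class TestResample:
    def test_length_arithmetic_1khz_to_100hz(self):
        out = resample_to_target(np.zeros(10000), 1000.0, 100.0)
        assert out.shape[0] == 1000

    def test_tone_survives_downsampling(self):
        fs_in, f0 = 1000.0, 2.0
        t = np.arange(20000) / fs_in
        y = resample_to_target(np.sin(2 * np.pi * f0 * t), fs_in, 100.0)
        spec = np.abs(np.fft.rfft(y))
        peak_hz = np.argmax(spec) * 100.0 / len(y)
        assert abs(peak_hz - f0) < 0.1

    def test_identity_when_rates_match(self):
        x = np.random.default_rng(0).normal(size=500)
        np.testing.assert_array_equal(resample_to_target(x, 100.0, 100.0), x)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_to_target(np.zeros(100), 50.0, 100.0)


class TestInterpolateMissing:
    def test_midpoint(self):
        np.testing.assert_allclose(
            interpolate_missing(np.array([1.0, np.nan, 3.0])), [1, 2, 3])

    def test_edge_fill_nearest(self):
        np.testing.assert_allclose(
            interpolate_missing(np.array([np.nan, 5.0, 5.0])), [5, 5, 5])

    def test_line_reconstructed_exactly(self):
        rng = np.random.default_rng(8)
        t = np.arange(200.0)
        y = 0.37 * t + 2.0
        mask = rng.random(200) < 0.05
        mask[[0, -1]] = False
        ym = y.copy()
        ym[mask] = np.nan
        np.testing.assert_allclose(interpolate_missing(ym), y, atol=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            interpolate_missing(np.full(10, np.nan))


class TestRPeaks:
    def test_flat_signal_gives_no_peaks(self):
        assert detect_r_peaks(np.zeros(1000), 100.0).size == 0

    def test_clean_60bpm_finds_ten_peaks_within_10ms(self):
        beats = generate_beat_times(10.0, 60.0, seed=0)
        rec = synthesize_record(beats, fs=100.0, noise=NoiseSpec.silent(),
                                duration_s=10.0)
        times = r_peak_times(rec.ecg, 100.0)
        assert times.size == 10
        assert np.max(np.abs(times - beats.beat_times)) < 0.010

    def test_refractory_keeps_larger_of_two_close_spikes(self):
        fs = 100.0
        ecg = np.zeros(1000)
        t = np.arange(1000) / fs
        for tc, amp in ((3.0, 0.6), (3.1, 1.0), (5.0, 1.0)):
            ecg += amp * np.exp(-0.5 * ((t - tc) / 0.01) ** 2)
        peaks = detect_r_peaks(ecg, fs, refractory_s=0.25)
        assert np.min(np.diff(peaks)) >= 0.25 * fs
        # the 3.1 s spike (larger) survives, the 3.0 s one does not
        assert np.any(np.abs(peaks - 310) <= 2)
        assert not np.any(np.abs(peaks - 300) <= 2)

    def test_indices_strictly_increasing_and_spaced(self):
        beats = generate_beat_times(30.0, 110.0, hrv_sd=0.03, seed=5)
        rec = synthesize_record(beats, fs=100.0, noise=NoiseSpec.silent(),
                                duration_s=30.0)
        peaks = detect_r_peaks(rec.ecg, 100.0, refractory_s=0.25)
        assert np.all(np.diff(peaks) >= 25)


class TestHrFromWindow:
    @pytest.mark.parametrize("peaks,expected", [
        ([0.0, 0.8, 1.6, 2.4, 3.2], 75.0),
        ([0.0, 1.0, 2.0, 3.0], 60.0),
        ([0.0, 0.7, 1.5, 2.4], 75.0),   # RR = [0.7, 0.8, 0.9], mean 0.8
    ])
    def test_mean_rr_arithmetic(self, peaks, expected):
        assert hr_from_window(np.array(peaks)) == pytest.approx(expected)

    def test_fewer_than_two_peaks_unlabeled(self):
        assert hr_from_window(np.array([1.0])) is None


def _record_of_length(n, fs=100.0, hr=72.0):
    beats = generate_beat_times(max(n / fs, 1.0), hr, seed=0)
    rec = synthesize_record(beats, fs=fs, noise=NoiseSpec.silent(),
                            duration_s=n / fs)
    return rec


class TestSegmentation:
    def test_ten_second_record_gives_seven_windows(self):
        rec = _record_of_length(1000)
        windows = segment_windows(rec)
        assert len(windows) == 7
        np.testing.assert_allclose([w.t_start for w in windows],
                                   np.arange(7.0))

    @pytest.mark.parametrize("n,expected", [(400, 1), (390, 0)])
    def test_boundary_lengths(self, n, expected):
        rec = _record_of_length(n)
        assert len(segment_windows(rec)) == expected

    @given(n=st.integers(min_value=100, max_value=6000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_window_count_formula(self, n):
        """count = floor((N/fs - window)/stride) + 1 (when >= one window)."""
        cfg = PreprocessConfig()
        fs = cfg.fs_target
        rec = SignalRecord("s", fs, np.zeros((n, 4)), np.zeros(n), np.zeros(n))
        windows = segment_windows(rec, cfg,
                                  peak_times=np.arange(0.5, n / fs, 0.8))
        dur = n / fs
        expected = 0 if dur < 4.0 else int(np.floor((dur - 4.0) / 1.0)) + 1
        # every window carries >= 2 peaks here, so none are dropped
        assert len(windows) == expected

    def test_constant_72bpm_labels(self, clean_record_72bpm):
        windows = segment_windows(clean_record_72bpm)
        assert windows
        for w in windows:
            assert abs(w.hr_bpm - 72.0) < 0.5


class TestExclusionAndZscore:
    def test_inclusive_bounds_on_documented_label_list(self):
        labels = [34.9, 35.0, 75.0, 120.0, 120.1]
        samples = [WindowedSample(np.zeros((400, 4)), np.zeros((400, 1)),
                                  hr, "s", float(i))
                   for i, hr in enumerate(labels)]
        kept = exclude_outliers(samples)
        assert [s.hr_bpm for s in kept] == [35.0, 75.0, 120.0]

    def test_in_range_labels_identity(self):
        samples = [WindowedSample(np.zeros((400, 4)), np.zeros((400, 1)),
                                  hr, "s", 0.0) for hr in (40.0, 80.0, 110.0)]
        assert exclude_outliers(samples) == samples

    def test_zscore_toy_example_population_sigma(self):
        out = zscore(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_zscore_constant_input_is_zeros(self):
        np.testing.assert_array_equal(zscore(np.full(400, 5.0)), 0.0)

    def test_zscore_idempotent(self):
        x = np.random.default_rng(3).normal(2.0, 7.0, 400)
        once = zscore(x)
        np.testing.assert_allclose(zscore(once), once, atol=1e-9)

    def test_zscore_moments(self):
        x = np.random.default_rng(4).normal(5.0, 3.0, (400, 4))
        z = zscore(x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-6)


class TestPipeline:
    def test_emitted_windows_satisfy_invariants(self):
        beats = generate_beat_times(30.0, 80.0, hrv_sd=0.02, seed=9)
        rec = synthesize_record(beats, fs=100.0, ptt_s=0.2,
                                noise=NoiseSpec(seed=9), duration_s=30.0)
        windows = preprocess_record(rec)
        assert windows
        for w in windows:
            assert w.bcg.shape == (400, 4)
            assert w.ppg.shape == (400, 1)
            assert 35.0 <= w.hr_bpm <= 120.0
            for ch in range(4):
                col = w.bcg[:, ch]
                assert abs(col.mean()) < 1e-6
                assert abs(col.std() - 1.0) < 1e-6

    def test_1khz_record_resampled_and_windowed(self):
        beats = generate_beat_times(12.0, 60.0, seed=2)
        rec = synthesize_record(beats, fs=1000.0, ptt_s=0.2,
                                noise=NoiseSpec.silent(), duration_s=12.0)
        windows = preprocess_record(rec)
        assert len(windows) == 9
        assert windows[0].bcg.shape == (400, 4)
        for w in windows:
            assert abs(w.hr_bpm - 60.0) < 0.5

    def test_nan_gaps_are_repaired(self):
        beats = generate_beat_times(20.0, 70.0, seed=3)
        rec = synthesize_record(beats, fs=100.0, noise=NoiseSpec.silent(),
                                duration_s=20.0)
        rec.bcg[500:505, 2] = np.nan
        rec.ppg[300:303, 0] = np.nan
        windows = preprocess_record(rec)
        assert windows
        assert all(np.isfinite(w.bcg).all() and np.isfinite(w.ppg).all()
                   for w in windows)

    def test_record_scope_zscore_alternative(self):
        beats = generate_beat_times(20.0, 70.0, seed=4)
        rec = synthesize_record(beats, fs=100.0, noise=NoiseSpec.silent(),
                                duration_s=20.0)
        cfg = PreprocessConfig(zscore_scope="record")
        windows = preprocess_record(rec, cfg)
        assert windows
        # whole-record normalization: individual windows are not re-centred
        means = np.array([w.ppg.mean() for w in windows])
        assert np.any(np.abs(means) > 1e-6)
        with pytest.raises(ValueError):
            PreprocessConfig(zscore_scope="subject")

    def test_noise_free_label_error_below_half_bpm(self, clean_record_72bpm):
        windows = preprocess_record(clean_record_72bpm)
        rec = clean_record_72bpm
        for w in windows:
            truth = rec.beat_times[(rec.beat_times >= w.t_start)
                                   & (rec.beat_times < w.t_start + 4.0)]
            hr_true = 60.0 / np.mean(np.diff(truth))
            assert abs(w.hr_bpm - hr_true) < 0.5
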