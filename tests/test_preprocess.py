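"""Filtering, fiducial detection, R-R cleaning, SQI masking,
imputation and sub-window tiling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from preshock.preprocess import (PreprocessingError, abp_quality_mask,
                                 bandpass_ecg, clean_rr_intervals,
                                 detect_breath_cycles, detect_r_peaks,
                                 fill_short_gaps, impute_chained,
                                 rolling_subwindows)

FS = 125.0


def _sine(freq, fs=FS, seconds=30):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def _attenuation_db(freq):
    x = _sine(freq)
    y = bandpass_ecg(x, FS)
    core = slice(int(5 * FS), int(25 * FS))  # avoid filter edges
    return 20 * np.log10(np.std(y[core]) / np.std(x[core]))


class TestBandpass:
    def test_stopband_and_passband_response(self):
        assert _attenuation_db(1.0) <= -20.0
        assert _attenuation_db(10.0) >= -3.0

    def test_dc_removed_and_length_preserved(self):
        x = np.full(1000, 3.7)
        y = bandpass_ecg(x, FS)
        assert y.shape == x.shape
        assert np.abs(y).max() < 1e-6

    def test_rate_too_low_raises(self):
        with pytest.raises(PreprocessingError):
            bandpass_ecg(np.zeros(100), 80.0)


def _spike_train(times_s, fs=FS, seconds=30):
    x = np.zeros(int(seconds * fs))
    idx = np.rint(np.asarray(times_s) * fs).astype(int)
    x[idx] = 1.0
    return x


class TestRPeaks:
    def test_exact_rr_on_60_bpm_train(self):
        times = np.arange(1, 29)  # 60 bpm
        beats = detect_r_peaks(_spike_train(times), FS)
        assert beats.peak_times.size == 28
        np.testing.assert_allclose(beats.rr_ms, 1000.0, atol=1000 / FS)

    def test_missing_spike_yields_double_interval(self):
        times = [t for t in range(1, 29) if t != 14]
        beats = detect_r_peaks(_spike_train(times), FS)
        assert (np.abs(beats.rr_ms - 2000) < 20).sum() == 1

    def test_flat_signal_raises(self):
        with pytest.raises(PreprocessingError):
            detect_r_peaks(np.zeros(1000), FS)


class TestCleanRR:
    def test_interpolates_out_of_range_interval(self):
        out = clean_rr_intervals(np.array([800.0, 2000.0, 820.0]))
        np.testing.assert_allclose(out, [800.0, 810.0, 820.0])

    def test_valid_series_untouched_and_idempotent(self):
        rr = np.array([700.0, 900.0, 1100.0, 640.0])
        np.testing.assert_array_equal(clean_rr_intervals(rr), rr)

    def test_all_invalid_raises(self):
        with pytest.raises(PreprocessingError):
            clean_rr_intervals(np.array([300.0, 300.0, 300.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(100, 3000), min_size=3, max_size=40))
    def test_idempotent_and_in_bounds(self, rr):
        rr = np.asarray(rr)
        if not ((rr > 400) & (rr < 1500)).any():
            return
        once = clean_rr_intervals(rr)
        np.testing.assert_array_equal(clean_rr_intervals(once), once)
        assert once.min() > 400 - 1e-9 and once.max() < 1500 + 1e-9


def _pulse_train(fs=FS, seconds=10, sbp=120.0, dbp=70.0, hr=75):
    t = np.arange(int(seconds * fs)) / fs
    period = 60.0 / hr
    phase = (t % period) / period
    shape = np.where(phase < 0.3, phase / 0.3, np.exp(-(phase - 0.3) / 0.35))
    return dbp + (sbp - dbp) * shape


class TestSqiMask:
    def test_clean_pulse_train_fully_valid(self):
        assert abp_quality_mask(_pulse_train(), FS).all()

    def test_flatline_span_invalid(self):
        x = _pulse_train()
        x[int(3 * FS) : int(5 * FS)] = 0.0
        mask = abp_quality_mask(x, FS)
        assert not mask[int(3.25 * FS) : int(4.75 * FS)].any()

    def test_single_spike_invalidates_exactly_its_window(self):
        x = _pulse_train()
        w = int(0.5 * FS)
        spike = int(4.1 * FS)
        x[spike] = 400.0
        mask = abp_quality_mask(x, FS)
        block = spike // w
        assert not mask[block * w : (block + 1) * w].any()
        assert mask[: block * w].all() and mask[(block + 1) * w :].all()


def _breath_wave(rate_bpm=12, fs=25.0, seconds=60, symmetric=True):
    t = np.arange(int(seconds * fs)) / fs
    f = rate_bpm / 60.0
    if symmetric:
        return 1 - np.cos(2 * np.pi * f * t)  # troughs at cycle boundaries
    return None


class TestBreathDetection:
    def test_count_matches_truth_on_sinusoid(self):
        breaths = detect_breath_cycles(_breath_wave(), 25.0)
        assert breaths.n_cycles == 12

    def test_symmetric_cycles_have_equal_rise_decay(self):
        breaths = detect_breath_cycles(_breath_wave(), 25.0)
        np.testing.assert_allclose(breaths.rise_times, breaths.decay_times,
                                   atol=2 / 25.0)

    def test_amplitude_modulation_recovered(self):
        fs, f = 25.0, 0.25
        t = np.arange(int(80 * fs)) / fs
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * t / 40.0)
        x = envelope * (1 - np.cos(2 * np.pi * f * t))
        breaths = detect_breath_cycles(x, fs)
        expected = 2.0 * envelope[np.rint(breaths.t_peak * fs).astype(int)]
        np.testing.assert_allclose(breaths.amplitudes + breaths.decay_amplitudes,
                                   2 * expected, rtol=0.15)

    def test_noise_robust_count_within_5pct(self):
        rng = np.random.default_rng(0)
        x = _breath_wave(seconds=120)
        snr10 = np.std(x) / np.sqrt(10)
        noisy = x + rng.standard_normal(x.size) * snr10
        breaths = detect_breath_cycles(noisy, 25.0)
        assert abs(breaths.n_cycles - 24) <= max(1, 0.05 * 24)

    def test_flat_raises(self):
        with pytest.raises(PreprocessingError):
            detect_breath_cycles(np.zeros(500), 25.0)


class TestGapsFill:
    def test_short_gap_interpolated_long_gap_kept(self):
        x = np.arange(100.0)
        mask = np.ones(100, bool)
        mask[10:12] = False  # 2 samples at 1 Hz = 2 s (boundary: filled)
        mask[50:60] = False  # 10 s gap stays
        filled, out_mask = fill_short_gaps(x, mask, fs=1.0, max_gap_s=2.0)
        assert out_mask[10:12].all()
        np.testing.assert_allclose(filled[10:12], [10.0, 11.0])
        assert not out_mask[50:60].any()


class TestImpute:
    def test_identity_without_missing(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 4)),
                          columns=list("abcd"))
        pd.testing.assert_frame_equal(impute_chained(df, seed=1), df)

    def test_collinear_column_recovers_linear_prediction(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        df = pd.DataFrame({"a": a, "b": 2.0 * a + 1.0, "c": rng.normal(size=40)})
        df.loc[7, "b"] = np.nan
        out = impute_chained(df, seed=2)
        assert out.loc[7, "b"] == pytest.approx(2.0 * a[7] + 1.0, abs=0.05)
        # observed cells untouched
        obs = df["b"].drop(7)
        pd.testing.assert_series_equal(out["b"].drop(7), obs)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        df.iloc[3, 1] = np.nan
        df.iloc[11, 4] = np.nan
        pd.testing.assert_frame_equal(impute_chained(df, seed=3),
                                      impute_chained(df, seed=3))

    def test_fully_missing_column_raises(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(PreprocessingError):
            impute_chained(df)


class TestRollingSubwindows:
    def test_30min_gives_5_overlapping_subwindows(self):
        subs = rolling_subwindows(0.0, 1800.0)
        assert len(subs) == 5
        assert subs == [(0.0, 600.0), (300.0, 900.0), (600.0, 1200.0),
                        (900.0, 1500.0), (1200.0, 1800.0)]

    def test_exact_10min_gives_one(self):
        assert rolling_subwindows(0.0, 600.0) == [(0.0, 600.0)]

    def test_too_short_raises(self):
        with pytest.raises(PreprocessingError):
            rolling_subwindows(0.0, 540.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0, 1e5), st.integers(2, 12))
    def test_tiling_covers_window_with_5min_overlaps(self, start, halves):
        end = start + halves * 300.0
        if end - start < 600.0:
            return
        subs = rolling_subwindows(start, end)
        assert subs[0][0] == start
        assert subs[-1][1] == pytest.approx(end)
        for (a0, a1), (b0, b1) in zip(subs[:-1], subs[1:]):
            assert b0 - a0 == pytest.approx(300.0)
            assert a1 - b0 == pytest.approx(300.0)  # 5-min overlap
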