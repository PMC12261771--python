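"""The 299-feature catalog: cardinalities, naming, hand-computed
values and degenerate-input behavior."""

import numpy as np
import pytest

from preshock.catalog import STAT_NAMES, catalog
from preshock.complexity import (central_tendency_measure,
                                 lempel_ziv_complexity, sample_entropy)
from preshock.features import (extract_abp_features, extract_ecg_features,
                               extract_resp_features, extract_spo2_features,
                               extract_subwindow, extract_window, hrv_features,
                               stat_battery)
from preshock.labeling import AnalysisWindow
from preshock.records import Channel, Covariates, WaveformRecord


class TestCatalog:
    def test_cardinalities(self):
        c = catalog()
        assert len(c.abp) == 90
        assert len(c.ecg) == 89
        assert len(c.resp) == 112
        assert len(c.spo2) == 8
        assert len(c.names) == 299
        assert len(set(c.names)) == 299

    def test_repeated_calls_identical(self):
        assert catalog() is catalog()

    def test_reported_headline_features_present(self):
        names = set(catalog().names)
        for f in ("ECG_HRV_pNN50", "RESP_Width_Mean", "RESP_Cycle_Rate_Mean",
                  "ABP_TimeSBP2DBP_SampEn", "ABP_AmplitudeDBP_Median",
                  "ABP_Psys_Median", "ABP_MeanAP_Mean", "ABP_PP_Max",
                  "ECG_HRV_MCVNN", "RESP_RRV_MeanBB",
                  "RESP_RRV_MFDFA_Alpha1_Peak",
                  "RESP_Cycle_Symmetry_RiseDecay_Max"):
            assert f in names, f


class TestStatBattery:
    def test_exactly_ten_outputs_in_catalog_order(self):
        out = stat_battery(np.arange(10.0))
        assert list(out) == list(STAT_NAMES)

    def test_constant_series_fallbacks(self):
        out = stat_battery(np.full(50, 7.0))
        assert out["Min"] == out["Mean"] == out["Max"] == out["Median"] == 7.0
        assert out["STD"] == 0.0 and out["Skewness"] == 0.0
        assert out["Kurtosis"] == 0.0 and out["SampEn"] == 0.0

    def test_hand_computed_moments(self):
        out = stat_battery(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert out["Mean"] == 3.0 and out["Median"] == 3.0
        assert out["STD"] == pytest.approx(np.sqrt(2.0))
        assert out["Skewness"] == 0.0
        assert out["Kurtosis"] == pytest.approx(-1.3)

    def test_empty_series_gives_ten_missing_markers(self):
        out = stat_battery(np.array([]))
        assert len(out) == 10 and all(np.isnan(v) for v in out.values())


def _pulse_train(fs=62.5, seconds=120, sbp_seq=None, dbp=70.0, period=0.8):
    """Deterministic pulse train with known per-beat systolic values."""
    n_beats = int(seconds / period)
    sbp_seq = np.full(n_beats, 120.0) if sbp_seq is None else np.resize(sbp_seq, n_beats)
    t = np.arange(int(seconds * fs)) / fs
    k = np.minimum((t / period).astype(int), n_beats - 1)
    phase = t / period - k
    shape = np.where(phase < 0.3, phase / 0.3,
                     (np.exp(-(phase - 0.3) / 0.35) - np.exp(-2.0))
                     / (1 - np.exp(-2.0)))
    return dbp + (sbp_seq[k] - dbp) * shape


class TestAbpFeatures:
    def test_cardinality_and_missing_markers_on_empty(self):
        out = extract_abp_features(np.array([]), np.array([], bool), 62.5)
        assert len(out) == 90
        assert all(np.isnan(v) for v in out.values())

    def test_periodic_identical_beats(self):
        x = _pulse_train()
        out = extract_abp_features(x, np.ones(x.size, bool), 62.5)
        assert len(out) == 90
        assert out["ABP_AmplitudeSBP_Median"] == pytest.approx(0.0, abs=0.3)
        assert out["ABP_TimeSBP2DBP_STD"] == pytest.approx(0.0, abs=0.03)
        assert out["ABP_Psys_Median"] == pytest.approx(120.0, abs=1.5)
        assert out["ABP_Pdia_Median"] == pytest.approx(70.0, abs=1.5)
        assert out["ABP_HR_Mean"] == pytest.approx(75.0, abs=1.0)

    def test_alternating_sbp_gives_median_amplitude_10(self):
        x = _pulse_train(sbp_seq=np.array([120.0, 130.0]))
        out = extract_abp_features(x, np.ones(x.size, bool), 62.5)
        assert out["ABP_AmplitudeSBP_Median"] == pytest.approx(10.0, abs=0.8)

    def test_map_formula_and_meanap_are_distinct(self):
        x = _pulse_train()
        out = extract_abp_features(x, np.ones(x.size, bool), 62.5)
        pp = out["ABP_PP_Median"]
        assert out["ABP_MAP_Median"] == pytest.approx(
            out["ABP_Pdia_Median"] + pp / 3.0, abs=0.5)
        assert abs(out["ABP_MAP_Median"] - out["ABP_MeanAP_Median"]) > 0.5


class TestEcgFeatures:
    def test_cardinality_89(self):
        rr = 800 + 50 * np.sin(np.arange(600) / 5.0)
        out = hrv_features(rr)
        assert len(out) == 89

    def test_constant_rr_time_domain_zeros(self):
        out = hrv_features(np.full(400, 800.0))
        assert out["ECG_HRV_pNN50"] == 0.0
        assert out["ECG_HRV_RMSSD"] == 0.0
        assert out["ECG_HRV_SDNN"] == 0.0

    def test_pnn50_hand_count(self):
        # diffs 60, 40, 55 -> 2 of 3 exceed 50 ms
        out = hrv_features(np.array([800.0, 860.0, 900.0, 955.0] * 5))
        d = np.diff(np.array([800.0, 860.0, 900.0, 955.0] * 5))
        expect = 100.0 * np.mean(np.abs(d) > 50)
        assert out["ECG_HRV_pNN50"] == pytest.approx(expect)

    def test_mcvnn_is_mad_over_median(self):
        rr = 800 + 100 * np.random.default_rng(0).standard_normal(300)
        out = hrv_features(rr)
        med = np.median(rr)
        mad = np.median(np.abs(rr - med))
        assert out["ECG_HRV_MCVNN"] == pytest.approx(mad / med)

    def test_too_short_series_gives_missing_markers(self):
        out = hrv_features(np.array([800.0, 820.0]))
        assert len(out) == 89 and all(np.isnan(v) for v in out.values())


def _resp_wave(fs=12.5, seconds=60, rate_bpm=12):
    t = np.arange(int(seconds * fs)) / fs
    return 1 - np.cos(2 * np.pi * rate_bpm / 60.0 * t)


class TestRespFeatures:
    def test_cardinality_112(self):
        x = _resp_wave(seconds=600)
        out = extract_resp_features(x, np.ones(x.size, bool), 12.5)
        assert len(out) == 112

    def test_symmetric_cycles_and_rate(self):
        x = _resp_wave(seconds=600)
        out = extract_resp_features(x, np.ones(x.size, bool), 12.5)
        assert out["RESP_Cycle_Symmetry_RiseDecay_Mean"] == pytest.approx(0.5, abs=0.03)
        assert out["RESP_Cycle_Rate_Mean"] == pytest.approx(12.0, abs=0.3)

    def test_no_breaths_gives_missing_markers(self):
        out = extract_resp_features(np.zeros(100), np.ones(100, bool), 12.5)
        assert len(out) == 112 and all(np.isnan(v) for v in out.values())


class TestSpo2Features:
    def test_constant_trace(self):
        x = np.full(600, 98.0)
        out = extract_spo2_features(x, np.ones(600, bool))
        assert out["SPO2_Smin"] == out["SPO2_Smax"] == 98.0
        assert out["SPO2_Ssd"] == 0.0
        assert out["SPO2_SampEn"] == 0.0
        assert out["SPO2_CTM"] == 1.0

    def test_nonlinear_features_pass_through_metric_functions(self):
        rng = np.random.default_rng(1)
        x = 96 + rng.standard_normal(600) * 0.5
        out = extract_spo2_features(x, np.ones(600, bool))
        assert out["SPO2_SampEn"] == pytest.approx(sample_entropy(x), abs=0)
        assert out["SPO2_LZC"] == pytest.approx(lempel_ziv_complexity(x), abs=0)
        assert out["SPO2_CTM"] == pytest.approx(central_tendency_measure(x), abs=0)


class TestWindowAssembly:
    @pytest.fixture(scope="class")
    def record(self):
        fs_abp, fs_ecg, fs_resp = 62.5, 125.0, 12.5
        seconds = 1800
        abp = _pulse_train(fs=fs_abp, seconds=seconds,
                           sbp_seq=120 + 5 * np.sin(np.arange(2250) / 7.0))
        ecg = np.zeros(int(seconds * fs_ecg))
        beat_idx = np.rint(np.arange(1, seconds / 0.8) * 0.8 * fs_ecg).astype(int)
        ecg[beat_idx] = 1.0
        resp = _resp_wave(fs=fs_resp, seconds=seconds)
        rng = np.random.default_rng(2)
        spo2 = 97 + 0.4 * rng.standard_normal(seconds)
        chans = {
            "ABP": Channel(fs_abp, abp, np.ones(abp.size, bool)),
            "ECG": Channel(fs_ecg, ecg, np.ones(ecg.size, bool)),
            "RESP": Channel(fs_resp, resp, np.ones(resp.size, bool)),
            "SPO2": Channel(1.0, spo2, np.ones(spo2.size, bool)),
        }
        return WaveformRecord("px", chans, 0.0, [],
                              Covariates(60, 0, 27, 36, 90))

    def test_five_rows_with_inherited_label_and_full_keys(self, record):
        w = AnalysisWindow("px", "observation", 0, 0.0, 1800.0, 1)
        rows = extract_window(record, w)
        assert len(rows) == 5
        for i, fv in enumerate(rows):
            assert fv.sub_window_index == i
            assert fv.label == 1
            assert set(fv.values) == set(catalog().names)

    def test_absent_channel_yields_nan_block_not_failure(self, record):
        slim = WaveformRecord("py", {k: v for k, v in record.channels.items()
                                     if k != "RESP"}, 0.0, [], record.covariates)
        vals = extract_subwindow(slim, 0.0, 600.0)
        assert len(vals) == 299
        assert all(np.isnan(vals[n]) for n in catalog().resp)
        assert np.isfinite(vals["ABP_Psys_Median"])
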