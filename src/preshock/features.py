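"""Computation of the fixed 299-feature catalog per 10-minute sub-window.

ABP features summarize nine beat-level pressure parameters with a
ten-statistic battery; ECG features are the 89-index HRV panel over
the cleaned R-R series; RESP features combine nine breath-cycle
parameters x ten statistics with a 22-index respiratory-rate-
variability (RRV) panel; SpO2 contributes five linear and three
nonlinear summaries.  Missing or degenerate inputs produce ``nan``
missing-markers, never exceptions, so every sub-window yields a full
299-key vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats as sstats

from . import complexity as cx
from .catalog import (ABP_PARAMS, RESP_PARAMS, STAT_NAMES, catalog)
from .labeling import AnalysisWindow
from .preprocess import (BreathSeries, PreprocessingError, abp_quality_mask,
                         bandpass_ecg, clean_rr_intervals, detect_breath_cycles,
                         detect_r_peaks, fill_short_gaps, rolling_subwindows)
from .records import WaveformRecord

HRV_BANDS = {"ULF": (0.0, 0.0033), "VLF": (0.0033, 0.04),
             "LF": (0.04, 0.15), "HF": (0.15, 0.4)}
RRV_BANDS = {"LF": (0.01, 0.05), "HF": (0.05, 0.15)}
_EPS = 1e-12


@dataclass
class FeatureVector:
    """One 10-minute sub-window's named values over the full catalog."""

    patient_id: str
    window_id: str
    sub_window_index: int
    label: int
    values: dict[str, float]

    def __post_init__(self):
        expected = set(catalog().names)
        if set(self.values) != expected:
            raise ValueError("feature keys must equal the catalog")


# ---------------------------------------------------------------------------
# statistic battery
# ---------------------------------------------------------------------------

def stat_battery(series) -> dict[str, float]:
    """The ten-statistic summary applied to every beat/cycle parameter.

    Order: Min, Mean, Max, Median, STD, Skewness, Kurtosis (excess),
    Hurst, Lyapunov, SampEn.  Empty input yields ten missing-markers;
    a constant series yields zero spread/shape statistics and the
    documented flat-series fallbacks for the nonlinear members.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {s: float("nan") for s in STAT_NAMES}
    sd = float(x.std())
    out = {
        "Min": float(x.min()),
        "Mean": float(x.mean()),
        "Max": float(x.max()),
        "Median": float(np.median(x)),
        "STD": sd,
        "Skewness": float(sstats.skew(x)) if sd > 0 else 0.0,
        "Kurtosis": float(sstats.kurtosis(x)) if sd > 0 else 0.0,
        "Hurst": cx.hurst_exponent(x),
        "Lyapunov": cx.largest_lyapunov(x),
        "SampEn": cx.sample_entropy(x),
    }
    return out


def _segmented_argmax(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Index of the maximum inside each [bounds[k], bounds[k+1]) segment."""
    seg = np.searchsorted(bounds, np.arange(x.size), side="right") - 1
    order = np.lexsort((x, seg))
    last = np.flatnonzero(np.diff(seg[order], append=seg[order][-1] + 1))
    idx_last = order[last]
    segs = seg[idx_last]
    keep = (segs >= 0) & (segs < bounds.size - 1)
    out = np.full(bounds.size - 1, -1)
    out[segs[keep]] = idx_last[keep]
    return out


# ---------------------------------------------------------------------------
# ABP
# ---------------------------------------------------------------------------

@dataclass
class AbpBeatParameters:
    """Nine per-beat pressure series for one sub-window."""

    series: dict[str, np.ndarray]


def abp_beat_parameters(abp: np.ndarray, valid: np.ndarray, fs: float,
                        ) -> AbpBeatParameters:
    """Fiducial detection and the nine beat-level parameter series.

    Psys/Pdia are systolic-peak and end-of-beat trough pressures; PP
    their difference; MeanAP the waveform average between adjacent
    onsets; MAP the formulaic Pdia + PP/3; HR from beat-to-beat time;
    TimeSBP2DBP the systolic-peak-to-next-diastolic interval; the
    amplitude series are absolute differences between consecutive
    systolic (resp. diastolic) values.  Beats touching invalid samples
    are dropped.
    """
    x = np.asarray(abp, dtype=float)
    empty = {p: np.array([]) for p in ABP_PARAMS}
    if x.size < fs or np.ptp(x) == 0:
        return AbpBeatParameters(empty)
    prom = 0.25 * np.std(x[valid]) if valid.any() else 0.0
    if prom <= 0:
        return AbpBeatParameters(empty)
    troughs, _ = sps.find_peaks(-x, distance=max(1, int(0.33 * fs)), prominence=prom)
    if troughs.size < 4:
        return AbpBeatParameters(empty)
    ok_beat = np.array([valid[a:b].all() for a, b in zip(troughs[:-1], troughs[1:])])
    peak_idx = _segmented_argmax(x, troughs)
    sums = np.add.reduceat(x, troughs)[:-1]
    widths = np.diff(troughs)
    good = ok_beat & (peak_idx >= 0)
    if good.sum() < 3:
        return AbpBeatParameters(empty)
    psys = x[peak_idx[good]]
    pdia = x[troughs[1:][good]]  # end-of-beat diastolic point
    pp = psys - pdia
    meanap = (sums / widths)[good]
    hr = 60.0 * fs / widths[good]
    t_sbp2dbp = (troughs[1:][good] - peak_idx[good]) / fs
    amp_sbp = np.abs(np.diff(psys))
    amp_dbp = np.abs(np.diff(pdia))
    return AbpBeatParameters({
        "Psys": psys, "Pdia": pdia, "PP": pp, "MeanAP": meanap,
        "MAP": pdia + pp / 3.0, "HR": hr, "TimeSBP2DBP": t_sbp2dbp,
        "AmplitudeSBP": amp_sbp, "AmplitudeDBP": amp_dbp,
    })


def extract_abp_features(abp: np.ndarray, valid: np.ndarray, fs: float) -> dict[str, float]:
    """90 named ABP features (9 parameters x 10 statistics)."""
    params = abp_beat_parameters(abp, valid, fs)
    out = {}
    for p in ABP_PARAMS:
        stats = stat_battery(params.series[p])
        for s in STAT_NAMES:
            out[f"ABP_{p}_{s}"] = stats[s]
    return out


# ---------------------------------------------------------------------------
# ECG / HRV
# ---------------------------------------------------------------------------

def _resample_even(times: np.ndarray, values: np.ndarray, fs: float) -> np.ndarray:
    grid = np.arange(times[0], times[-1], 1.0 / fs)
    return np.interp(grid, times, values)


def _band_power(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    m = (f > band[0]) & (f <= band[1])
    if not m.any():
        return 0.0
    return float(np.trapezoid(p[m], f[m]))


def _band_peak(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    m = (f > band[0]) & (f <= band[1])
    if not m.any():
        return float("nan")
    return float(f[m][np.argmax(p[m])])


def _hrv_frequency(nn4: np.ndarray) -> dict[str, float]:
    f, p = sps.welch(nn4, fs=4.0, nperseg=min(nn4.size, 1024), detrend="linear")
    bands = {k: _band_power(f, p, b) for k, b in HRV_BANDS.items()}
    total = sum(bands.values())
    lf, hf = bands["LF"], bands["HF"]
    out = dict(bands)
    out["TotalPower"] = total
    out["LnVLF"] = float(np.log(bands["VLF"] + _EPS))
    out["LnLF"] = float(np.log(lf + _EPS))
    out["LnHF"] = float(np.log(hf + _EPS))
    out["LnTotalPower"] = float(np.log(total + _EPS))
    out["LF_HF"] = lf / (hf + _EPS)
    out["LFnu"] = 100.0 * lf / (lf + hf + _EPS)
    out["HFnu"] = 100.0 * hf / (lf + hf + _EPS)
    for k in ("ULF", "VLF", "LF", "HF"):
        out[f"Rel{k}"] = 100.0 * bands[k] / (total + _EPS)
    out["PeakVLF"] = _band_peak(f, p, HRV_BANDS["VLF"])
    out["PeakLF"] = _band_peak(f, p, HRV_BANDS["LF"])
    out["PeakHF"] = _band_peak(f, p, HRV_BANDS["HF"])
    return out


def _hrv_stft(nn4: np.ndarray) -> dict[str, float]:
    nper = min(nn4.size, 256)
    f, _, z = sps.stft(nn4 - nn4.mean(), fs=4.0, nperseg=nper,
                       noverlap=nper * 3 // 4)
    psd = np.abs(z) ** 2
    lf_m = (f > HRV_BANDS["LF"][0]) & (f <= HRV_BANDS["LF"][1])
    hf_m = (f > HRV_BANDS["HF"][0]) & (f <= HRV_BANDS["HF"][1])
    lf_t = psd[lf_m].sum(axis=0)
    hf_t = psd[hf_m].sum(axis=0)
    ratio = lf_t / (hf_t + _EPS)
    return {
        "STFT_LF_Mean": float(lf_t.mean()), "STFT_LF_STD": float(lf_t.std()),
        "STFT_HF_Mean": float(hf_t.mean()), "STFT_HF_STD": float(hf_t.std()),
        "STFT_LFHF_Mean": float(ratio.mean()), "STFT_LFHF_STD": float(ratio.std()),
    }


def _hrv_wavelet(nn4: np.ndarray) -> dict[str, float]:
    # at 4 Hz: detail level j spans (2/2^j, 4/2^j] Hz; LF ~ D5-D6, HF ~ D3-D4
    level = min(6, pywt.dwt_max_level(nn4.size, "db4"))
    coeffs = pywt.wavedec(nn4 - nn4.mean(), "db4", level=level)
    details = coeffs[1:][::-1]  # D1 ... Dlevel
    def _sq(idxs):
        parts = [details[i - 1] ** 2 for i in idxs if i <= len(details)]
        return np.concatenate(parts) if parts else np.array([0.0])
    lf_sq = _sq((5, 6))
    hf_sq = _sq((3, 4))
    energies = np.array([float((d ** 2).sum()) for d in details]) + _EPS
    p = energies / energies.sum()
    return {
        "WT_LF_Mean": float(lf_sq.mean()), "WT_LF_STD": float(lf_sq.std()),
        "WT_HF_Mean": float(hf_sq.mean()), "WT_HF_STD": float(hf_sq.std()),
        "WT_LFHF": float(lf_sq.sum() / (hf_sq.sum() + _EPS)),
        "WT_Entropy": float(-(p * np.log(p)).sum()),
    }


def _segment_runs(sign: np.ndarray) -> list[int]:
    runs, count = [], 1
    for a, b in zip(sign[:-1], sign[1:]):
        if a == b:
            count += 1
        else:
            runs.append(count)
            count = 1
    runs.append(count)
    return runs


def _hrv_fragmentation(d: np.ndarray) -> dict[str, float]:
    sgn = np.sign(d)
    sgn[sgn == 0] = 1
    inflect = sgn[1:] != sgn[:-1]
    runs = _segment_runs(sgn)
    # alternation segments: maximal stretches of consecutive inflections
    alt_runs, count = [], 0
    for flip in inflect:
        if flip:
            count += 1
        elif count:
            alt_runs.append(count + 1)
            count = 0
    if count:
        alt_runs.append(count + 1)
    n = d.size
    return {
        "PIP": 100.0 * inflect.sum() / max(n - 1, 1),
        "IALS": 1.0 / np.mean(runs) if runs else float("nan"),
        "PSS": 100.0 * sum(r for r in runs if r < 3) / n,
        "PAS": 100.0 * sum(r for r in alt_runs if r >= 4) / n,
    }


def _hrv_asymmetry(d: np.ndarray) -> dict[str, float]:
    nz = d[d != 0]
    if nz.size == 0:
        return {"GI": float("nan"), "SI": float("nan"),
                "AI": float("nan"), "PI": float("nan")}
    up = nz > 0
    return {
        "GI": 100.0 * np.abs(nz[up]).sum() / np.abs(nz).sum(),
        "SI": 100.0 * (nz[up] ** 2).sum() / (nz ** 2).sum(),
        "AI": 100.0 * up.sum() / nz.size,
        "PI": 100.0 * (~up).sum() / nz.size,
    }


def hrv_features(rr_ms: np.ndarray, peak_times: np.ndarray | None = None) -> dict[str, float]:
    """The 89-index HRV panel over a cleaned R-R series (ms)."""
    names = [n.removeprefix("ECG_HRV_") for n in catalog().ecg]
    out = {n: float("nan") for n in names}
    rr = np.asarray(rr_ms, dtype=float)
    rr = rr[np.isfinite(rr)]
    if rr.size < 10:
        return {f"ECG_HRV_{k}": v for k, v in out.items()}
    if peak_times is None:
        peak_times = np.concatenate(([0.0], np.cumsum(rr))) / 1000.0
    t_nn = peak_times[1:]
    d = np.diff(rr)
    med = float(np.median(rr))
    mad = float(np.median(np.abs(rr - med)))
    out.update({
        "MeanNN": float(rr.mean()), "SDNN": float(rr.std(ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d ** 2))), "SDSD": float(d.std(ddof=1)) if d.size > 1 else float("nan"),
        "CVNN": float(rr.std(ddof=1) / rr.mean()),
        "CVSD": float(np.sqrt(np.mean(d ** 2)) / rr.mean()),
        "MedianNN": med, "MadNN": mad, "MCVNN": mad / med,
        "IQRNN": float(np.subtract(*np.percentile(rr, [75, 25]))),
        "pNN10": 100.0 * float(np.mean(np.abs(d) > 10)),
        "pNN20": 100.0 * float(np.mean(np.abs(d) > 20)),
        "pNN30": 100.0 * float(np.mean(np.abs(d) > 30)),
        "pNN50": 100.0 * float(np.mean(np.abs(d) > 50)),
        "MinNN": float(rr.min()), "MaxNN": float(rr.max()),
        "RangeNN": float(np.ptp(rr)),
        "SkewNN": float(sstats.skew(rr)) if rr.std() > 0 else 0.0,
        "KurtNN": float(sstats.kurtosis(rr)) if rr.std() > 0 else 0.0,
        "Prc20NN": float(np.percentile(rr, 20)),
        "Prc80NN": float(np.percentile(rr, 80)),
    })
    # geometric: histogram at the conventional 1/128 s bin width
    binw = 7.8125
    edges = np.arange(rr.min(), rr.max() + binw, binw)
    if edges.size > 1:
        counts, _ = np.histogram(rr, bins=edges)
        peak = counts.max()
        if peak > 0:
            out["HTI"] = rr.size / peak
            out["TINN"] = 2.0 * binw * rr.size / peak  # triangular-base width
    # per-minute segment statistics
    seg = np.floor(t_nn / 60.0).astype(int)
    if np.unique(seg).size >= 2:
        groups = pd.Series(rr).groupby(seg)
        out["SDANN"] = float(groups.mean().std(ddof=1))
        out["SDNNI"] = float(groups.std(ddof=1).mean())
    # frequency and time-frequency panels need an evenly sampled series
    if t_nn[-1] - t_nn[0] > 60:
        nn4 = _resample_even(t_nn, rr, 4.0)
        out.update(_hrv_frequency(nn4))
        out.update(_hrv_stft(nn4))
        out.update(_hrv_wavelet(nn4))
    sd1, sd2 = cx.poincare_descriptors(rr)
    out["SD1"], out["SD2"] = sd1, sd2
    out["SD1_SD2"] = sd1 / (sd2 + _EPS)
    out["EllipseArea"] = float(np.pi * sd1 * sd2)
    out["CSI"] = sd2 / (sd1 + _EPS)
    out["CVI"] = float(np.log10(16.0 * sd1 * sd2 + _EPS))
    out["ApEn"] = cx.approximate_entropy(rr)
    out["SampEn"] = cx.sample_entropy(rr)
    mse = cx.multiscale_entropy(rr)
    for i, s in enumerate((2, 3, 4, 5), start=1):
        out[f"MSE_{s}"] = float(mse[i])
    finite = mse[np.isfinite(mse)]
    out["MSE_Mean"] = float(finite.mean()) if finite.size else float("nan")
    out["DFA_Alpha1"] = cx.dfa_alpha(rr, (4, 16))
    out["DFA_Alpha2"] = cx.dfa_alpha(rr, (16, 64)) if rr.size >= 130 else float("nan")
    out["DFA_Alpha"] = cx.dfa_alpha(rr)
    out["CD"] = cx.correlation_dimension(rr)
    out["Hurst"] = cx.hurst_exponent(rr)
    out["Lyapunov"] = cx.largest_lyapunov(rr)
    out["LZC"] = cx.lempel_ziv_complexity(rr)
    out["CTM"] = cx.central_tendency_measure(rr)
    counts, _ = np.histogram(rr, bins=16)
    p = counts[counts > 0] / rr.size
    out["ShanEn"] = float(-(p * np.log(p)).sum())
    # Katz and Petrosian fractal dimensions
    ln = np.log10(rr.size)
    dists = np.sqrt((np.arange(1, rr.size) ** 2) + (rr[1:] - rr[0]) ** 2)
    length = float(np.sum(np.sqrt(1.0 + d ** 2))) if d.size else 0.0
    if length > 0 and dists.size:
        out["KFD"] = float(ln / (ln + np.log10(dists.max() / length + _EPS)))
    sgn_changes = int(np.sum(np.diff(np.sign(d)) != 0)) if d.size > 1 else 0
    out["PFD"] = float(ln / (ln + np.log10(rr.size / (rr.size + 0.4 * sgn_changes))))
    if d.size > 3:
        out.update(_hrv_fragmentation(d))
        out.update(_hrv_asymmetry(d))
    out["MFDFA_Alpha1_Peak"] = cx.mfdfa_alpha1_peak(rr)
    return {f"ECG_HRV_{k}": out[k] for k in names}


def extract_ecg_features(ecg: np.ndarray, valid: np.ndarray, fs: float) -> dict[str, float]:
    """89 HRV features from a raw ECG sub-window (filter, detect, clean)."""
    blank = {n: float("nan") for n in catalog().ecg}
    try:
        x, mask = fill_short_gaps(ecg, valid, fs)
        filtered = bandpass_ecg(x, fs)
        beats = detect_r_peaks(filtered, fs)
        rr = clean_rr_intervals(beats.rr_ms)
    except PreprocessingError:
        return blank
    return hrv_features(rr, beats.peak_times)


# ---------------------------------------------------------------------------
# RESP
# ---------------------------------------------------------------------------

@dataclass
class RespCycleParameters:
    series: dict[str, np.ndarray]


def resp_cycle_parameters(breaths: BreathSeries) -> RespCycleParameters:
    rise_amp = breaths.amplitudes
    decay_amp = breaths.decay_amplitudes
    bb = breaths.durations
    return RespCycleParameters({
        "Cycle_Amplitude": rise_amp,
        "Width": breaths.decay_times,
        "PeakPeak_Time": np.diff(breaths.t_peak),
        "TroughTrough_Time": bb,
        "Amplitude": decay_amp,
        "Cycle_Rate": 60.0 / bb,
        "RVT": rise_amp / bb,
        "Cycle_Symmetry_PeakTrough": rise_amp / (rise_amp + decay_amp + _EPS),
        "Cycle_Symmetry_RiseDecay": breaths.rise_times / (bb + _EPS),
    })


def _burg_psd(x: np.ndarray, order: int, freqs: np.ndarray) -> np.ndarray:
    from statsmodels.regression.linear_model import burg

    ar, sigma2 = burg(x - x.mean(), order=order)
    k = np.arange(1, order + 1)
    denom = np.abs(1.0 - (ar[None, :] * np.exp(-2j * np.pi * freqs[:, None] * k)).sum(axis=1)) ** 2
    return sigma2 / np.maximum(denom, _EPS)


def rrv_features(breaths: BreathSeries) -> dict[str, float]:
    """The 22-index respiratory-rate-variability panel (BB in seconds)."""
    names = [n.removeprefix("RESP_RRV_") for n in catalog().resp if n.startswith("RESP_RRV_")]
    out = {n: float("nan") for n in names}
    bb = breaths.durations
    if bb.size < 8:
        return {f"RESP_RRV_{k}": v for k, v in out.items()}
    t = breaths.t_end
    d = np.diff(bb)
    out.update({
        "MeanBB": float(bb.mean()), "SDBB": float(bb.std(ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d ** 2))),
        "SDSD": float(d.std(ddof=1)) if d.size > 1 else float("nan"),
        "CVBB": float(bb.std(ddof=1) / bb.mean()),
        "MedianBB": float(np.median(bb)),
    })
    # evenly resampled BB(t) at 1 Hz for Welch / Burg / wavelet
    if t[-1] - t[0] > 30:
        bb1 = _resample_even(t, bb, 1.0)
        f, p = sps.welch(bb1, fs=1.0, nperseg=min(bb1.size, 256), detrend="linear")
        out["Welch_LF"] = _band_power(f, p, RRV_BANDS["LF"])
        out["Welch_HF"] = _band_power(f, p, RRV_BANDS["HF"])
        out["Welch_LFHF"] = out["Welch_LF"] / (out["Welch_HF"] + _EPS)
        fgrid = np.linspace(0.005, 0.2, 200)
        try:
            pb = _burg_psd(bb1, order=min(12, bb1.size // 4), freqs=fgrid)
            out["Burg_LF"] = _band_power(fgrid, pb, RRV_BANDS["LF"])
            out["Burg_HF"] = _band_power(fgrid, pb, RRV_BANDS["HF"])
            out["Burg_LFHF"] = out["Burg_LF"] / (out["Burg_HF"] + _EPS)
        except (np.linalg.LinAlgError, ValueError):
            pass
        pls = sps.lombscargle(t, bb - bb.mean(), 2 * np.pi * fgrid, normalize=False)
        out["LombScargle_LF"] = _band_power(fgrid, pls, RRV_BANDS["LF"])
        out["LombScargle_HF"] = _band_power(fgrid, pls, RRV_BANDS["HF"])
        out["LombScargle_LFHF"] = out["LombScargle_LF"] / (out["LombScargle_HF"] + _EPS)
        level = min(5, pywt.dwt_max_level(bb1.size, "db4"))
        coeffs = pywt.wavedec(bb1 - bb1.mean(), "db4", level=level)
        details = coeffs[1:][::-1]
        lf_e = sum(float((details[i - 1] ** 2).sum()) for i in (4, 5) if i <= len(details))
        hf_e = float((details[2] ** 2).sum()) if len(details) >= 3 else 0.0
        out["WT_LF"] = lf_e
        out["WT_HF"] = hf_e
        out["WT_LFHF"] = lf_e / (hf_e + _EPS)
    out["SampEn"] = cx.sample_entropy(bb)
    sd1, sd2 = cx.poincare_descriptors(bb)
    out["SD1"], out["SD2"] = sd1, sd2
    out["MFDFA_Alpha1_Peak"] = cx.mfdfa_alpha1_peak(bb)
    return {f"RESP_RRV_{k}": out[k] for k in names}


def extract_resp_features(resp: np.ndarray, valid: np.ndarray, fs: float) -> dict[str, float]:
    """112 respiratory features: 9 x 10 cycle statistics + 22 RRV indices."""
    blank = {n: float("nan") for n in catalog().resp}
    try:
        x, _ = fill_short_gaps(resp, valid, fs)
        breaths = detect_breath_cycles(x, fs)
    except PreprocessingError:
        return blank
    params = resp_cycle_parameters(breaths)
    out = {}
    for p in RESP_PARAMS:
        stats = stat_battery(params.series[p])
        for s in STAT_NAMES:
            out[f"RESP_{p}_{s}"] = stats[s]
    out.update(rrv_features(breaths))
    return out


# ---------------------------------------------------------------------------
# SpO2
# ---------------------------------------------------------------------------

def extract_spo2_features(spo2: np.ndarray, valid: np.ndarray) -> dict[str, float]:
    """8 oximetry features: 5 linear summaries + SampEn, LZC, CTM."""
    x = np.asarray(spo2, dtype=float)[np.asarray(valid, dtype=bool)]
    if x.size < 5:
        return {n: float("nan") for n in catalog().spo2}
    return {
        "SPO2_Smin": float(x.min()), "SPO2_Smean": float(x.mean()),
        "SPO2_Smax": float(x.max()), "SPO2_Smedian": float(np.median(x)),
        "SPO2_Ssd": float(x.std()),
        "SPO2_SampEn": cx.sample_entropy(x),
        "SPO2_LZC": cx.lempel_ziv_complexity(x),
        "SPO2_CTM": cx.central_tendency_measure(x),
    }


# ---------------------------------------------------------------------------
# window-level assembly
# ---------------------------------------------------------------------------

def extract_subwindow(record: WaveformRecord, start: float, end: float) -> dict[str, float]:
    """All 299 features for one 10-minute interval of a record."""
    values: dict[str, float] = {}
    abp = record.channels.get("ABP")
    if abp is not None:
        ch = abp.slice(start, end)
        x, mask = fill_short_gaps(ch.samples, ch.valid_mask, abp.sampling_rate)
        q = abp_quality_mask(x, abp.sampling_rate) & mask
        values.update(extract_abp_features(x, q, abp.sampling_rate))
    else:
        values.update({n: float("nan") for n in catalog().abp})
    ecg = record.channels.get("ECG")
    if ecg is not None:
        ch = ecg.slice(start, end)
        values.update(extract_ecg_features(ch.samples, ch.valid_mask, ecg.sampling_rate))
    else:
        values.update({n: float("nan") for n in catalog().ecg})
    resp = record.channels.get("RESP")
    if resp is not None:
        ch = resp.slice(start, end)
        values.update(extract_resp_features(ch.samples, ch.valid_mask, resp.sampling_rate))
    else:
        values.update({n: float("nan") for n in catalog().resp})
    spo2 = record.channels.get("SPO2")
    if spo2 is not None:
        ch = spo2.slice(start, end)
        values.update(extract_spo2_features(ch.samples, ch.valid_mask))
    else:
        values.update({n: float("nan") for n in catalog().spo2})
    return values


def extract_window(record: WaveformRecord, window: AnalysisWindow) -> list[FeatureVector]:
    """Five FeatureVectors per 30-minute window (10-min rolling, 5-min step)."""
    out = []
    for i, (a, b) in enumerate(rolling_subwindows(window.start, window.end)):
        values = extract_subwindow(record, a, b)
        out.append(FeatureVector(record.patient_id, window.window_id, i,
                                 window.label, values))
    return out


def feature_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Long feature table: one row per (patient, window, sub-window)."""
    rows = []
    for v in vectors:
        row = {"patient_id": v.patient_id, "window_id": v.window_id,
               "sub_window": v.sub_window_index, "label": v.label}
        row.update({n: v.values[n] for n in catalog().names})
        rows.append(row)
    return pd.DataFrame(rows)
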