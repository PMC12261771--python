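"""Signal cleaning and segmentation.

Covers the per-channel conditioning that precedes feature extraction:
zero-phase 3-45 Hz ECG bandpass, derivative-threshold R-peak detection
with a 200 ms refractory period, physiological R-R validity cleaning
(400-1500 ms, linear interpolation of violations), a 0.5 s-granular
arterial-pressure signal-quality mask, prominence-based breath-cycle
detection, chained-equation imputation of the feature table, and the
10-minute / 5-minute-overlap rolling sub-windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

RR_VALID_MS = (400.0, 1500.0)  # open interval; outside is interpolated
ABP_PRESSURE_BOUNDS = (20.0, 300.0)  # mmHg
ABP_SLEW_LIMIT = 25.0  # mmHg per sample within a check window
SQI_WINDOW_S = 0.5
MIN_BREATH_CYCLE_S = 1.5


class PreprocessingError(RuntimeError):
    pass


@dataclass
class BeatSeries:
    """Cardiac fiducials: R-peak (or pulse) times and interval series."""

    peak_times: np.ndarray  # seconds
    rr_ms: np.ndarray  # len(peak_times) - 1

    def __post_init__(self):
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("fiducial times must be strictly increasing")


@dataclass
class BreathSeries:
    """Per-cycle breath fiducials: start trough -> peak -> end trough.

    Cycles are stored as parallel arrays; adjacent cycles usually share
    a trough but need not (a rejected cycle leaves a gap).
    """

    t_start: np.ndarray
    t_peak: np.ndarray
    t_end: np.ndarray
    v_start: np.ndarray
    v_peak: np.ndarray
    v_end: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.t_peak.size

    @property
    def durations(self) -> np.ndarray:
        """Trough-to-trough cycle duration (the breath-to-breath interval)."""
        return self.t_end - self.t_start

    @property
    def rise_times(self) -> np.ndarray:
        return self.t_peak - self.t_start

    @property
    def decay_times(self) -> np.ndarray:
        return self.t_end - self.t_peak

    @property
    def amplitudes(self) -> np.ndarray:
        """Rise amplitude: peak minus preceding trough."""
        return self.v_peak - self.v_start

    @property
    def decay_amplitudes(self) -> np.ndarray:
        return self.v_peak - self.v_end


def bandpass_ecg(ecg: np.ndarray, fs: float, band: tuple[float, float] = (3.0, 45.0),
                 order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output length equals input."""
    if fs <= 2 * band[1]:
        raise PreprocessingError(f"sampling rate {fs} Hz too low for band {band}")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ecg, dtype=float))


def detect_r_peaks(ecg: np.ndarray, fs: float, refractory_s: float = 0.2) -> BeatSeries:
    """Amplitude/derivative-threshold R-peak detector.

    The threshold adapts to the upper envelope of the filtered signal;
    the refractory period suppresses double-counting within a beat.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        raise PreprocessingError("no peaks found (flat signal)")
    height = 0.4 * np.percentile(np.abs(x), 99.5)
    if height <= 0:
        raise PreprocessingError("no peaks found")
    idx, _ = sps.find_peaks(x, height=height, distance=max(1, int(refractory_s * fs)))
    if idx.size < 2:
        raise PreprocessingError("no peaks found")
    times = idx / fs
    rr = np.diff(times) * 1000.0
    return BeatSeries(peak_times=times, rr_ms=rr)


def clean_rr_intervals(rr_ms: np.ndarray,
                       bounds: tuple[float, float] = RR_VALID_MS) -> np.ndarray:
    """Replace R-R intervals outside the open (400, 1500) ms interval.

    Violations (heart rate below 40 or above 150 bpm) are re-estimated
    by linear interpolation between the nearest valid neighbours; valid
    intervals are returned untouched, so the operation is idempotent.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 3:
        raise PreprocessingError("need at least 3 intervals")
    valid = (rr > bounds[0]) & (rr < bounds[1])
    if not valid.any():
        raise PreprocessingError("no valid R-R anchor")
    if valid.all():
        return rr.copy()
    idx = np.arange(rr.size)
    out = rr.copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], rr[valid])
    return out


def abp_quality_mask(abp: np.ndarray, fs: float,
                     pressure_bounds: tuple[float, float] = ABP_PRESSURE_BOUNDS,
                     slew_limit: float = ABP_SLEW_LIMIT,
                     window_s: float = SQI_WINDOW_S) -> np.ndarray:
    """Signal-quality mask at 0.5 s check-window granularity.

    A window is invalid if any sample leaves [20, 300] mmHg, the window
    is flat (zero variance), or the within-window slew exceeds the
    physiologic limit.  Criteria use within-window differences only, so
    an isolated artifact invalidates exactly its own window.
    """
    x = np.asarray(abp, dtype=float)
    w = max(1, int(round(window_s * fs)))
    n = x.size
    nb = n // w
    bad = np.zeros(nb + (1 if n % w else 0), dtype=bool)
    if nb:
        blocks = x[: nb * w].reshape(nb, w)
        lo, hi = blocks.min(axis=1), blocks.max(axis=1)
        bad_blocks = (lo < pressure_bounds[0]) | (hi > pressure_bounds[1])
        if w > 1:
            bad_blocks |= (hi - lo) == 0
            slew = np.abs(np.diff(blocks, axis=1)).max(axis=1)
            bad_blocks |= slew > slew_limit
        bad[:nb] = bad_blocks
    if n % w:  # trailing partial window
        blk = x[nb * w :]
        bad[-1] = (
            np.any((blk < pressure_bounds[0]) | (blk > pressure_bounds[1]))
            or (blk.size > 1 and np.ptp(blk) == 0)
            or (blk.size > 1 and np.max(np.abs(np.diff(blk))) > slew_limit)
        )
    return ~np.repeat(bad, [w] * nb + ([n - nb * w] if n % w else []))


def detect_breath_cycles(resp: np.ndarray, fs: float,
                         min_cycle_s: float = MIN_BREATH_CYCLE_S,
                         prominence_factor: float = 0.25) -> BreathSeries:
    """Prominence-based trough/peak pairing of the respiratory trace.

    The trace is smoothed with a zero-phase 1 Hz low-pass before
    fiducial search (breath content lives well below 0.5 Hz); peaks
    and troughs must alternate, and cycles shorter than ``min_cycle_s``
    or with sub-threshold prominence are rejected.  Record endpoints
    count as trough candidates so boundary-complete cycles are kept.
    """
    x = np.asarray(resp, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        raise PreprocessingError("no breaths found")
    if fs > 2.5:
        sos = sps.butter(2, 1.0, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    dist = max(1, int(min_cycle_s * fs))
    prom = prominence_factor * np.std(x)
    peaks, _ = sps.find_peaks(x, distance=dist, prominence=prom)
    pad = x.max() + 10 * prom
    troughs, _ = sps.find_peaks(-np.concatenate(([pad], x, [pad])),
                                distance=dist, prominence=prom)
    troughs = np.clip(troughs - 1, 0, x.size - 1)
    if peaks.size < 1 or troughs.size < 2:
        raise PreprocessingError("no breaths found")
    # one cycle per consecutive trough pair holding exactly one best peak
    start, peak, end = [], [], []
    for a, b in zip(troughs[:-1], troughs[1:]):
        inside = peaks[(peaks > a) & (peaks < b)]
        if inside.size == 0:
            continue
        start.append(a)
        peak.append(inside[np.argmax(x[inside])])
        end.append(b)
    if not peak:
        raise PreprocessingError("no breaths found")
    s, p, e = np.array(start), np.array(peak), np.array(end)
    return BreathSeries(t_start=s / fs, t_peak=p / fs, t_end=e / fs,
                        v_start=x[s], v_peak=x[p], v_end=x[e])


def fill_short_gaps(samples: np.ndarray, valid_mask: np.ndarray, fs: float,
                    max_gap_s: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation across short masked gaps in a raw signal.

    Gaps no longer than ``max_gap_s`` are filled before fiducial
    detection; longer gaps stay masked and surface downstream as
    missing feature values.
    """
    x = np.asarray(samples, dtype=float).copy()
    mask = np.asarray(valid_mask, dtype=bool).copy()
    if mask.all() or not mask.any():
        return x, mask
    inv = ~mask
    # label contiguous invalid runs; fill all short runs in one pass
    edges = np.flatnonzero(np.diff(np.concatenate(([0], inv.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    max_len = int(max_gap_s * fs)
    fill = np.zeros(x.size, dtype=bool)
    for s, e in zip(starts, ends):
        if e - s <= max_len:
            fill[s:e] = True
    if fill.any():
        good = np.flatnonzero(mask)
        x[fill] = np.interp(np.flatnonzero(fill), good, x[good])
        mask[fill] = True
    return x, mask


def impute_chained(features: pd.DataFrame, seed: int = 0, max_iter: int = 10) -> pd.DataFrame:
    """Chained-equation imputation of a feature table (MICE-style).

    Missing cells are filled by iterated conditional regression on all
    other features (sklearn's IterativeImputer with a fixed iteration
    count and seed); observed cells are never altered.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    num = features.select_dtypes(include=[np.number])
    fully_missing = [c for c in num.columns if num[c].isna().all()]
    if fully_missing:
        raise PreprocessingError(f"fully missing columns: {fully_missing}")
    if not num.isna().any().any():
        return features.copy()
    imputer = IterativeImputer(max_iter=max_iter, random_state=seed,
                               sample_posterior=False, keep_empty_features=True)
    filled = imputer.fit_transform(num.to_numpy())
    out = features.copy()
    out[num.columns] = filled
    # guarantee the observed cells byte-identically
    observed = ~num.isna()
    out[num.columns] = out[num.columns].where(~observed, num)
    return out


def rolling_subwindows(start: float, end: float, width_s: float = 600.0,
                       step_s: float = 300.0) -> list[tuple[float, float]]:
    """10-minute sub-intervals at 5-minute steps tiling [start, end).

    A 30-minute window yields the 5 sub-windows at offsets 0, 5, 10,
    15 and 20 minutes, consecutive pairs overlapping by 5 minutes.
    """
    if end - start < width_s - 1e-9:
        raise PreprocessingError("window shorter than one sub-window")
    out = []
    t = start
    while t + width_s <= end + 1e-9:
        out.append((t, t + width_s))
        t += step_s
    return out
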