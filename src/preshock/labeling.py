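"""Shock-event detection and self-controlled window construction.

The event rule: a hypotensive episode is a maximal run of 1 Hz mean
arterial pressure (MAP) <= 65 mmHg lasting strictly more than one
minute; it qualifies as shock when a serum lactate >= 2 mmol/L (the
comparison operator is configurable) falls within 12 h of the episode
onset.  Only the first qualifying event per patient counts.

Each shock patient contributes one 30-minute observation window ending
one hour before onset (the prediction blackout) and one 30-minute
self-control window: Scenario 1 ends at the 24-hour washout boundary
before onset; Scenario 2 starts at the 7-day washout boundary after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import MODALITIES, WaveformRecord, missing_fraction

MAP_THRESHOLD = 65.0
MIN_EPISODE_S = 60.0          # strictly more than one minute
LACTATE_THRESHOLD = 2.0
LACTATE_WINDOW_S = 12 * 3600.0
OBS_OFFSET_S = 90 * 60.0      # observation window starts 90 min pre-onset
BLACKOUT_S = 60 * 60.0        # prediction window: no data within 1 h of onset
WINDOW_S = 30 * 60.0
WASHOUT1_S = 24 * 3600.0
WASHOUT2_S = 7 * 24 * 3600.0
MIN_PREONSET_S = 90 * 60.0
MAX_MISSING = 0.5


class LabelingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ShockEvent:
    episode_start: float
    episode_end: float
    qualifying_lactate: tuple[float, float]  # (timestamp, mmol/L)

    @property
    def onset(self) -> float:
        return self.episode_start


@dataclass(frozen=True)
class AnalysisWindow:
    patient_id: str
    role: str          # "observation" | "control"
    scenario: int      # 1 | 2 | 0 (observation)
    start: float
    end: float
    label: int

    @property
    def window_id(self) -> str:
        return f"{self.patient_id}:{self.role}"


def beatwise_map_series(abp: np.ndarray, fs: float,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """One time-averaged pressure per detected beat.

    Beat onsets are located as pulse-train troughs (detected on a
    ~25 Hz decimated copy for speed, which is ample for onset timing);
    each beat's MAP is the raw-sample mean between adjacent onsets.
    """
    x = np.asarray(abp, dtype=float)
    if x.size < fs or np.ptp(x) == 0:
        raise LabelingError("no detectable beats")
    dec = max(1, int(fs // 12.5))
    xd = x[::dec]
    fsd = fs / dec
    prom = 0.25 * np.std(xd)
    troughs, _ = sps.find_peaks(-xd, distance=max(1, int(0.33 * fsd)),
                                prominence=prom, wlen=max(4, int(2.0 * fsd)))
    if troughs.size < 3:
        raise LabelingError("no detectable beats")
    onsets = troughs * dec
    means = np.add.reduceat(x, onsets)[:-1] / np.diff(onsets)
    times = onsets[:-1] / fs
    return times, means


def map_series_1hz(beat_times: np.ndarray, beat_map: np.ndarray,
                   duration_s: float) -> np.ndarray:
    """Beat-wise MAP interpolated onto the 1 Hz grid used by the rule."""
    grid = np.arange(int(duration_s))
    return np.interp(grid, beat_times, beat_map)


def detect_hypotension_episodes(map_1hz: np.ndarray,
                                threshold: float = MAP_THRESHOLD,
                                min_duration_s: float = MIN_EPISODE_S,
                                ) -> list[tuple[float, float]]:
    """Maximal runs with MAP <= threshold lasting strictly > 1 minute.

    Input is a regular 1 Hz series; each sample covers one second, so a
    61-sample run (61 s) qualifies and a 60-sample run does not.
    """
    below = np.asarray(map_1hz) <= threshold
    if not below.any():
        return []
    padded = np.concatenate(([0], below.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    return [(float(s), float(e)) for s, e in zip(starts, ends)
            if (e - s) > min_duration_s]


def qualify_shock_event(episodes: list[tuple[float, float]],
                        labs: list[tuple[float, float]],
                        threshold: float = LACTATE_THRESHOLD,
                        op: str = "ge",
                        window_s: float = LACTATE_WINDOW_S) -> ShockEvent | None:
    """First episode with a qualifying lactate within the 12 h window."""
    if op not in ("ge", "gt"):
        raise ValueError("op must be 'ge' or 'gt'")
    for start, end in episodes:
        for t, val in labs:
            hit = val >= threshold if op == "ge" else val > threshold
            if hit and abs(t - start) <= window_s:
                return ShockEvent(start, end, (t, val))
    return None


def build_windows(event: ShockEvent, record: WaveformRecord,
                  scenario_preference: int = 1) -> list[AnalysisWindow]:
    """Observation + one self-control window, both fully in-record.

    The control sits flush against the washout boundary: Scenario 1
    ends 24 h before onset, Scenario 2 starts 7 days after.  When both
    are feasible the preferred scenario wins.
    """
    onset = event.onset
    dur = record.duration
    out = []
    obs = (onset - OBS_OFFSET_S, onset - BLACKOUT_S)
    if obs[0] >= 0 and obs[1] <= dur:
        out.append(AnalysisWindow(record.patient_id, "observation", 0,
                                  obs[0], obs[1], 1))
    s1 = (onset - WASHOUT1_S - WINDOW_S, onset - WASHOUT1_S)
    s2 = (onset + WASHOUT2_S, onset + WASHOUT2_S + WINDOW_S)
    candidates = [(1, s1), (2, s2)] if scenario_preference == 1 else [(2, s2), (1, s1)]
    for scen, (a, b) in candidates:
        if a >= 0 and b <= dur:
            out.append(AnalysisWindow(record.patient_id, "control", scen, a, b, 0))
            break
    return out


def apply_exclusions(cohort: list[tuple[WaveformRecord, ShockEvent | None,
                                        list[AnalysisWindow]]],
                     max_missing: float = MAX_MISSING,
                     ) -> tuple[list[tuple[WaveformRecord, ShockEvent,
                                           list[AnalysisWindow]]],
                                list[tuple[str, str]]]:
    """Cohort exclusion rules; the log records the first triggered reason.

    Order: no qualifying event; a missing channel; less than 90 min of
    pre-onset data; more than 50% missing in any used window/channel;
    no feasible self-control window.
    """
    included, log = [], []
    for record, event, windows in cohort:
        pid = record.patient_id
        if event is None:
            log.append((pid, "no qualifying shock event"))
            continue
        missing_ch = [m for m in MODALITIES if m not in record.channels]
        if missing_ch:
            log.append((pid, f"missing channel: {','.join(missing_ch)}"))
            continue
        if event.onset < MIN_PREONSET_S:
            log.append((pid, "less than 90 min of pre-onset data"))
            continue
        over = None
        for w in windows:
            frac = missing_fraction(record, w.start, w.end)
            bad = [f"{ch}@{w.role}" for ch, f in frac.items() if f > max_missing]
            if bad:
                over = bad[0]
                break
        if over:
            log.append((pid, f"more than 50% missing values ({over})"))
            continue
        if not any(w.role == "control" for w in windows):
            log.append((pid, "no feasible control window"))
            continue
        included.append((record, event, windows))
    return included, log


def label_record(record: WaveformRecord, lactate_op: str = "ge",
                 scenario_preference: int = 1,
                 ) -> tuple[ShockEvent | None, list[AnalysisWindow]]:
    """Run the full labeling chain on one record."""
    abp = record.channels.get("ABP")
    if abp is None:
        return None, []
    from .preprocess import fill_short_gaps

    filled, _ = fill_short_gaps(abp.samples, abp.valid_mask, abp.sampling_rate)
    times, beat_map = beatwise_map_series(filled, abp.sampling_rate)
    series = map_series_1hz(times, beat_map, record.duration)
    # suppress 1-2 s artifact blips (e.g. beat segmentation misfires at
    # dropout gaps) without moving a monotone threshold crossing
    from scipy.ndimage import median_filter

    series = median_filter(series, size=5, mode="nearest")
    episodes = detect_hypotension_episodes(series)
    event = qualify_shock_event(episodes, record.labs, op=lactate_op)
    if event is None:
        return None, []
    return event, build_windows(event, record, scenario_preference)
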