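"""Seedable generator of multi-channel ICU records with ground-truth shock.

Each synthetic patient carries four channels at native rates (ABP beat
train, ECG R-peak spike train, quasi-periodic respiration, slow SpO2
trend), sparse serum-lactate labs, and demographic covariates.  Shock
patients sustain a mean-arterial-pressure dip to <= 65 mmHg for more
than one minute at a known onset, with a qualifying lactate (>= 2
mmol/L) within 12 h.  Configurable pre-shock drift perturbs the
generative parameters of selected feature families only inside the
90 minutes preceding onset:

* extra white R-R jitter         -> pNN50 rises
* respiratory symmetry shift     -> peak-to-trough width falls
* respiratory rate delta         -> cycle rate falls
* systolic-timing jitter         -> SampEn of TimeSBP2DBP rises
* pulse-pressure jitter scaling  -> median diastolic step amplitude falls

All randomness is drawn up front from a per-patient seeded stream and
effects are applied as deterministic transforms of those draws, so a
record is byte-reproducible under a fixed (config, seed) and drift can
be injected or removed without disturbing the base draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .records import Channel, Covariates, WaveformRecord

DRIFT_WINDOW_S = 90 * 60.0  # drift active in [onset - 90 min, onset)

# ABP pulse morphology: linear rise over a fraction of the beat, then
# exponential-style decay with this time constant (as a beat fraction).
ABP_RISE_FRAC = 0.30
ABP_DECAY_TAU = 0.35


def abp_shape_mean(rise_frac):
    """Closed-form beat-average of the unit pulse shape.

    The pulse rises linearly from 0 to 1 over ``rise_frac`` of the beat
    then follows a normalized exponential decay that reaches exactly 0
    at the beat end (so the end-of-beat trough equals DBP regardless of
    the rise fraction).  With E = exp(-(1 - rf)/tau) the time average
    is rf/2 + (tau (1 - E) - (1 - rf) E) / (1 - E); beat-wise mean
    pressure therefore has an analytic oracle: DBP + mean * PP.
    """
    rf = np.asarray(rise_frac, dtype=float)
    e = np.exp(-(1.0 - rf) / ABP_DECAY_TAU)
    return rf / 2.0 + (ABP_DECAY_TAU * (1.0 - e) - (1.0 - rf) * e) / (1.0 - e)


@dataclass(frozen=True)
class DriftSpec:
    """Per-family pre-shock effect magnitudes (zero disables a family)."""

    rr_jitter_ms: float = 0.0          # extra white R-R jitter (SD, ms)
    resp_symmetry_shift: float = 0.0   # additive shift of the rise fraction
    resp_rate_delta: float = 0.0       # breaths/min added to the cycle rate
    sbp2dbp_jitter: float = 0.0        # SD of systolic-timing jitter (beat fraction)
    pp_jitter_scale: float = 1.0       # multiplier on beat-to-beat PP jitter

    def is_null(self) -> bool:
        return (self.rr_jitter_ms == 0 and self.resp_symmetry_shift == 0
                and self.resp_rate_delta == 0 and self.sbp2dbp_jitter == 0
                and self.pp_jitter_scale == 1.0)


#: Default study-condition drift: directions follow the reported
#: risk-associated shifts (higher pNN50, narrower breaths, slower
#: breathing, more irregular systolic-diastolic timing, smaller
#: diastolic steps).
DEFAULT_DRIFT = DriftSpec(
    rr_jitter_ms=20.0,
    resp_symmetry_shift=0.22,
    resp_rate_delta=-2.0,
    sbp2dbp_jitter=0.035,
    pp_jitter_scale=0.55,
)

NULL_DRIFT = DriftSpec()


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative settings.

    Default waveform rates (62.5 Hz pressure/ECG, 12.5 Hz respiration,
    1 Hz oximetry trend) are integer decimations of monitor-archive
    rates, ample for beat- and breath-level fiducials.  Baselines are
    population means with between-patient spread; the shock episode is
    a scripted MAP trajectory crossing 65 mmHg at the true onset.
    """

    n_patients: int = 100
    seed: int = 0
    shock_fraction: float = 1.0
    fs_abp: float = 62.5
    fs_ecg: float = 125.0
    fs_resp: float = 12.5
    fs_spo2: float = 1.0
    # baseline hemodynamics
    map_baseline_mean: float = 85.0   # mmHg
    map_baseline_sd: float = 4.0
    pp_mean: float = 45.0             # mmHg
    pp_sd_between: float = 6.0
    pp_jitter_sd: float = 3.0         # beat-to-beat
    map_beat_noise_sd: float = 0.3
    abp_noise_sd: float = 0.4         # per-sample measurement noise
    hr_mean: float = 85.0             # bpm
    hr_sd: float = 10.0
    rr_hf_jitter_ms: float = 12.0     # white successive-difference jitter
    rr_ar_sd_ms: float = 18.0
    rr_lf_amp_ms: float = 15.0
    rr_hf_amp_ms: float = 10.0
    resp_rate_mean: float = 16.0      # breaths/min
    resp_rate_sd: float = 1.2
    resp_amp_mean: float = 1.0
    resp_sym_mean: float = 0.40
    spo2_mean: float = 97.0
    # record layout (hours around onset)
    pre_onset_hours: float = 24.75
    post_onset_hours: float = 2.0
    episode_depth: float = 58.0       # mmHg plateau during the episode
    episode_hold_s: float = 720.0
    # labs
    lactate_baseline_mean: float = 1.0
    lactate_baseline_sd: float = 0.25
    lactate_rise_lo: float = 2.5
    lactate_rise_hi: float = 5.5
    lactate_lag_hours: tuple[float, float] = (0.5, 8.0)
    lab_interval_hours: tuple[float, float] = (4.0, 12.0)
    missingness_rate: float = 0.01
    drift: DriftSpec = field(default_factory=lambda: DEFAULT_DRIFT)

    def __post_init__(self):
        if not 0 <= self.shock_fraction <= 1:
            raise ValueError("shock_fraction must be in [0, 1]")
        if not 0 <= self.missingness_rate <= 1:
            raise ValueError("missingness_rate must be in [0, 1]")
        if self.shock_fraction > 0 and self.pre_onset_hours * 3600 < 1.5 * 3600:
            raise ValueError("record too short to host the observation window "
                             "and washout before the event")

    @property
    def duration_s(self) -> float:
        return (self.pre_onset_hours + self.post_onset_hours) * 3600.0

    @property
    def onset_s(self) -> float:
        return self.pre_onset_hours * 3600.0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["drift"] = asdict(self.drift)
        return d


@dataclass
class GroundTruth:
    patient_id: str
    shock: bool
    onset_s: float | None
    scenario1_feasible: bool
    scenario2_feasible: bool
    effects: DriftSpec


# ---------------------------------------------------------------------------
# per-patient random draws (effects-independent)
# ---------------------------------------------------------------------------

@dataclass
class _PatientDraws:
    shock: bool
    map_base: float
    pp_base: float
    hr_base: float
    resp_rate_base: float
    rr_ar: np.ndarray
    rr_white: np.ndarray
    rr_extra: np.ndarray        # unit normals, scaled by drift jitter
    pp_jitter: np.ndarray       # unit normals
    map_eps: np.ndarray
    rise_white: np.ndarray      # unit normals for systolic-timing jitter
    resp_rate_ar: np.ndarray
    resp_amp: np.ndarray
    resp_sym_noise: np.ndarray
    spo2: np.ndarray
    lab_times: np.ndarray
    lab_values: np.ndarray
    shock_lab: tuple[float, float] | None
    gap_starts: dict[str, np.ndarray]
    gap_lens: dict[str, np.ndarray]
    covariates: Covariates


def _ar1(rng, n, phi, sd):
    from scipy.signal import lfilter

    eps = rng.standard_normal(n) * sd * np.sqrt(1 - phi**2)
    return lfilter([1.0], [1.0, -phi], eps)


def _draw_patient(config: SimulationConfig, idx: int) -> _PatientDraws:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, idx]))
    shock = bool(rng.random() < config.shock_fraction)
    dur = config.duration_s
    hr = float(np.clip(rng.normal(config.hr_mean, config.hr_sd), 55, 130))
    n_beats = int(dur / (60.0 / hr) * 1.25) + 16
    n_breaths = int(dur / (60.0 / (config.resp_rate_mean + 4)) * 1.3) + 16
    n_spo2 = int(dur * config.fs_spo2)

    lab_times = []
    t = float(rng.uniform(0.5, 2.0)) * 3600
    while t < dur:
        lab_times.append(t)
        t += float(rng.uniform(*config.lab_interval_hours)) * 3600
    lab_times = np.array(lab_times)
    lab_values = np.clip(
        rng.normal(config.lactate_baseline_mean, config.lactate_baseline_sd,
                   lab_times.size), 0.3, 1.8)
    shock_lab = None
    if shock:
        lag = float(rng.uniform(*config.lactate_lag_hours)) * 3600
        shock_lab = (config.onset_s + lag,
                     float(rng.uniform(config.lactate_rise_lo, config.lactate_rise_hi)))

    gap_starts, gap_lens = {}, {}
    n_gaps = int(np.ceil(dur * config.missingness_rate / 0.6)) if config.missingness_rate else 0
    for name in ("ABP", "ECG", "RESP", "SPO2"):
        gap_lens[name] = rng.uniform(0.2, 1.0, size=n_gaps)
        gap_starts[name] = rng.uniform(0, max(dur - 1.0, 1.0), size=n_gaps)

    sex = int(rng.random() < 0.53)
    cov = Covariates(
        age=float(np.clip(rng.normal(65.0, 14.8), 18, 95)),
        sex=sex,
        bmi=float(np.clip(rng.normal(29.6, 7.4), 15, 60)),
        neck_cm=float(np.clip(rng.normal(40.0 if sex else 35.0, 3.5), 25, 55)),
        waist_cm=float(np.clip(rng.normal(102.0, 14.0), 60, 160)),
    )

    return _PatientDraws(
        shock=shock,
        map_base=float(max(rng.normal(config.map_baseline_mean, config.map_baseline_sd), 76.0)),
        pp_base=float(np.clip(rng.normal(config.pp_mean, config.pp_sd_between), 25, 70)),
        hr_base=hr,
        resp_rate_base=float(np.clip(rng.normal(config.resp_rate_mean, config.resp_rate_sd), 10, 24)),
        rr_ar=_ar1(rng, n_beats, 0.95, config.rr_ar_sd_ms),
        rr_white=rng.standard_normal(n_beats),
        rr_extra=rng.standard_normal(n_beats),
        pp_jitter=rng.standard_normal(n_beats),
        map_eps=rng.standard_normal(n_beats) * config.map_beat_noise_sd,
        rise_white=rng.standard_normal(n_beats),
        resp_rate_ar=_ar1(rng, n_breaths, 0.9, 0.8),
        resp_amp=np.clip(1.0 + _ar1(rng, n_breaths, 0.9, 0.12), 0.4, 2.0),
        resp_sym_noise=rng.standard_normal(n_breaths),
        spo2=np.clip(97.0 + _ar1(rng, n_spo2, 0.995, 0.5)
                     + rng.standard_normal(n_spo2) * 0.15, 85, 100),
        lab_times=lab_times,
        lab_values=lab_values,
        shock_lab=shock_lab,
        gap_starts=gap_starts,
        gap_lens=gap_lens,
        covariates=cov,
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _map_target(t: np.ndarray, base: float, onset: float, config: SimulationConfig,
                shock: bool) -> np.ndarray:
    """Scripted beat-level MAP trajectory (mmHg).

    Shock patients decline from baseline to 74 mmHg over four minutes,
    then collapse at 3 mmHg/s, crossing 65 mmHg exactly at onset, hold
    at the episode depth and recover; the trajectory stays >= 72 mmHg
    everywhere else, so the steep crossing pins the detectable onset to
    the true one within a single 1 Hz sample.
    """
    if not shock:
        return np.full(t.shape, base)
    depth = config.episode_depth
    hold = config.episode_hold_s
    pts_t = np.array([
        0.0, onset - 240.0, onset - 3.0, onset - 3.0 + (74.0 - depth) / 3.0,
        onset + hold, onset + hold + 120.0, config.duration_s,
    ])
    pts_v = np.array([base, base, 74.0, depth, depth, max(base - 7, 72.0),
                      max(base - 7, 72.0)])
    return np.interp(t, pts_t, pts_v)


def _drift_mask(times: np.ndarray, onset: float | None) -> np.ndarray:
    if onset is None:
        return np.zeros(times.shape, dtype=bool)
    return (times >= onset - DRIFT_WINDOW_S) & (times < onset)


def _beat_times(draws: _PatientDraws, config: SimulationConfig,
                effects: DriftSpec, onset: float | None) -> tuple[np.ndarray, np.ndarray]:
    """R-peak times and per-beat RR (s), covering the record duration."""
    n = draws.rr_ar.size
    rr_mean = 60.0 / draws.hr_base
    approx_t = np.arange(n) * rr_mean
    lf = config.rr_lf_amp_ms * np.sin(2 * np.pi * 0.095 * approx_t)
    hf = config.rr_hf_amp_ms * np.sin(2 * np.pi * (draws.resp_rate_base / 60.0) * approx_t)
    jitter = draws.rr_white * config.rr_hf_jitter_ms
    extra = draws.rr_extra * effects.rr_jitter_ms * _drift_mask(approx_t, onset)
    rr_ms = rr_mean * 1000.0 + draws.rr_ar + lf + hf + jitter + extra
    rr = np.clip(rr_ms, 420.0, 1400.0) / 1000.0
    t = np.concatenate(([0.3], 0.3 + np.cumsum(rr)))[:-1]
    keep = t < config.duration_s - 0.5
    return t[keep], rr[keep]


def _piecewise_render(n: int, fs: float, starts: np.ndarray,
                      values_fn) -> np.ndarray:
    """Evaluate a per-segment shape over a sample grid (float32).

    ``starts`` are segment onset times; ``values_fn(k, phase)`` maps the
    per-sample segment index and fractional phase to sample values.
    Segment lookup uses run-length expansion rather than a search, so
    the cost is a handful of sequential passes over the sample grid.
    """
    start_idx = np.clip(np.ceil(starts * fs - 1e-9).astype(np.int64), 0, n)
    counts = np.diff(np.concatenate((start_idx, [n])))
    lead = int(start_idx[0])
    k = np.repeat(np.arange(starts.size), counts)
    # within-segment sample offsets are computed exactly in integers so
    # phase precision does not degrade with absolute record time
    delta = (np.arange(lead, n, dtype=np.int64) - start_idx[k]).astype(np.float32)
    frac = (start_idx - starts * fs).astype(np.float32)  # in [0, 1)
    seg_len = np.empty(starts.size)
    seg_len[:-1] = np.diff(starts)
    seg_len[-1] = max(n / fs - starts[-1], 1e-3)
    inv_len = (1.0 / (seg_len * fs)).astype(np.float32)
    phase = (delta + frac[k]) * inv_len[k]
    np.clip(phase, 0.0, 1.0, out=phase)
    body = values_fn(k, phase)
    if lead:
        head = np.full(lead, body[0], dtype=np.float32)
        return np.concatenate((head, body))
    return body


def _render_abp(t_r: np.ndarray, rr: np.ndarray, draws: _PatientDraws,
                config: SimulationConfig, effects: DriftSpec,
                onset: float | None) -> np.ndarray:
    """Beat-by-beat pulse train sampled at the ABP rate."""
    onsets = t_r + 0.2  # pulse transit from R peak to pressure upstroke
    nb = onsets.size
    in_drift = _drift_mask(onsets, onset)
    pp_scale = np.where(in_drift, effects.pp_jitter_scale, 1.0)
    pp = draws.pp_base + draws.pp_jitter[:nb] * config.pp_jitter_sd * pp_scale
    pp = np.clip(pp, 15.0, 90.0)
    # nominal rise fraction (slow modulation + small physiological noise);
    # the drift adds timing jitter that moves the systolic peak without
    # moving the diastolic endpoint, so it perturbs TimeSBP2DBP but not
    # the beat's mean pressure budget
    rise_nom = np.clip(ABP_RISE_FRAC
                       + 0.02 * np.sin(2 * np.pi * 0.01 * onsets)
                       + 0.004 * draws.rise_white[:nb], 0.12, 0.55)
    rise = np.clip(rise_nom + effects.sbp2dbp_jitter * draws.rise_white[:nb] * in_drift,
                   0.12, 0.55)
    m_target = _map_target(onsets, draws.map_base, onset if onset is not None else 0.0,
                           config, draws.shock)
    m_beat = m_target + draws.map_eps[:nb]
    if draws.shock and onset is not None:
        episode = (onsets >= onset - 360.0) & (onsets <= onset + config.episode_hold_s + 180.0)
        m_beat = np.where(episode, m_beat, np.maximum(m_beat, 68.0))
    else:
        m_beat = np.maximum(m_beat, 70.0)
    dbp = (m_beat - abp_shape_mean(rise_nom) * pp).astype(np.float32)
    pp32 = pp.astype(np.float32)
    rise32 = rise.astype(np.float32)
    inv_tau = np.float32(1.0 / ABP_DECAY_TAU)
    efloor = np.exp((rise32 - 1.0) * inv_tau)  # decay endpoint before normalization
    scale32 = (1.0 / (1.0 - efloor)).astype(np.float32)

    def shape(k, phase):
        rk = rise32[k]
        decay = (np.exp((rk - phase) * inv_tau) - efloor[k]) * scale32[k]
        out = np.where(phase < rk, phase / rk, decay)
        out *= pp32[k]
        out += dbp[k]
        return out

    n = int(config.duration_s * config.fs_abp)
    return _piecewise_render(n, config.fs_abp, onsets, shape)


def _render_resp(draws: _PatientDraws, config: SimulationConfig, effects: DriftSpec,
                 onset: float | None) -> np.ndarray:
    nb = draws.resp_rate_ar.size
    approx_t = np.arange(nb) * 60.0 / draws.resp_rate_base
    rate = (draws.resp_rate_base + draws.resp_rate_ar
            + effects.resp_rate_delta * _drift_mask(approx_t, onset))
    rate = np.clip(rate, 6.0, 30.0)
    period = 60.0 / rate
    starts = np.concatenate(([0.0], np.cumsum(period)))[:-1]
    keep = starts < config.duration_s
    starts = starts[keep]
    nb = starts.size
    sym = (config.resp_sym_mean + 0.03 * draws.resp_sym_noise[:nb]
           + effects.resp_symmetry_shift * _drift_mask(starts, onset))
    sym = np.clip(sym, 0.2, 0.8).astype(np.float32)
    amp = (draws.resp_amp[:nb] * config.resp_amp_mean).astype(np.float32)

    def shape(k, phase):
        sk = sym[k]
        val = np.where(
            phase < sk,
            0.5 * (1.0 - np.cos(np.float32(np.pi) * phase / sk)),
            0.5 * (1.0 + np.cos(np.float32(np.pi) * (phase - sk) / (1.0 - sk))),
        )
        return amp[k] * val

    n = int(config.duration_s * config.fs_resp)
    return _piecewise_render(n, config.fs_resp, starts, shape)


def _apply_gaps(samples: np.ndarray, fs: float, starts: np.ndarray,
                lens: np.ndarray) -> Channel:
    mask = np.ones(samples.size, dtype=bool)
    for s, l in zip(starts, lens):
        i0 = int(s * fs)
        i1 = min(samples.size, i0 + max(1, int(l * fs)))
        mask[i0:i1] = False
    samples = np.array(samples, copy=True)
    samples[~mask] = 0.0
    return Channel(fs, samples, mask)


def simulate_patient(config: SimulationConfig, patient_index: int,
                     effects: DriftSpec | None = None,
                     ) -> tuple[WaveformRecord, GroundTruth]:
    """Generate one patient.  ``effects`` overrides the config drift.

    Non-shock patients receive no drift and a MAP trajectory that never
    satisfies the event rule.
    """
    draws = _draw_patient(config, patient_index)
    onset = config.onset_s if draws.shock else None
    eff = effects if effects is not None else config.drift
    if not draws.shock:
        eff = NULL_DRIFT

    t_r, rr = _beat_times(draws, config, eff, onset)
    rng_noise = np.random.default_rng(
        np.random.SeedSequence([config.seed, patient_index, 7]))
    abp = _render_abp(t_r, rr, draws, config, eff, onset)
    abp = abp + (rng_noise.standard_normal(abp.size) * config.abp_noise_sd
                 ).astype(np.float32)

    # ECG as a clean R-peak spike train: all cardiac information lives
    # in the R-R point process
    n_ecg = int(config.duration_s * config.fs_ecg)
    ecg = np.zeros(n_ecg, dtype=np.float32)
    r_idx = np.rint(t_r * config.fs_ecg).astype(int)
    r_idx = r_idx[(r_idx > 0) & (r_idx < n_ecg - 1)]
    ecg[r_idx] = 1.0
    ecg[r_idx - 1] += 0.35
    ecg[r_idx + 1] += 0.35

    resp = _render_resp(draws, config, eff, onset)
    resp = resp + (rng_noise.standard_normal(resp.size) * 0.02).astype(np.float32)

    pid = f"p{patient_index:04d}"
    channels = {
        "ABP": _apply_gaps(abp, config.fs_abp, draws.gap_starts["ABP"], draws.gap_lens["ABP"]),
        "ECG": _apply_gaps(ecg, config.fs_ecg, draws.gap_starts["ECG"], draws.gap_lens["ECG"]),
        "RESP": _apply_gaps(resp, config.fs_resp, draws.gap_starts["RESP"], draws.gap_lens["RESP"]),
        "SPO2": Channel(config.fs_spo2, draws.spo2, np.ones(draws.spo2.size, dtype=bool)),
    }

    labs = list(zip(draws.lab_times, draws.lab_values))
    if draws.shock_lab is not None:
        labs.append(draws.shock_lab)
        labs.sort()

    record = WaveformRecord(pid, channels, 0.0, labs, draws.covariates,
                            meta={"patient_index": patient_index,
                                  "seed": config.seed})
    truth = GroundTruth(
        patient_id=pid,
        shock=draws.shock,
        onset_s=onset,
        scenario1_feasible=draws.shock and config.pre_onset_hours * 3600 >= 24.5 * 3600,
        scenario2_feasible=draws.shock
        and config.post_onset_hours * 3600 >= (7 * 24 + 0.5) * 3600,
        effects=eff,
    )
    return record, truth


def simulate_cohort(config: SimulationConfig):
    """Lazily yield (record, truth) for each patient; seed-reproducible."""
    if config.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    for idx in range(config.n_patients):
        yield simulate_patient(config, idx)


def inject_preshock_drift(record: WaveformRecord, config: SimulationConfig,
                          onset: float, effects: DriftSpec) -> WaveformRecord:
    """Return a copy with drift applied only inside [onset - 90 min, onset).

    The patient is re-synthesized from the same base draws with the
    requested effects and the drift window spliced in; every sample
    outside the window is bit-identical to the input.
    """
    if onset - DRIFT_WINDOW_S < 0:
        raise ValueError("drift window extends before the record")
    idx = record.meta.get("patient_index")
    if idx is None:
        raise ValueError("record does not carry generator provenance")
    fresh, _ = simulate_patient(config, idx, effects=effects)
    w0, w1 = onset - DRIFT_WINDOW_S, onset
    channels = {}
    for name, ch in record.channels.items():
        i0, i1 = ch.sample_range(w0, w1)
        samples = ch.samples.copy()
        mask = ch.valid_mask.copy()
        samples[i0:i1] = fresh.channels[name].samples[i0:i1]
        mask[i0:i1] = fresh.channels[name].valid_mask[i0:i1]
        channels[name] = Channel(ch.sampling_rate, samples, mask)
    return WaveformRecord(record.patient_id, channels, record.record_start,
                          list(record.labs), record.covariates, dict(record.meta))
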