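"""Domain types and waveform/lab I/O.

A :class:`WaveformRecord` holds one ICU patient's aligned multi-channel
signals (ABP in mmHg, ECG in mV, RESP in arbitrary units, SpO2 in %),
each at its native sampling rate with an explicit validity mask, plus
timestamped serum-lactate labs and demographic covariates.

Time convention: all intervals are half-open ``[start, end)`` in
absolute seconds from ``record_start``; sample ``i`` of a channel at
rate ``fs`` covers ``[i/fs, (i+1)/fs)``.

Two on-disk formats are supported:

* CSV long format — one waveform file per patient with columns
  ``(timestamp, channel, value)``; rows for invalid samples are simply
  absent.  Labs and metadata travel in ``<id>_labs.csv`` and
  ``<id>_meta.json`` sidecars.
* A minimal WFDB-compatible layout — one format-16 ``.hea``/``.dat``
  record per channel (so each channel keeps its native rate), with
  invalid samples stored as the WFDB invalid-sample sentinel -32768.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("ABP", "ECG", "RESP", "SPO2")
_WFDB_INVALID = -32768
_WFDB_GAIN = {"ABP": 80.0, "ECG": 8000.0, "RESP": 400.0, "SPO2": 200.0}
_UNITS = {"ABP": "mmHg", "ECG": "mV", "RESP": "a.u.", "SPO2": "%"}


class RecordFormatError(ValueError):
    """Raised for unknown formats, corrupt headers or duplicate channels."""


@dataclass
class Channel:
    """One modality's samples at its native rate, with a validity mask."""

    sampling_rate: float
    samples: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if not np.issubdtype(self.samples.dtype, np.floating):
            self.samples = self.samples.astype(float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.shape != self.valid_mask.shape:
            raise ValueError("samples and valid_mask must have equal length")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def slice(self, start: float, end: float) -> "Channel":
        """Samples whose coverage lies inside [start, end) seconds."""
        i0, i1 = self.sample_range(start, end)
        return Channel(self.sampling_rate, self.samples[i0:i1], self.valid_mask[i0:i1])

    def sample_range(self, start: float, end: float) -> tuple[int, int]:
        fs = self.sampling_rate
        i0 = int(np.ceil(start * fs - 1e-9))
        i1 = int(np.ceil(end * fs - 1e-9))
        return max(i0, 0), min(i1, self.samples.size)


@dataclass
class Covariates:
    """Demographics used by the adjusted regression."""

    age: float
    sex: int  # 1 = male, 0 = female
    bmi: float
    neck_cm: float
    waist_cm: float

    def as_dict(self) -> dict:
        return {"age": self.age, "sex": self.sex, "bmi": self.bmi,
                "neck_cm": self.neck_cm, "waist_cm": self.waist_cm}


@dataclass
class WaveformRecord:
    """One patient's aligned channels, labs and covariates."""

    patient_id: str
    channels: dict[str, Channel]
    record_start: float = 0.0
    labs: list[tuple[float, float]] = field(default_factory=list)
    covariates: Covariates | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in self.channels:
            if name not in MODALITIES:
                raise RecordFormatError(f"unknown channel {name!r}")
        for t, lac in self.labs:
            if lac < 0:
                raise ValueError("lactate must be >= 0")

    @property
    def duration(self) -> float:
        return max((ch.duration for ch in self.channels.values()), default=0.0)

    def has_all_channels(self) -> bool:
        return all(m in self.channels for m in MODALITIES)


def missing_fraction(record: WaveformRecord, start: float, end: float) -> dict[str, float]:
    """Per-channel fraction of invalid samples over [start, end).

    The denominator is the number of samples the channel is expected to
    cover in the interval; samples beyond the channel's span count as
    missing.
    """
    if end <= start:
        raise ValueError("empty interval")
    out = {}
    for name, ch in record.channels.items():
        expected = int(round((end - start) * ch.sampling_rate))
        if expected == 0:
            out[name] = 0.0
            continue
        i0, i1 = ch.sample_range(start, end)
        valid = int(ch.valid_mask[i0:i1].sum())
        out[name] = 1.0 - valid / expected
    return out


# ---------------------------------------------------------------------------
# CSV long format
# ---------------------------------------------------------------------------

def write_csv_record(record: WaveformRecord, directory: str | Path) -> Path:
    """Write ``<id>.csv`` (long format), ``<id>_labs.csv`` and ``<id>_meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    meta_channels = {}
    for name, ch in record.channels.items():
        idx = np.flatnonzero(ch.valid_mask)
        frames.append(pd.DataFrame({
            "timestamp": idx / ch.sampling_rate,
            "channel": name,
            "value": ch.samples[idx],
        }))
        meta_channels[name] = {"sampling_rate": ch.sampling_rate,
                               "n_samples": int(ch.samples.size)}
    path = directory / f"{record.patient_id}.csv"
    body = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["timestamp", "channel", "value"])
    body.to_csv(path, index=False)  # pandas writes shortest round-trip reprs
    pd.DataFrame(record.labs, columns=["timestamp", "lactate_mmol_per_L"]).to_csv(
        directory / f"{record.patient_id}_labs.csv", index=False)
    meta = {"patient_id": record.patient_id, "record_start": record.record_start,
            "channels": meta_channels,
            "covariates": record.covariates.as_dict() if record.covariates else None}
    (directory / f"{record.patient_id}_meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _read_csv_record(path: Path) -> WaveformRecord:
    directory, pid = path.parent, path.stem
    meta_path = directory / f"{pid}_meta.json"
    if not meta_path.exists():
        raise RecordFormatError(f"missing metadata sidecar for {pid}")
    meta = json.loads(meta_path.read_text())
    body = pd.read_csv(path, float_precision="round_trip")
    channels = {}
    for name, info in meta["channels"].items():
        fs, n = float(info["sampling_rate"]), int(info["n_samples"])
        samples = np.zeros(n)
        mask = np.zeros(n, dtype=bool)
        rows = body[body["channel"] == name]
        if len(rows):
            idx = np.rint(rows["timestamp"].to_numpy() * fs).astype(int)
            if np.any((idx < 0) | (idx >= n)):
                raise RecordFormatError(f"timestamp outside declared span in {name}")
            samples[idx] = rows["value"].to_numpy()
            mask[idx] = True
        channels[name] = Channel(fs, samples, mask)
    labs_path = directory / f"{pid}_labs.csv"
    labs = []
    if labs_path.exists():
        lab_df = pd.read_csv(labs_path, float_precision="round_trip")
        labs = list(zip(lab_df["timestamp"], lab_df["lactate_mmol_per_L"]))
    cov = Covariates(**meta["covariates"]) if meta.get("covariates") else None
    return WaveformRecord(pid, channels, meta.get("record_start", 0.0), labs, cov)


# ---------------------------------------------------------------------------
# Minimal WFDB-compatible format (format 16, one record per channel)
# ---------------------------------------------------------------------------

def write_wfdb_record(record: WaveformRecord, directory: str | Path) -> Path:
    """Write one format-16 .hea/.dat pair per channel plus lab/meta sidecars.

    Samples are quantized by the per-modality gain; the declared
    precision of the round-trip is 1/gain.  Invalid samples are stored
    as the sentinel -32768.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, ch in record.channels.items():
        base = f"{record.patient_id}_{name}"
        gain = _WFDB_GAIN[name]
        q = np.rint(ch.samples * gain).astype(np.int64)
        q = np.clip(q, -32767, 32767)
        q[~ch.valid_mask] = _WFDB_INVALID
        q.astype("<i2").tofile(directory / f"{base}.dat")
        header = (f"{base} 1 {ch.sampling_rate:g} {ch.samples.size}\n"
                  f"{base}.dat 16 {gain:g}(0)/{_UNITS[name]} 16 0 0 0 0 {name}\n")
        (directory / f"{base}.hea").write_text(header)
    pd.DataFrame(record.labs, columns=["timestamp", "lactate_mmol_per_L"]).to_csv(
        directory / f"{record.patient_id}_labs.csv", index=False)
    meta = {"patient_id": record.patient_id, "record_start": record.record_start,
            "channels": sorted(record.channels),
            "covariates": record.covariates.as_dict() if record.covariates else None}
    (directory / f"{record.patient_id}_meta.json").write_text(json.dumps(meta, indent=1))
    return directory / f"{record.patient_id}_meta.json"


_HEA_SIGNAL_RE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)\s+(?P<gain>[\d.eE+-]+)\((?P<base>-?\d+)\)/(?P<units>\S+)"
    r"\s+\d+\s+\d+\s+\d+\s+\d+\s+\d+\s+(?P<desc>\S+)\s*$")


def _read_wfdb_channel(hea_path: Path) -> tuple[str, Channel]:
    lines = [ln for ln in hea_path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise RecordFormatError(f"corrupt header {hea_path.name}")
    head = lines[0].split()
    if len(head) < 4:
        raise RecordFormatError(f"corrupt header line in {hea_path.name}")
    fs, n = float(head[2]), int(head[3])
    m = _HEA_SIGNAL_RE.match(lines[1])
    if not m:
        raise RecordFormatError(f"corrupt signal line in {hea_path.name}")
    if m.group("fmt") != "16":
        raise RecordFormatError(f"unsupported WFDB format {m.group('fmt')}")
    gain = float(m.group("gain"))
    baseline = int(m.group("base"))
    raw = np.fromfile(hea_path.parent / m.group("file"), dtype="<i2")
    if raw.size != n:
        raise RecordFormatError(f"sample count mismatch in {m.group('file')}")
    mask = raw != _WFDB_INVALID
    samples = np.where(mask, (raw.astype(float) - baseline) / gain, 0.0)
    return m.group("desc"), Channel(fs, samples, mask)


def _read_wfdb_record(meta_path: Path) -> WaveformRecord:
    meta = json.loads(meta_path.read_text())
    pid = meta["patient_id"]
    directory = meta_path.parent
    channels = {}
    for name in meta["channels"]:
        hea = directory / f"{pid}_{name}.hea"
        if not hea.exists():
            continue  # explicitly absent channel
        desc, ch = _read_wfdb_channel(hea)
        if desc in channels:
            raise RecordFormatError(f"duplicate channel {desc}")
        channels[desc] = ch
    labs_path = directory / f"{pid}_labs.csv"
    labs = []
    if labs_path.exists():
        lab_df = pd.read_csv(labs_path, float_precision="round_trip")
        labs = list(zip(lab_df["timestamp"], lab_df["lactate_mmol_per_L"]))
    cov = Covariates(**meta["covariates"]) if meta.get("covariates") else None
    return WaveformRecord(pid, channels, meta.get("record_start", 0.0), labs, cov)


def read_waveform_record(path: str | Path, format: str = "csv") -> WaveformRecord:
    """Read a record previously written in CSV long format or WFDB layout.

    ``path`` is the ``<id>.csv`` file for CSV, or the ``<id>_meta.json``
    manifest for the WFDB layout.  Channels absent from the files are
    flagged absent (missing key), never zero-filled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv_record(path)
    if format == "wfdb":
        return _read_wfdb_record(path)
    raise RecordFormatError(f"unknown format {format!r}")
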