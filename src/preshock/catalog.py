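"""The fixed 299-feature catalog.

Four modalities contribute a fixed, versioned, ordered name list:

* ABP — 9 beat-level pressure parameters x 10 summary statistics = 90
* ECG — 89 heart-rate-variability indices over the R-R series
  (time, frequency, time-frequency, nonlinear domains)
* RESP — 9 breath-cycle parameters x 10 statistics + 22 respiratory
  rate variability (RRV) indices = 112
* SpO2 — 5 linear + 3 nonlinear summaries = 8

The cardinalities are structural constants of the pipeline; the module
asserts them at import time so any edit to the lists fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATALOG_VERSION = "1.0"

STAT_NAMES = ("Min", "Mean", "Max", "Median", "STD",
              "Skewness", "Kurtosis", "Hurst", "Lyapunov", "SampEn")

ABP_PARAMS = ("Psys", "Pdia", "PP", "MeanAP", "MAP", "HR",
              "TimeSBP2DBP", "AmplitudeSBP", "AmplitudeDBP")

RESP_PARAMS = ("Cycle_Amplitude", "Width", "PeakPeak_Time", "TroughTrough_Time",
               "Amplitude", "Cycle_Rate", "RVT",
               "Cycle_Symmetry_PeakTrough", "Cycle_Symmetry_RiseDecay")

# 89 HRV indices; every index the source material names is present
# (SDNN, SDANN, RMSSD, pNN50, MCVNN, ULF/VLF/LF/HF, LnHF, LF/HF,
#  STFT and wavelet power summaries, SD1, SD2, ApEn, SampEn, MSE,
#  DFA, CD).
HRV_TIME = (
    "MeanNN", "SDNN", "SDANN", "SDNNI", "RMSSD", "SDSD", "CVNN", "CVSD",
    "MedianNN", "MadNN", "MCVNN", "IQRNN", "pNN10", "pNN20", "pNN30", "pNN50",
    "MinNN", "MaxNN", "RangeNN", "SkewNN", "KurtNN", "Prc20NN", "Prc80NN",
    "HTI", "TINN",
)
HRV_FREQ = (
    "ULF", "VLF", "LF", "HF", "TotalPower", "LnVLF", "LnLF", "LnHF",
    "LnTotalPower", "LF_HF", "LFnu", "HFnu", "RelULF", "RelVLF", "RelLF",
    "RelHF", "PeakVLF", "PeakLF", "PeakHF",
)
HRV_TIMEFREQ = (
    "STFT_LF_Mean", "STFT_LF_STD", "STFT_HF_Mean", "STFT_HF_STD",
    "STFT_LFHF_Mean", "STFT_LFHF_STD",
    "WT_LF_Mean", "WT_LF_STD", "WT_HF_Mean", "WT_HF_STD",
    "WT_LFHF", "WT_Entropy",
)
HRV_NONLINEAR = (
    "SD1", "SD2", "SD1_SD2", "EllipseArea", "CSI", "CVI",
    "ApEn", "SampEn", "MSE_2", "MSE_3", "MSE_4", "MSE_5", "MSE_Mean",
    "DFA_Alpha1", "DFA_Alpha2", "DFA_Alpha", "CD", "Hurst", "Lyapunov",
    "LZC", "CTM", "ShanEn", "KFD", "PFD",
    "PIP", "IALS", "PSS", "PAS", "GI", "SI", "AI", "PI",
    "MFDFA_Alpha1_Peak",
)
HRV_NAMES = HRV_TIME + HRV_FREQ + HRV_TIMEFREQ + HRV_NONLINEAR

# 22 RRV indices over the breath-to-breath interval series.
RRV_NAMES = (
    "MeanBB", "SDBB", "RMSSD", "SDSD", "CVBB", "MedianBB",
    "Welch_LF", "Welch_HF", "Welch_LFHF",
    "Burg_LF", "Burg_HF", "Burg_LFHF",
    "LombScargle_LF", "LombScargle_HF", "LombScargle_LFHF",
    "SampEn", "SD1", "SD2",
    "WT_LF", "WT_HF", "WT_LFHF",
    "MFDFA_Alpha1_Peak",
)

SPO2_NAMES = ("Smin", "Smean", "Smax", "Smedian", "Ssd", "SampEn", "LZC", "CTM")

ABP_FEATURES = tuple(f"ABP_{p}_{s}" for p in ABP_PARAMS for s in STAT_NAMES)
ECG_FEATURES = tuple(f"ECG_HRV_{n}" for n in HRV_NAMES)
RESP_FEATURES = tuple(
    [f"RESP_{p}_{s}" for p in RESP_PARAMS for s in STAT_NAMES]
    + [f"RESP_RRV_{n}" for n in RRV_NAMES]
)
SPO2_FEATURES = tuple(f"SPO2_{n}" for n in SPO2_NAMES)

assert len(ABP_FEATURES) == 90
assert len(ECG_FEATURES) == 89
assert len(RESP_FEATURES) == 112
assert len(SPO2_FEATURES) == 8


@dataclass(frozen=True)
class FeatureCatalog:
    """Immutable ordered feature-name catalog with per-modality lists."""

    version: str
    abp: tuple[str, ...]
    ecg: tuple[str, ...]
    resp: tuple[str, ...]
    spo2: tuple[str, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return self.abp + self.ecg + self.resp + self.spo2

    @property
    def cardinalities(self) -> dict[str, int]:
        return {"ABP": len(self.abp), "ECG": len(self.ecg),
                "RESP": len(self.resp), "SPO2": len(self.spo2),
                "total": len(self.names)}

    def index(self, name: str) -> int:
        return self.names.index(name)


_CATALOG = FeatureCatalog(CATALOG_VERSION, ABP_FEATURES, ECG_FEATURES,
                          RESP_FEATURES, SPO2_FEATURES)
assert len(set(_CATALOG.names)) == 299


def catalog() -> FeatureCatalog:
    """The versioned catalog; repeated calls return the same object."""
    return _CATALOG
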