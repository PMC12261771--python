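"""Schema-validated run configuration for the command-line pipeline.

A single YAML/JSON file drives every stage; unknown keys are rejected
and the fully-resolved config (plus its hash and seed) is serialized
into every artifact's sidecar so a report is reproducible from its
sidecar alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import DriftSpec, SimulationConfig


class DriftSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rr_jitter_ms: float = 20.0
    resp_symmetry_shift: float = 0.22
    resp_rate_delta: float = -2.0
    sbp2dbp_jitter: float = 0.035
    pp_jitter_scale: float = 0.55

    def to_spec(self) -> DriftSpec:
        return DriftSpec(**self.model_dump())


class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 40
    shock_fraction: float = 1.0
    pre_onset_hours: float = 24.75
    post_onset_hours: float = 2.0
    missingness_rate: float = 0.01
    drift: DriftSettings = Field(default_factory=DriftSettings)

    def to_config(self, seed: int) -> SimulationConfig:
        d = self.model_dump()
        d.pop("drift")
        return SimulationConfig(seed=seed, drift=self.drift.to_spec(), **d)


class LabelingSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lactate_op: str = "ge"  # 'ge' or 'gt'
    scenario_preference: int = 1


class TrainingSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    top_k: int = 65
    threshold: float = 0.5
    n_boot: int = 1000


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "runs/default"
    record_format: str = "wfdb"  # 'wfdb' or 'csv'
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    labeling: LabelingSettings = Field(default_factory=LabelingSettings)
    training: TrainingSettings = Field(default_factory=TrainingSettings)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def sidecar(self) -> dict:
        return {"config": self.model_dump(), "config_hash": self.config_hash(),
                "seed": self.seed}


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
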