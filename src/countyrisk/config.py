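"""Pipeline configuration: a validated, hashable YAML-backed record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["SamplerSettings", "PipelineConfig"]


@dataclasses.dataclass
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.85
    max_treedepth: int = 10
    rhat_threshold: float = 1.01

    def validate(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 0:
            raise ValueError("sampler settings must be positive")
        if not (0 < self.target_accept < 1):
            raise ValueError("target_accept must lie in (0, 1)")


@dataclasses.dataclass
class PipelineConfig:
    records_csv: str | None = None
    census_csv: str | None = None
    covariates_csv: str | None = None
    out_dir: str = "countyrisk-out"
    seed: int = 0
    stage1: SamplerSettings = dataclasses.field(default_factory=SamplerSettings)
    stage2: SamplerSettings = dataclasses.field(
        default_factory=lambda: SamplerSettings(warmup=500, draws=500,
                                                target_accept=0.9,
                                                rhat_threshold=1.02)
    )
    ratio_specs: list[str] = dataclasses.field(default_factory=list)  # e.g. "BU/WU"
    eco_outcomes: list[str] = dataclasses.field(
        default_factory=lambda: ["BU/WU", "BU/WA"]
    )
    eco_models: list[str] = dataclasses.field(
        default_factory=lambda: [f"M{i}" for i in range(1, 26)]
    )
    pooled_method: str = "hyper_mean"

    def validate(self) -> None:
        self.stage1.validate()
        self.stage2.validate()
        if self.pooled_method not in ("hyper_mean", "median_of_counties"):
            raise ValueError(f"unknown pooled method {self.pooled_method!r}")
        for path in (self.records_csv, self.census_csv, self.covariates_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        for key in ("stage1", "stage2"):
            if isinstance(payload.get(key), dict):
                payload[key] = SamplerSettings(**payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the full configuration, embedded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
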