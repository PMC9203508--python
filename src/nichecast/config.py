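"""Run configuration.

Every constant the analysis protocol fixes — the 0.1° grid, the 0.5-unit
environmental-filter bins, the 2.5/97.5 hull percentiles, the 70/30
split repeated 10 times, the CBI > 0.5 retention rule, the 50 km coastal
buffer, the 1000 t catch display threshold — lives here as a named,
schema-validated default rather than a literal in the code.  Configs are
flat YAML; every stochastic stage derives its own seed from the master
seed plus the stage name.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class DomainConfig(BaseModel):
    bounds: tuple[float, float, float, float] = (-2.0, 8.0, 36.0, 48.0)
    cell_size: float = 0.1


class SynthConfig(BaseModel):
    n_occurrences: int = 1000
    effort_strength: float = 2.0
    effort_scale_km: float = 150.0
    duplicate_fraction: float = 0.05
    onland_fraction: float = 0.02
    unreliable_fraction: float = 0.05
    pre1990_fraction: float = 0.1079
    undated_fraction: float = 0.1637
    niche_optima: dict[str, float] = Field(
        default_factory=lambda: {"SBT": 17.5, "SBTr": 5.0, "Log_PP": -6.7}
    )
    niche_tolerances: dict[str, float] = Field(
        default_factory=lambda: {"SBT": 2.0, "SBTr": 2.5, "Log_PP": 0.8}
    )
    gcm_bias_sd: float = 0.5
    gcm_noise_sd: float = 0.2
    n_gcms: int = 5
    n_eez: int = 4


class PrepConfig(BaseModel):
    recent_year: int = 1990
    edge_distance_km: float = 100.0
    outlier_distance_km: float = 1000.0
    round_decimals: int = 4
    min_depth_m: float = 150.0
    max_depth_m: float = 1000.0
    coastal_buffer_km: float = 50.0


class EnvSpaceConfig(BaseModel):
    priority: list[str] = Field(
        default_factory=lambda: ["SBT", "SBTr", "Log_PP", "SBTvar", "SST", "SSTr", "SSTvar", "SSS"]
    )
    correlation_threshold: float = 0.7
    bin_width: float = 0.5
    hull_percentiles: tuple[float, float] = (2.5, 97.5)


class ModelConfig(BaseModel):
    algorithms: list[str] = Field(
        default_factory=lambda: ["NPPEN", "GLM", "GAM", "GBM", "ANN", "FDA", "MARS", "RF"]
    )
    cv_runs: int = 10
    cbi_threshold: float = 0.5
    curve_tolerance: float = 0.02


class ProjectionConfig(BaseModel):
    rcps: list[float] = Field(default_factory=lambda: [2.6, 4.5, 8.5])
    decades: list[str] = Field(default_factory=lambda: ["2030-2039", "2050-2059", "2090-2099"])
    area_threshold: float = 0.5
    threshold_sweep: list[float] = Field(default_factory=lambda: [0.3, 0.5, 0.7])


class EEZConfig(BaseModel):
    min_catch_t: float = 1000.0


class RunConfig(BaseModel):
    """Validated, flat pipeline configuration."""

    species: str = "synthfish"
    seed: int = 42
    domain: DomainConfig = Field(default_factory=DomainConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    prep: PrepConfig = Field(default_factory=PrepConfig)
    envspace: EnvSpaceConfig = Field(default_factory=EnvSpaceConfig)
    models: ModelConfig = Field(default_factory=ModelConfig)
    projection: ProjectionConfig = Field(default_factory=ProjectionConfig)
    eez: EEZConfig = Field(default_factory=EEZConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return (self.seed * 100_003 + zlib.adler32(stage.encode())) % (2**31 - 1)
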