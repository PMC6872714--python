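"""Pipeline configuration: a single validated record driving every stage.

The configuration round-trips losslessly through YAML; the defaults encode
the study conditions (500 ml tidal volume, tau = 5 s, dt = 1 ms, metrics at
peak inhalation t* = 1.25 s, air at ~20 C, 20-patient cohort).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .breathing import BreathingWaveform
from .flow_solver import FluidProperties, SolverSettings
from .geometry import GeometryParams

__all__ = [
    "WaveformConfig",
    "FluidConfig",
    "SolverConfig",
    "CohortConfig",
    "PipelineConfig",
]


class WaveformConfig(BaseModel):
    tidal_volume_ml: float = Field(500.0, gt=0)
    cycle_period_s: float = Field(5.0, gt=0)
    duration_s: float | None = Field(None, gt=0)  # default: half cycle
    time_step_s: float = Field(1e-3, gt=0)
    sample_time_s: float = Field(1.25, gt=0)

    def build(self) -> BreathingWaveform:
        return BreathingWaveform.from_tidal_volume(
            tidal_volume_m3=self.tidal_volume_ml * 1e-6,
            cycle_period_s=self.cycle_period_s,
            duration_s=self.duration_s,
            time_step_s=self.time_step_s,
        )


class FluidConfig(BaseModel):
    density_kgm3: float = Field(1.204, gt=0)
    viscosity_pas: float = Field(1.82e-5, gt=0)

    def build(self) -> FluidProperties:
        return FluidProperties(**self.model_dump())


class SolverConfig(BaseModel):
    friction_model: str = "laminar_turbulent_blend"
    expansion_loss_enabled: bool = True
    expansion_threshold: float = Field(0.10, gt=0)
    area_floor_m2: float = Field(1e-7, gt=0)

    def build(self, waveform_cfg: WaveformConfig) -> SolverSettings:
        return SolverSettings(
            time_step_s=waveform_cfg.time_step_s,
            sample_time_s=waveform_cfg.sample_time_s,
            friction_model=self.friction_model,
            expansion_loss_enabled=self.expansion_loss_enabled,
            expansion_threshold=self.expansion_threshold,
            area_floor_m2=self.area_floor_m2,
        )


class CohortConfig(BaseModel):
    n: int = Field(20, ge=2)
    seed: int = 0
    sigma_geom: float = Field(0.05, ge=0)
    sigma_ahi: float = Field(0.2, ge=0)


class PipelineConfig(BaseModel):
    """Full pipeline configuration (geometry -> simulation -> metrics ->
    correlation)."""

    geometry: GeometryParams = GeometryParams()
    waveform: WaveformConfig = WaveformConfig()
    fluid: FluidConfig = FluidConfig()
    solver: SolverConfig = SolverConfig()
    cohort: CohortConfig = CohortConfig()
    output_dir: str = "airwaycp_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True), encoding="utf-8"
        )
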