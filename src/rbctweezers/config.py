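"""Run configuration: a validated schema for the whole pipeline.

Configs are JSON or TOML files validated against the pydantic schema
below before any stage runs; unknown keys are rejected so typos fail
fast instead of silently falling back to defaults.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .physics import Chamber, Medium
from .synthetic import (
    CohortDesign,
    NoiseModel,
    TrueParameterSchedule,
    leukodepleted_schedule,
    standard_schedule,
)
from .units import convert_units


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MediumConfig(_Strict):
    permittivity: float = Field(1.06e-9, gt=0, description="C^2 N^-1 m^-2")
    viscosity_cP: float = Field(1.65, gt=0)

    def build(self) -> Medium:
        return Medium(
            permittivity=self.permittivity,
            viscosity=convert_units(self.viscosity_cP, "cP", "Pa*s"),
        )


class ChamberConfig(_Strict):
    d_m: float = Field(1.0e-2, gt=0, description="electrode separation")
    z1_m: float = Field(50e-6, gt=0, description="cell-to-floor distance Z1")
    z2_m: float = Field(50e-6, gt=0, description="cell-to-coverslip distance Z2")

    def build(self) -> Chamber:
        return Chamber(electrode_separation=self.d_m, z_bottom=self.z1_m, z_top=self.z2_m)


class CohortConfig(_Strict):
    days: list[int] = Field(default=[1, 8, 15, 22, 29, 36])
    n_cells_zeta: int = Field(40, ge=1)
    n_cells_elastic: int = Field(20, ge=0)
    arm: str = Field("standard", pattern="^(standard|leukodepleted)$")

    def build(self, seed: int) -> CohortDesign:
        return CohortDesign(
            days=tuple(self.days),
            n_cells_zeta=self.n_cells_zeta,
            n_cells_elastic=self.n_cells_elastic,
            arm=self.arm,
            seed=seed,
        )


class NoiseConfig(_Strict):
    velocity_rel_sd: float = Field(0.04, ge=0)
    position_noise_sd_m: float = Field(0.2e-6, ge=0)
    length_noise_sd_m: float = Field(0.15e-6, ge=0)

    def build(self) -> NoiseModel:
        return NoiseModel(
            velocity_rel_sd=self.velocity_rel_sd,
            position_noise_sd=self.position_noise_sd_m,
            length_noise_sd=self.length_noise_sd_m,
        )


class RosConfig(_Strict):
    enabled: bool = True
    n_events: int = Field(20_000, ge=100)


class RunConfig(_Strict):
    """Top-level pipeline configuration (all fields have defaults)."""

    medium: MediumConfig = MediumConfig()
    chamber: ChamberConfig = ChamberConfig()
    cohort: CohortConfig = CohortConfig()
    noise: NoiseConfig = NoiseConfig()
    ros: RosConfig = RosConfig()
    seed: int = 0
    out_dir: str = "rbc_run"
    frames: bool = False  # also render/consume image stacks (slow path)

    def schedule(self) -> TrueParameterSchedule:
        if self.cohort.arm == "leukodepleted":
            return leukodepleted_schedule()
        return standard_schedule()


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a JSON/TOML config file (or defaults) and apply overrides.

    Raises :class:`ConfigError` on unknown keys, bad types or an
    unreadable file.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        try:
            if path.suffix.lower() == ".toml":
                data = tomllib.loads(path.read_text())
            else:
                data = json.loads(path.read_text())
        except (OSError, ValueError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
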