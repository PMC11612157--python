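"""Declarative experiment configuration with validation and seed derivation.

A single YAML file describes an experiment: optics (DMD and camera geometry,
pixel size, max irradiance), culture parameters, illumination schedule and
seeds.  Unknown keys are rejected so typos fail loudly, every numeric field
is validated, and each module draws its randomness from a seed derived
deterministically from the root seed — no hidden entropy sources.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OpticsConfig(_Strict):
    dmd_shape: tuple[int, int] = (1080, 1920)
    camera_shape: tuple[int, int] = (2048, 2048)
    pixel_size_um: float = Field(1.083, gt=0)
    max_irradiance: float = Field(175.0, gt=0)
    blur_sigma_px: float = Field(0.0, ge=0)

    @field_validator("dmd_shape", "camera_shape")
    @classmethod
    def _positive_dims(cls, v):
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("image dimensions must be positive")
        return v


class CultureConfig(_Strict):
    n_apopto: int = Field(500, ge=0)
    n_insensitive: int = Field(0, ge=0)
    k_on: float = Field(1e-3, gt=0)
    k_off_half_life_s: float = Field(17.0, gt=0)
    theta_I: float = Field(35.0, gt=0)
    dose_scale: float = Field(0.286, gt=0)
    death_threshold_median: float = Field(1.0, gt=0)
    death_threshold_sigma: float = Field(0.1, gt=0)
    t_lag_h: float = Field(0.5, gt=0)
    gfp_half_life_h: float = Field(3.0, gt=0)
    diffusion_um2_per_min: float = Field(0.5, ge=0)
    doubling_time_h: float = Field(14.0, gt=0)
    shielded: bool = False


class ScheduleEntry(_Strict):
    pattern: str = "full_on"
    start_h: float = Field(0.0, ge=0)
    stop_h: float = Field(16.0, gt=0)


class ExperimentConfig(_Strict):
    seed: int = Field(..., ge=0)
    optics: OpticsConfig = OpticsConfig()
    culture: CultureConfig = CultureConfig()
    schedule: list[ScheduleEntry] = []
    duration_h: float = Field(16.0, gt=0)
    imaging_interval_min: float = Field(30.0, gt=0)
    output_dir: str = "out"

    def derive_seed(self, module: str) -> int:
        """Deterministic per-module seed below 2³¹."""
        return (self.seed + zlib.crc32(module.encode())) % (2**31)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read, validate, and default-fill an experiment config file."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return ExperimentConfig(**raw)
    except Exception as exc:  # pydantic ValidationError carries the key names
        raise ConfigError(f"invalid config {path}: {exc}") from exc
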