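"""Run configuration: YAML in, validated typed config out.

Defaults mirror the acquisition and analysis conventions of the 10 Hz
fast-fMRI pulsation studies this pipeline implements: band edges
cardiac 0.51-5 Hz / respiratory 0.08-0.49 Hz / vasomotor 0.01-0.08 Hz,
cycle lengths 0.9 / 6 / 20 s, pyramid depths 3 / 1 / 0, permutation
testing with 5000 sign flips at alpha 0.05.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .cycles import BAND_CYCLE_SECONDS
from .flow import BAND_PYRAMID_DEPTH

__all__ = ["RunConfig", "load_config", "BandConfig", "FlowConfig", "StatsConfig"]


class BandConfig(BaseModel):
    f_low: float
    f_high: float

    @model_validator(mode="after")
    def _ordered(self):
        if not 0 <= self.f_low < self.f_high:
            raise ValueError("need 0 <= f_low < f_high")
        return self


class FlowConfig(BaseModel):
    window_radius: int = 2
    pyramid_depth: dict[str, int] = Field(
        default_factory=lambda: dict(BAND_PYRAMID_DEPTH)
    )
    conditioning_threshold: float = 1e-4
    n_iter: int = 2
    ridge: float = 0.01


class StatsConfig(BaseModel):
    n_perm: int = 5000
    alpha: float = 0.05
    use_tfce: bool = True
    tfce_h: float = 2.0
    tfce_e: float = 0.5
    sigma_threshold: float = 4.0


class PhantomSimConfig(BaseModel):
    kind: Literal["phantom"] = "phantom"
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    duration_s: float = 60.0
    pulse_freq_hz: float = 2.0
    peak_velocity_cm_s: float = 22.0
    noise_sd: float = 0.01


class CohortSimConfig(BaseModel):
    kind: Literal["cohort"] = "cohort"
    n_subjects: int = 22
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    duration_s: float = 60.0
    noise_sd: float = 0.01


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    mode: Literal["phantom", "cohort"]
    output_dir: Path
    seed: int = 0
    input_series: Path | None = None
    simulation: PhantomSimConfig | CohortSimConfig | None = None
    bands: dict[str, BandConfig] = Field(
        default_factory=lambda: {
            "cardiac": BandConfig(f_low=0.51, f_high=5.0),
            "respiratory": BandConfig(f_low=0.08, f_high=0.49),
            "vasomotor": BandConfig(f_low=0.01, f_high=0.08),
        }
    )
    cycle_seconds: dict[str, float] = Field(
        default_factory=lambda: dict(BAND_CYCLE_SECONDS)
    )
    flow: FlowConfig = Field(default_factory=FlowConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    n_spectrum_bins: int = 4096
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _has_input(self):
        if self.simulation is None and self.input_series is None:
            raise ValueError("config needs either a simulation spec or input_series")
        if self.input_series is not None and not Path(self.input_series).exists():
            raise ValueError(f"input_series does not exist: {self.input_series}")
        if self.simulation is not None and self.simulation.kind != self.mode:
            raise ValueError("simulation kind must match run mode")
        return self

    def cycle_frames(self, band: str, fs: float) -> int:
        n = self.cycle_seconds[band] * fs
        # tolerate float32 round-trip of the TR stored in NIfTI headers
        if abs(n - round(n)) > 1e-3:
            raise ValueError(
                f"cycle length {self.cycle_seconds[band]} s x fs {fs} Hz "
                "is not an integer frame count"
            )
        return int(round(n))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    return RunConfig.model_validate(raw)
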