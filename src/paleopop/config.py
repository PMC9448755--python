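"""Declarative pipeline configuration.

Defaults reproduce the analysis constants: τ ∈ {0.1, 0.5, 0.9}, 1000
h-block folds of 70/30 with h = 4500 km, viability threshold 0.2
persons/100 km², 500-year time steps.  Unknown keys are rejected on load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .qgam import DEFAULT_LAMBDA_GRID


class PeriodSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    GS2: float = 21.0
    GI1: float = 14.7
    GS1: float = 11.7
    HolInit: float = 11.7
    EHol: float = 8.0

    def as_dict(self) -> dict[str, float]:
        return dict(self.model_dump())


class WorldSettings(BaseModel):
    """Synthetic-world overrides (subset of SyntheticWorldConfig)."""

    model_config = ConfigDict(extra="forbid")
    grid_nlat: int = 36
    grid_nlon: int = 60
    n_societies: int = 340
    noise_sd_log10density: float = 0.25
    time_start_kyBP: float = 21.0
    time_end_kyBP: float = 8.0
    time_step_ky: float = 0.5


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    taus: tuple[float, ...] = (0.1, 0.5, 0.9)
    n_folds: int = 1000
    train_frac: float = 0.7
    h_km: float = 4500.0
    strategy: str = "buffered"
    d_min: float = 0.2
    basis_size: int = 10
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    analogy_policy: str = "variable"
    variables: tuple[str, ...] = ("ET", "TS", "TAP")
    seed: int = 0
    dates_per_person: float = 0.002
    periods: PeriodSettings = PeriodSettings()
    world: WorldSettings = WorldSettings()
    out_dir: str = "results"

    @field_validator("taus")
    @classmethod
    def _taus_in_unit(cls, v):
        if any(not 0.0 < t < 1.0 for t in v):
            raise ValueError("taus must lie in (0, 1)")
        return v

    @field_validator("train_frac")
    @classmethod
    def _frac(cls, v):
        if not 0.0 < v < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        return v

    @field_validator("strategy")
    @classmethod
    def _strategy(cls, v):
        if v not in ("buffered", "literal"):
            raise ValueError("strategy must be 'buffered' or 'literal'")
        return v


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)


def dump_config(cfg: PipelineConfig) -> dict:
    return cfg.model_dump()
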