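"""Run configuration: YAML round-trip with strict validation.

The config mirrors the stage parameters one-to-one; unknown keys are
rejected so typos fail before any computation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cohort import DEFAULT_TWIN_SHARE

__all__ = ["RunConfig", "GeographyConfig", "CohortSection", "BiasGridSection",
           "FeBiasSection", "TraitSection", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeographyConfig(_Strict):
    n_counties: int = 98
    districts_per_county: int = 14
    parishes_per_district: int = 2
    cells_per_parish: int = 90


class KernelSection(_Strict):
    scales_km: list[float]
    weights: list[float]
    long_share: float


class CohortSection(_Strict):
    n_families: int = 18479
    q: float = 0.012
    p: float = 0.283
    agegap_mean: float = 4.5
    twin_share: float = DEFAULT_TWIN_SHARE
    sibling_error_correlation: float = 0.0
    birth_year_range: tuple[int, int] = (1936, 1965)
    error_kernel: Optional[KernelSection] = None   # None = calibrated default
    move_kernel: Optional[KernelSection] = None

    @field_validator("p", "q", "twin_share", "sibling_error_correlation")
    @classmethod
    def _unit_interval(cls, v, info):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must lie in [0, 1], got {v}")
        return v


class BiasGridSection(_Strict):
    levels: list[str] = Field(default_factory=lambda: ["district"])
    rho_grid: list[float] = Field(default_factory=lambda: [0.0, 0.5, 0.9])
    k_grid: list[float] = Field(default_factory=lambda: [0.0, 0.5, 1.0])
    p_by_level: dict[str, float] = Field(
        default_factory=lambda: {"cell": 0.283, "parish": 0.168, "district": 0.158})
    q_by_level: dict[str, float] = Field(
        default_factory=lambda: {"cell": 0.012, "parish": 0.009, "district": 0.009})
    n_reps: int = 200
    n_surfaces: int = 10
    include_oriv: bool = False


class FeBiasSection(_Strict):
    rho_grid: list[float] = Field(default_factory=lambda: [0.0, 0.5, 0.9])
    r_grid: list[float] = Field(default_factory=lambda: [-0.5, 0.0, 0.5])
    sigma_ratios: list[float] = Field(default_factory=lambda: [0.1, 0.5, 1.0, 5.0])
    beta: float = 1.0
    p: float = 0.158
    q: float = 0.009
    n_reps: int = 250


class TraitSection(_Strict):
    rho: float = 0.975
    noise_sd: float = 1.0
    p_error: float = 0.283
    ref_multiple: int = 10
    level: str = "district"


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "sibloc_output"
    geography: GeographyConfig = Field(default_factory=GeographyConfig)
    cohort: CohortSection = Field(default_factory=CohortSection)
    bias_grid: BiasGridSection = Field(default_factory=BiasGridSection)
    fe_bias: FeBiasSection = Field(default_factory=FeBiasSection)
    trait: TraitSection = Field(default_factory=TraitSection)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
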