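"""Run configuration: a validated, fully-defaulted description of an
end-to-end analysis.

Configs are YAML with nested sections (cohort / analysis / economics);
unknown keys are rejected for typo safety and every range is checked
before any computation starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .erf import AGE_GROUPS

__all__ = ["CohortConfig", "AnalysisConfig", "EconomicsConfig", "RunConfig", "validate_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArchetypeConfig(_Strict):
    name: str
    koppen: str
    annual_mean_temp: float | None = None
    seasonal_amplitude: float | None = None
    uhi_amplitude: float | None = None

    def overrides(self) -> dict:
        out = {}
        for key in ("annual_mean_temp", "seasonal_amplitude", "uhi_amplitude"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


_DEFAULT_ARCHETYPES = [
    ArchetypeConfig(name="oceanic", koppen="Cfb", annual_mean_temp=10.0, seasonal_amplitude=7.0),
    ArchetypeConfig(name="mediterranean", koppen="Csa", annual_mean_temp=17.0, seasonal_amplitude=8.0),
    ArchetypeConfig(name="continental", koppen="Dfb", annual_mean_temp=8.0, seasonal_amplitude=11.0),
    ArchetypeConfig(name="subpolar", koppen="Dfc", annual_mean_temp=4.0, seasonal_amplitude=12.0),
]


class CohortConfig(_Strict):
    n_cities: int = Field(default=10, ge=1)
    grid_rows: int = Field(default=40, ge=2)
    grid_cols: int = Field(default=40, ge=2)
    start_date: str = "2015-01-01"
    end_date: str = "2017-12-31"
    uhi_amplitude: float = Field(default=2.0, ge=0)
    uhi_seasonal_modulation: float = Field(default=0.3, ge=0, le=1)
    weather_autocorrelation: float = Field(default=0.7, ge=0, lt=1)
    weather_sd: float = Field(default=3.0, gt=0)
    water_fraction: float = Field(default=0.05, ge=0, lt=1)
    hill_height: float = Field(default=0.0, ge=0)
    total_adults: float = Field(default=1_000_000.0, gt=0)
    population_impervious_spearman: float = Field(default=0.47, ge=-1, le=1)
    n_draws: int = Field(default=100, ge=1)
    coefficient_sd: float = Field(default=0.1, ge=0)
    archetypes: list[ArchetypeConfig] = Field(default_factory=lambda: list(_DEFAULT_ARCHETYPES))

    @model_validator(mode="after")
    def _non_empty_archetypes(self) -> "CohortConfig":
        if not self.archetypes:
            raise ValueError("archetype list must not be empty")
        return self


class AnalysisConfig(_Strict):
    extreme_fraction: float = Field(default=0.02, gt=0, le=0.5)
    elevation_threshold_m: float = Field(default=100.0, gt=0)
    day_classification: Literal["cell", "domain"] = "cell"
    imperviousness_bin_width: float = Field(default=5.0, gt=0)
    mc_bin_width: float = Field(default=0.01, gt=0)
    confidence_level_median: float = Field(default=0.95, gt=0, lt=1)
    confidence_level_adverse: float = Field(default=0.90, gt=0, lt=1)
    correlation_alpha: float = Field(default=0.01, gt=0, lt=1)


class EconomicsConfig(_Strict):
    vsl_base: float = Field(default=3.6e6, gt=0)
    vsl_ppp: float = Field(default=0.853, gt=0)
    vsl_cpi_base: float = Field(default=84.7, gt=0)
    cpi_target: float = Field(default=107.8, gt=0)
    voly_base: float = Field(default=40_000.0, gt=0)
    voly_cpi_base: float = Field(default=93.1, gt=0)
    voly_low: float = Field(default=29_000.0, gt=0)
    voly_high: float = Field(default=116_000.0, gt=0)
    life_expectancy: dict[str, float] = Field(
        default_factory=lambda: {"20-44": 50.0, "45-64": 28.0, "65-74": 16.0, "75-84": 9.0, "85+": 5.0}
    )

    @model_validator(mode="after")
    def _check_life_table(self) -> "EconomicsConfig":
        missing = set(AGE_GROUPS) - set(self.life_expectancy)
        if missing:
            raise ValueError(f"life_expectancy missing age groups {sorted(missing)}")
        return self


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/demo"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    economics: EconomicsConfig = Field(default_factory=EconomicsConfig)


def validate_config(raw: str | dict | Path) -> RunConfig:
    """Parse and validate a YAML config (text, path or mapping) into a
    typed, defaulted :class:`RunConfig`; unknown keys and out-of-range
    values raise with the offending entry named."""
    if isinstance(raw, Path):
        raw = raw.read_text()
    if isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = raw
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return RunConfig.model_validate(data)
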