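"""Monetary valuation of attributable-mortality differentials.

Two accounting bases are supported:

* **VSL** (value of a statistical life): the annual urban-minus-rural
  attributable-mortality differential per 100,000 adults is multiplied
  by a VSL converted to target-year euros via purchasing power parity
  and the consumer price index ratio,

      VSL_target-EUR = VSL_base-currency × PPP × CPI_target / CPI_base.

* **VOLY** (value of a life year): per-age differentials are first
  weighted by remaining life expectancy to years of life lost (YLL),
  then valued per life year (central plus low/high bounds).

Headline currency amounts are reported at 3 significant figures for
VSL-scale values and 2 for VOLY-scale values; unrounded values are
carried internally.  No discounting of future life years is applied.
The per-adult denominator is the adult (20+) population of the analysis
domain, the youngest modelled age group starting at 20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .erf import AGE_GROUPS

__all__ = [
    "CurrencyBasis",
    "ValuationParams",
    "LifeTable",
    "EconomicImpact",
    "convert_valuation",
    "round_sig",
    "vsl_impact",
    "compute_yll",
    "voly_impact",
    "economic_impact",
]


@dataclass(frozen=True)
class CurrencyBasis:
    """PPP (EUR per unit of source currency; 1 for EUR inputs) and CPI
    index values for the base and target years."""

    ppp: float
    cpi_base: float
    cpi_target: float

    def __post_init__(self) -> None:
        if min(self.ppp, self.cpi_base, self.cpi_target) <= 0:
            raise ValueError("PPP and CPI values must be positive")


def convert_valuation(amount: float, basis: CurrencyBasis) -> float:
    """amount × PPP × CPI_target / CPI_base, in target-year EUR."""
    if amount <= 0:
        raise ValueError("amount must be positive")
    return amount * basis.ppp * basis.cpi_target / basis.cpi_base


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (for reported headline
    values)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class ValuationParams:
    """Calibrated monetary parameters in target-year EUR."""

    vsl: float
    voly_central: float
    voly_low: float
    voly_high: float

    def __post_init__(self) -> None:
        if not self.voly_low <= self.voly_central <= self.voly_high:
            raise ValueError("VOLY bounds must satisfy low <= central <= high")
        if self.vsl <= 0:
            raise ValueError("VSL must be positive")


def default_valuation() -> ValuationParams:
    """VSL of 3.6 M 2005-USD converted with 2005 euro-area PPP 0.853 and
    CPI 84.7→107.8; VOLY of 40,000 2010-EUR with CPI 93.1→107.8, bounds
    29,000–116,000 2021-EUR."""
    vsl = convert_valuation(3.6e6, CurrencyBasis(ppp=0.853, cpi_base=84.7, cpi_target=107.8))
    voly = convert_valuation(40_000.0, CurrencyBasis(ppp=1.0, cpi_base=93.1, cpi_target=107.8))
    return ValuationParams(vsl=vsl, voly_central=voly, voly_low=29_000.0, voly_high=116_000.0)


@dataclass(frozen=True)
class LifeTable:
    """Expected remaining life years per age group; non-increasing with
    age."""

    life_expectancy: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AGE_GROUPS) - set(self.life_expectancy)
        if missing:
            raise ValueError(f"missing age groups {sorted(missing)}")
        vals = [self.life_expectancy[a] for a in AGE_GROUPS]
        if any(v < 0 for v in vals):
            raise ValueError("life expectancy must be non-negative")
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("life expectancy must be non-increasing across age groups")


def default_life_table() -> LifeTable:
    """Rounded European remaining life expectancy at the group midpoints."""
    return LifeTable({"20-44": 50.0, "45-64": 28.0, "65-74": 16.0, "75-84": 9.0, "85+": 5.0})


def vsl_impact(annual_differential_per_100k: float, vsl: float) -> float:
    """EUR per adult inhabitant per year: (AN per 100k / 100,000) × VSL."""
    return annual_differential_per_100k / 1e5 * vsl


def compute_yll(
    per_age_annual_per_100k: Mapping[str, float], life_table: LifeTable
) -> float:
    """Years of life lost per 100k per year: Σ_age AN_age × LE_age."""
    missing = set(AGE_GROUPS) - set(per_age_annual_per_100k)
    if missing:
        raise ValueError(f"missing age groups {sorted(missing)}")
    return float(
        sum(per_age_annual_per_100k[a] * life_table.life_expectancy[a] for a in AGE_GROUPS)
    )


def voly_impact(yll_per_100k: float, voly: float) -> float:
    """EUR per adult inhabitant per year: (YLL per 100k / 100,000) × VOLY."""
    return yll_per_100k / 1e5 * voly


@dataclass
class EconomicImpact:
    """Per-city monetary valuation of the UHI mortality differential, in
    target-year EUR per adult inhabitant per year."""

    vsl_heat: float
    vsl_cold: float
    vsl_net: float
    yll_heat_per_100k: float
    yll_cold_per_100k: float
    yll_net_per_100k: float
    voly_net_central: float
    voly_net_low: float
    voly_net_high: float

    def as_row(self) -> dict[str, float]:
        return dict(self.__dict__)


def economic_impact(
    heat_per_100k: float,
    cold_per_100k: float,
    per_age_heat: Mapping[str, float],
    per_age_cold: Mapping[str, float],
    valuation: ValuationParams,
    life_table: LifeTable,
) -> EconomicImpact:
    """Value heat/cold/net annual mortality differentials under both the
    VSL and the YLL/VOLY accounting."""
    vsl_heat = vsl_impact(heat_per_100k, valuation.vsl)
    vsl_cold = vsl_impact(cold_per_100k, valuation.vsl)
    yll_heat = compute_yll(per_age_heat, life_table)
    yll_cold = compute_yll(per_age_cold, life_table)
    yll_net = yll_heat + yll_cold
    return EconomicImpact(
        vsl_heat=vsl_heat,
        vsl_cold=vsl_cold,
        vsl_net=vsl_heat + vsl_cold,
        yll_heat_per_100k=yll_heat,
        yll_cold_per_100k=yll_cold,
        yll_net_per_100k=yll_net,
        voly_net_central=voly_impact(yll_net, valuation.voly_central),
        voly_net_low=voly_impact(yll_net, valuation.voly_low),
        voly_net_high=voly_impact(yll_net, valuation.voly_high),
    )
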