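"""Daily temperature-attributable mortality per cell, age group and day.

The attributable fraction of deaths on a day at temperature ``t`` is

    AF = (RR - 1) / RR

with RR the (lag-cumulative) relative risk at ``t``.  Multiplying AF by
the age group's annual all-cause mortality rate, divided by the length
of the calendar year, gives the daily attributable number AN per 100,000
inhabitants of that age group.  Each cell-day is classified warm or cold
per age group by comparing the cell's temperature with the age-specific
MMT; the same day can be heat-related for one age group and cold-related
for another.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .erf import AGE_GROUPS, ERFCurve
from .grids import AnalysisMask, DailyTemperatureCube, StaticLayer

__all__ = [
    "AgeStructure",
    "BaselineMortality",
    "ExtremeDaySets",
    "CellAttribution",
    "attributable_fraction",
    "daily_attributable_number",
    "classify_thermal",
    "find_extreme_days",
    "aggregate_ages",
    "attribute_cube",
    "esp2013_age_structure",
]


@dataclass(frozen=True)
class AgeStructure:
    """Adult age-group shares (fractions summing to 1)."""

    shares: dict[str, float]
    source: str = "local"

    def __post_init__(self) -> None:
        missing = set(AGE_GROUPS) - set(self.shares)
        if missing:
            raise ValueError(f"missing age groups {sorted(missing)}")
        vals = np.array([self.shares[a] for a in AGE_GROUPS])
        if np.any(vals < 0):
            raise ValueError("age shares must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"age shares sum to {vals.sum()}, expected 1")


@dataclass(frozen=True)
class BaselineMortality:
    """Annual all-cause deaths per 100,000 per age group (averaged over
    the analysis years)."""

    rates: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AGE_GROUPS) - set(self.rates)
        if missing:
            raise ValueError(f"missing age groups {sorted(missing)}")
        if any(self.rates[a] < 0 for a in AGE_GROUPS):
            raise ValueError("baseline mortality rates must be non-negative")


def esp2013_age_structure() -> AgeStructure:
    """Adult (20+) age shares of the 2013 European standard population,
    from the packaged reference table."""
    with resources.files("uhimort").joinpath("data/esp2013.csv").open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    df = df[df["age_group"].isin(AGE_GROUPS)]
    tot = df["standard_population"].sum()
    shares = {r.age_group: r.standard_population / tot for r in df.itertuples()}
    return AgeStructure(shares, source="ESP2013")


def attributable_fraction(rr: float | np.ndarray) -> float | np.ndarray:
    """AF = (RR − 1)/RR.

    Curves are recentred so RR >= 1 on the U-shape; interpolation noise
    marginally below 1 (within 1e-4, the largest dip a curve recentred at
    0.1 °C MMT resolution can legitimately show between grid points) is
    clamped to 1, anything lower is a contract violation.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("relative risk must be positive")
    if np.any(rr < 1.0 - 1e-4):
        raise ValueError(f"relative risk below 1 (min {rr.min()}); curve not recentred?")
    rr = np.maximum(rr, 1.0)
    af = (rr - 1.0) / rr
    return af if af.ndim else float(af)


def daily_attributable_number(
    af: float | np.ndarray, annual_rate_per_100k: float, days_in_year: int | np.ndarray
) -> float | np.ndarray:
    """AN per 100k per day = AF × annual rate / calendar-year length."""
    if np.any(np.asarray(annual_rate_per_100k) < 0):
        raise ValueError("negative baseline mortality")
    diy = np.asarray(days_in_year)
    if not np.all((diy == 365) | (diy == 366)):
        raise ValueError("days_in_year must be 365 or 366")
    out = np.asarray(af) * annual_rate_per_100k / diy
    return out if out.ndim else float(out)


def classify_thermal(t: float | np.ndarray, mmt: float) -> np.ndarray | bool:
    """True for warm (t strictly above the MMT), False for cold; a day at
    exactly the MMT is labelled cold, where AF = 0 makes the label inert."""
    out = np.asarray(t) > mmt
    return out if out.ndim else bool(out)


@dataclass
class ExtremeDaySets:
    """The warmest/coldest days of the analysis window by the domain
    population-weighted daily mean temperature."""

    heat_days: pd.DatetimeIndex
    cold_days: pd.DatetimeIndex
    domain_series: pd.Series


def find_extreme_days(
    cube: DailyTemperatureCube,
    population: StaticLayer,
    mask: AnalysisMask,
    fraction: float = 0.02,
) -> ExtremeDaySets:
    """Select the warmest and coldest ``fraction`` of days (round half
    up), ranked by the domain population-weighted daily mean temperature
    over included cells; ties break toward the earlier date."""
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    n = cube.n_days
    k = int(np.floor(fraction * n + 0.5))
    if k < 1:
        raise ValueError(f"window of {n} days too short for fraction {fraction}")
    sel = mask.included
    w = population.values[sel]
    if w.sum() <= 0:
        raise ValueError("zero total population over included cells")
    flat = cube.values.reshape(n, -1)[:, sel.ravel()]
    series = pd.Series(flat @ w / w.sum(), index=cube.dates, name="domain_tmean_c")
    order_warm = np.lexsort((np.arange(n), -series.values))
    order_cold = np.lexsort((np.arange(n), series.values))
    heat = cube.dates[np.sort(order_warm[:k])]
    cold = cube.dates[np.sort(order_cold[:k])]
    return ExtremeDaySets(heat, cold, series)


def aggregate_ages(
    per_age: Mapping[str, float | np.ndarray], weights: AgeStructure
) -> float | np.ndarray:
    """Share-weighted sum of per-age per-100k quantities (the all-adult
    rate under the given age structure)."""
    missing = set(AGE_GROUPS) - set(per_age)
    if missing:
        raise ValueError(f"missing age groups {sorted(missing)}")
    out = sum(weights.shares[a] * np.asarray(per_age[a]) for a in AGE_GROUPS)
    out = np.asarray(out)
    return out if out.ndim else float(out)


@dataclass
class CellAttribution:
    """Per-age daily attributable numbers and warm/cold labels on the
    included cells of one city.

    ``an[age]`` and ``warm[age]`` have shape ``(n_days, n_included)``;
    ``cell_index`` maps columns back to flat grid positions.
    """

    dates: pd.DatetimeIndex
    mask: AnalysisMask
    cell_index: np.ndarray
    an: dict[str, np.ndarray]
    warm: dict[str, np.ndarray]
    days_in_year: np.ndarray

    @property
    def urban_cols(self) -> np.ndarray:
        return self.mask.urban.ravel()[self.cell_index]

    @property
    def rural_cols(self) -> np.ndarray:
        return self.mask.rural.ravel()[self.cell_index]


def attribute_cube(
    cube: DailyTemperatureCube,
    curves: Mapping[str, ERFCurve],
    baseline: BaselineMortality,
    mask: AnalysisMask,
    day_classification: Literal["cell", "domain"] = "cell",
    domain_series: pd.Series | None = None,
) -> CellAttribution:
    """Vectorized attribution over all included cells, days and ages.

    ``day_classification`` chooses whether the warm/cold label compares
    the cell's own temperature (default) or the domain-mean temperature
    against the age-specific MMT.
    """
    missing = set(AGE_GROUPS) - set(curves)
    if missing:
        raise ValueError(f"missing ERF curves for {sorted(missing)}")
    if day_classification not in ("cell", "domain"):
        raise ValueError(f"unknown day_classification {day_classification!r}")
    if day_classification == "domain" and domain_series is None:
        raise ValueError("domain-level classification needs the domain series")
    sel = mask.included.ravel()
    cell_index = np.flatnonzero(sel)
    t = cube.values.reshape(cube.n_days, -1)[:, cell_index]
    diy = cube.dates.is_leap_year.astype(int) + 365
    an: dict[str, np.ndarray] = {}
    warm: dict[str, np.ndarray] = {}
    for age in AGE_GROUPS:
        curve = curves[age]
        if curve.mmt is None:
            raise ValueError(f"curve for {age} not calibrated (no MMT)")
        af = attributable_fraction(curve.rr(t))
        an[age] = daily_attributable_number(af, baseline.rates[age], diy[:, None])
        if day_classification == "cell":
            warm[age] = classify_thermal(t, curve.mmt)
        else:
            dom = domain_series.reindex(cube.dates).values
            warm[age] = np.broadcast_to(
                classify_thermal(dom, curve.mmt)[:, None], t.shape
            ).copy()
    return CellAttribution(cube.dates, mask, cell_index, an, warm, diy)
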