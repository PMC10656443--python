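"""Urban-minus-rural impact differentials and their aggregation.

The UHI impact on mortality is computed per day as the difference
between the unweighted spatial average attributable number (AN, per
100,000 per day) over included urban cells and the same average over
included rural cells.  Averages are unweighted by population because the
risk is assessed from the perspective of an individual inhabitant;
population weighting enters only the exposure-bias diagnostic.

Daily differentials are then aggregated to an annual net (mean over
years of within-year sums), meteorological-season means (DJF/MAM/JJA/SON
pooled across years, December attached to the following winter), and
mean daily differentials over the heat- and cold-extreme day sets.  The
heat and cold components partition the annual net exactly, since every
cell-day is either warm or cold for a given age group.

Uncertainty in the exposure-response curves is propagated by recomputing
the city aggregates for every Monte-Carlo ERF draw; cohort summaries
(median impact, count of cities with adverse annual net) are summarized
by empirical quantiles across draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import (
    AgeStructure,
    BaselineMortality,
    CellAttribution,
    ExtremeDaySets,
    aggregate_ages,
    attributable_fraction,
)
from .erf import AGE_GROUPS, ERFEnsemble
from .grids import AnalysisMask, DailyTemperatureCube, StaticLayer

logger = logging.getLogger(__name__)

__all__ = [
    "ImpactSeries",
    "ImpactSummary",
    "MCSummary",
    "daily_differential",
    "aggregate_periods",
    "ensemble_impacts",
    "imperviousness_profile",
    "cohort_profiles",
    "builtup_differential",
    "age_standardize",
    "exposure_bias",
    "assign_climate_groups",
    "correlation_matrix",
    "mc_confidence",
    "city_metrics",
]

SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}

_COMPONENTS = ("total", "heat", "cold")


@dataclass
class ImpactSeries:
    """Daily urban/rural mean AN and their difference, per age group and
    aggregated over ages ('all'), split into total/heat/cold components.

    Each entry of ``frames`` is a DataFrame indexed by date with columns
    ``urban_<c>, rural_<c>, diff_<c>`` for c in total/heat/cold.
    """

    frames: dict[str, pd.DataFrame]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frames["all"].index

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.frames[key]


def daily_differential(attr: CellAttribution, age_structure: AgeStructure) -> ImpactSeries:
    """Per-day urban-minus-rural mean attributable number.

    Unweighted means within each stratum; heat/cold components use the
    age-specific warm/cold cell-day labels, so heat + cold = total
    exactly for every age group and date.
    """
    u = attr.urban_cols
    r = attr.rural_cols
    if not u.any():
        raise ValueError("no included urban cells")
    if not r.any():
        raise ValueError("no included rural cells")
    frames: dict[str, pd.DataFrame] = {}
    for age in AGE_GROUPS:
        an, warm = attr.an[age], attr.warm[age]
        cols = {}
        for comp, arr in (
            ("total", an),
            ("heat", an * warm),
            ("cold", an * ~warm),
        ):
            cols[f"urban_{comp}"] = arr[:, u].mean(axis=1)
            cols[f"rural_{comp}"] = arr[:, r].mean(axis=1)
            cols[f"diff_{comp}"] = cols[f"urban_{comp}"] - cols[f"rural_{comp}"]
        frames[age] = pd.DataFrame(cols, index=attr.dates)
    frames["all"] = sum(
        age_structure.shares[a] * frames[a] for a in AGE_GROUPS
    )
    return ImpactSeries(frames)


@dataclass
class ImpactSummary:
    """Temporal aggregates of the daily differential for one city.

    ``annual_net`` and components are per 100k per year (mean over
    calendar years of within-year sums); seasonal and extreme-day values
    are mean daily differentials (per 100k per day).
    """

    annual_net: float
    heat_component: float
    cold_component: float
    seasonal: dict[str, float]
    heat_extreme_mean: float
    cold_extreme_mean: float
    heat_extreme_pct: float
    cold_extreme_pct: float
    per_age: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {
            "annual_net": self.annual_net,
            "heat_component": self.heat_component,
            "cold_component": self.cold_component,
            "heat_extreme_mean": self.heat_extreme_mean,
            "cold_extreme_mean": self.cold_extreme_mean,
            "heat_extreme_pct": self.heat_extreme_pct,
            "cold_extreme_pct": self.cold_extreme_pct,
        }
        row.update({f"seasonal_{s}": v for s, v in self.seasonal.items()})
        return row


def _annual_sum(series: pd.Series) -> float:
    """Mean over calendar years of within-year sums."""
    return float(series.groupby(series.index.year).sum().mean())


def _extreme_stats(frame: pd.DataFrame, days: pd.DatetimeIndex) -> tuple[float, float]:
    sub = frame.loc[frame.index.isin(days)]
    diff = float(sub["diff_total"].mean())
    rural = float(sub["rural_total"].mean())
    if rural == 0.0:
        logger.warning("rural extreme-day mean AN is zero; percent change undefined")
        return diff, float("nan")
    return diff, 100.0 * diff / rural


def aggregate_periods(series: ImpactSeries, extremes: ExtremeDaySets) -> ImpactSummary:
    """Aggregate a daily impact series to the reporting periods."""
    frame = series["all"]
    seasons = {
        s: float(frame.loc[[SEASON_OF_MONTH[m] == s for m in frame.index.month], "diff_total"].mean())
        for s in ("DJF", "MAM", "JJA", "SON")
    }
    heat_mean, heat_pct = _extreme_stats(frame, extremes.heat_days)
    cold_mean, cold_pct = _extreme_stats(frame, extremes.cold_days)
    per_age = {}
    for age in AGE_GROUPS:
        f = series[age]
        per_age[age] = {
            "annual_net": _annual_sum(f["diff_total"]),
            "heat_component": _annual_sum(f["diff_heat"]),
            "cold_component": _annual_sum(f["diff_cold"]),
            "heat_extreme_mean": float(
                f.loc[f.index.isin(extremes.heat_days), "diff_total"].mean()
            ),
            "cold_extreme_mean": float(
                f.loc[f.index.isin(extremes.cold_days), "diff_total"].mean()
            ),
        }
    return ImpactSummary(
        annual_net=_annual_sum(frame["diff_total"]),
        heat_component=_annual_sum(frame["diff_heat"]),
        cold_component=_annual_sum(frame["diff_cold"]),
        seasonal=seasons,
        heat_extreme_mean=heat_mean,
        cold_extreme_mean=cold_mean,
        heat_extreme_pct=heat_pct,
        cold_extreme_pct=cold_pct,
        per_age=per_age,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo ensemble propagation


def ensemble_impacts(
    cube: DailyTemperatureCube,
    mask: AnalysisMask,
    ensembles: Mapping[str, ERFEnsemble],
    baseline: BaselineMortality,
    age_structure: AgeStructure,
    extremes: ExtremeDaySets,
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """City aggregates for every ERF draw, via a temperature histogram.

    Because AF depends on temperature alone, cell-days are tabulated once
    into ``bin_width``-°C bins per stratum/day-set and each draw's curve
    is evaluated exactly at the bin centres; the only approximation is
    the sub-bin temperature discretization (≤ bin_width/2).  Returns a
    DataFrame indexed by draw (0 = central) with columns annual_net,
    heat_component, cold_component, heat_extreme_mean, cold_extreme_mean
    (all-age, per 100k per year / per day).
    """
    n_days = cube.n_days
    diy = (cube.dates.is_leap_year.astype(int) + 365).astype(float)
    n_years = len(np.unique(cube.dates.year))
    flat = cube.values.reshape(n_days, -1)
    strata = {"u": mask.urban.ravel(), "r": mask.rural.ravel()}
    lo = np.floor(flat.min() / bin_width) * bin_width
    nbins = int(np.ceil((flat.max() - lo) / bin_width)) + 1
    centers = lo + (np.arange(nbins) + 0.5) * bin_width

    heat_sel = cube.dates.isin(extremes.heat_days)
    cold_sel = cube.dates.isin(extremes.cold_days)
    k = int(heat_sel.sum())

    hists: dict[tuple[str, str], np.ndarray] = {}
    for sname, smask in strata.items():
        if not smask.any():
            raise ValueError(f"empty {'urban' if sname == 'u' else 'rural'} stratum")
        t_s = flat[:, smask]
        n_cells = t_s.shape[1]
        idx = np.clip(((t_s - lo) / bin_width).astype(np.int64), 0, nbins - 1)
        w_ann = np.broadcast_to((1.0 / diy / n_years)[:, None], t_s.shape)
        hists[(sname, "ann")] = np.bincount(
            idx.ravel(), weights=w_ann.ravel(), minlength=nbins
        ) / n_cells
        for dname, dsel in (("heat", heat_sel), ("cold", cold_sel)):
            w = np.broadcast_to((dsel / diy)[:, None], t_s.shape)
            hists[(sname, dname)] = np.bincount(
                idx.ravel(), weights=w.ravel(), minlength=nbins
            ) / (n_cells * k)

    n_draws = min(e.n_draws for e in ensembles.values())
    out = np.zeros((n_draws, 5))
    for age in AGE_GROUPS:
        share = age_structure.shares[age]
        rate = baseline.rates[age]
        for j in range(n_draws):
            curve = ensembles[age].draws[j]
            af = attributable_fraction(curve.rr(centers))
            warm = centers > curve.mmt
            d_ann = hists[("u", "ann")] - hists[("r", "ann")]
            d_heat = hists[("u", "heat")] - hists[("r", "heat")]
            d_cold = hists[("u", "cold")] - hists[("r", "cold")]
            heat_comp = float(np.sum(af * warm * d_ann))
            cold_comp = float(np.sum(af * ~warm * d_ann))
            out[j, 0] += share * rate * (heat_comp + cold_comp)
            out[j, 1] += share * rate * heat_comp
            out[j, 2] += share * rate * cold_comp
            out[j, 3] += share * rate * float(np.sum(af * d_heat))
            out[j, 4] += share * rate * float(np.sum(af * d_cold))
    return pd.DataFrame(
        out,
        columns=[
            "annual_net",
            "heat_component",
            "cold_component",
            "heat_extreme_mean",
            "cold_extreme_mean",
        ],
        index=pd.RangeIndex(n_draws, name="draw"),
    )


@dataclass
class MCSummary:
    """Empirical confidence summary of a cohort statistic across ERF
    draws; ``central`` is the statistic of the central curves."""

    central: float
    lower: float
    upper: float
    level: float
    summary: str
    ensemble: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def mc_confidence(
    central_by_city: pd.Series,
    draws_by_city: pd.DataFrame,
    level: float = 0.95,
    summary: Literal["median", "adverse_count"] = "median",
) -> MCSummary:
    """Confidence interval of a cohort summary across ERF draws.

    ``draws_by_city`` is (n_draws × n_cities).  The summary is either the
    median impact across cities or the count of cities with adverse
    (positive) annual net differential; the interval is the empirical
    (1−level)/2 and 1−(1−level)/2 quantile of the per-draw summaries.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    if draws_by_city.shape[0] < 1:
        raise ValueError("need at least one draw")
    vals = draws_by_city.values
    if summary == "median":
        per_draw = np.median(vals, axis=1)
        central = float(np.median(central_by_city.values))
    elif summary == "adverse_count":
        per_draw = (vals > 0).sum(axis=1).astype(float)
        central = float((central_by_city.values > 0).sum())
    else:
        raise ValueError(f"unknown summary {summary!r}")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(per_draw, [alpha, 1.0 - alpha])
    return MCSummary(central, float(lower), float(upper), level, summary, per_draw)


# ---------------------------------------------------------------------------
# spatial structure diagnostics


def _per_cell_aggregates(
    attr: CellAttribution, age_structure: AgeStructure, extremes: ExtremeDaySets
) -> pd.DataFrame:
    """Per-included-cell annual net AN and extreme-day mean AN (all-age)."""
    an_all = sum(age_structure.shares[a] * attr.an[a] for a in AGE_GROUPS)
    years = attr.dates.year.values
    annual = np.zeros(an_all.shape[1])
    for y in np.unique(years):
        annual += an_all[years == y].sum(axis=0)
    annual /= len(np.unique(years))
    heat = an_all[attr.dates.isin(extremes.heat_days)].mean(axis=0)
    cold = an_all[attr.dates.isin(extremes.cold_days)].mean(axis=0)
    return pd.DataFrame(
        {"annual": annual, "heat_extreme": heat, "cold_extreme": cold},
        index=attr.cell_index,
    )


def imperviousness_profile(
    attr: CellAttribution,
    imperviousness: StaticLayer,
    age_structure: AgeStructure,
    extremes: ExtremeDaySets,
    bin_width: float = 5.0,
) -> pd.DataFrame:
    """Impact differential vs rural mean as a function of Δimperviousness.

    Δimperviousness is each included cell's imperviousness minus the mean
    over included rural cells; cells are binned at ``bin_width`` percent
    and per-bin mean differences from the rural-mean impact are returned.
    Empty bins are simply absent (missing, never zero).
    """
    cells = _per_cell_aggregates(attr, age_structure, extremes)
    imp = imperviousness.values.ravel()[attr.cell_index]
    rural = attr.rural_cols
    if not rural.any():
        raise ValueError("no included rural cells")
    rural_imp = imp[rural].mean()
    dimp = imp - rural_imp
    rural_ref = cells[rural].mean()
    binned = cells.copy()
    binned["dimp_bin"] = np.floor(dimp / bin_width) * bin_width
    grouped = binned.groupby("dimp_bin")
    prof = grouped[["annual", "heat_extreme", "cold_extreme"]].mean() - rural_ref
    prof.columns = ["annual_net", "heat_extreme", "cold_extreme"]
    prof["n_cells"] = grouped.size()
    prof.attrs["max_dimp"] = float(dimp.max())
    return prof.reset_index()


def cohort_profiles(
    per_city: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    min_max_dimp: float = 80.0,
    min_cities: int = 4,
) -> pd.DataFrame:
    """Climate-group median Δimperviousness profiles.

    Cities whose maximum urban-rural imperviousness difference is below
    ``min_max_dimp`` percent are excluded; group medians supported by
    fewer than ``min_cities`` cities at a bin are suppressed.
    """
    rows = []
    for city, prof in per_city.items():
        if prof.attrs.get("max_dimp", np.inf) < min_max_dimp:
            continue
        p = prof.copy()
        p["city"] = city
        p["group"] = groups[city]
        rows.append(p)
    if not rows:
        return pd.DataFrame(
            columns=["group", "dimp_bin", "annual_net", "heat_extreme", "cold_extreme", "n_cities"]
        )
    pooled = pd.concat(rows, ignore_index=True)
    med = pooled.groupby(["group", "dimp_bin"]).agg(
        annual_net=("annual_net", "median"),
        heat_extreme=("heat_extreme", "median"),
        cold_extreme=("cold_extreme", "median"),
        n_cities=("city", "nunique"),
    )
    med.loc[med["n_cities"] < min_cities, ["annual_net", "heat_extreme", "cold_extreme"]] = np.nan
    return med.reset_index()


def builtup_differential(
    attr: CellAttribution,
    imperviousness: StaticLayer,
    age_structure: AgeStructure,
    extremes: ExtremeDaySets,
    high: float = 90.0,
    low: float = 10.0,
) -> tuple[float, float]:
    """Mean AN difference between the most (≥``high``%) and least
    (≤``low``%) built-up included cells on heat-extreme days, absolute
    (per 100k per day) and percent of the least built-up stratum.
    Returns (nan, nan) with a diagnostic when a stratum is empty."""
    cells = _per_cell_aggregates(attr, age_structure, extremes)
    imp = imperviousness.values.ravel()[attr.cell_index]
    hi_sel, lo_sel = imp >= high, imp <= low
    if not hi_sel.any() or not lo_sel.any():
        logger.warning(
            "built-up differential undefined: %d cells >= %g%%, %d cells <= %g%%",
            hi_sel.sum(), high, lo_sel.sum(), low,
        )
        return float("nan"), float("nan")
    hi = float(cells["heat_extreme"].values[hi_sel].mean())
    lo_val = float(cells["heat_extreme"].values[lo_sel].mean())
    diff = hi - lo_val
    pct = 100.0 * diff / lo_val if lo_val != 0 else float("nan")
    return diff, pct


def age_standardize(per_age: Mapping[str, float], standard: AgeStructure) -> float:
    """Re-weight per-age per-100k results with a standard age structure
    (e.g. ESP2013) instead of the local one."""
    return aggregate_ages(per_age, standard)


def exposure_bias(
    attr: CellAttribution,
    population: StaticLayer,
    age_structure: AgeStructure,
    extremes: ExtremeDaySets,
    day_set: Literal["heat", "cold"] = "heat",
) -> float:
    """Percent change of the urban mean AN when weighting cells by
    population instead of equally, over the given extreme-day set.

    Positive values mean population is concentrated where the UHI impact
    is largest (exposure bias of the individual-perspective estimate).
    """
    u = attr.urban_cols
    if not u.any():
        raise ValueError("no included urban cells")
    w = population.values.ravel()[attr.cell_index][u]
    if w.sum() <= 0:
        raise ValueError("zero urban population")
    an_all = sum(age_structure.shares[a] * attr.an[a] for a in AGE_GROUPS)
    days = extremes.heat_days if day_set == "heat" else extremes.cold_days
    per_cell = an_all[attr.dates.isin(days)][:, u].mean(axis=0)
    unweighted = per_cell.mean()
    if unweighted == 0:
        logger.warning("unweighted urban mean AN is zero; exposure bias undefined")
        return float("nan")
    weighted = float(np.sum(w * per_cell) / w.sum())
    return 100.0 * (weighted - unweighted) / unweighted


# ---------------------------------------------------------------------------
# cohort-level analyses

_BASE_CLASS_NAMES = {
    "A": "Tropical", "B": "Arid", "C": "Temperate", "D": "Cold", "E": "Polar",
}


def assign_climate_groups(labels: Mapping[str, str]) -> dict[str, str]:
    """Map Köppen–Geiger codes to analysis climate groups.

    Codes shared by two or more cities form their own group.  A code held
    by a single city is merged into the same-base-letter group with the
    most agreement in the remaining letters (ties to the larger, then
    alphabetically first, group); the merged group is relabelled by its
    base classification.  A singleton with no same-base companion keeps
    its base-class label and is flagged in the log.
    """
    counts = pd.Series(list(labels.values())).value_counts()
    group_of: dict[str, str] = {code: code for code in counts.index}
    for code in sorted(counts.index[counts == 1]):
        base = code[0]
        candidates = [c for c in counts.index if c != code and c[0] == base]
        if not candidates:
            logger.warning("Köppen code %s has no same-base group; labelled %s",
                           code, _BASE_CLASS_NAMES.get(base, base))
            group_of[code] = _BASE_CLASS_NAMES.get(base, base)
            continue

        def _agreement(c: str) -> int:
            return sum(1 for a, b in zip(code[1:], c[1:]) if a == b)

        best = max(candidates, key=lambda c: (_agreement(c), counts[c], [-ord(x) for x in c]))
        label = _BASE_CLASS_NAMES.get(base, base)
        group_of[code] = label
        group_of[best] = label
    return {city: group_of[code] for city, code in labels.items()}


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n ≤ 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlation_matrix(
    metrics: pd.DataFrame,
    impacts: pd.DataFrame,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations between city metrics and impact
    aggregates, with two-sided p-values and an ``alpha`` significance
    mask.

    Exact permutation p-values are used for n ≤ 9 cities, the
    large-sample t approximation otherwise; constant columns are masked
    with a diagnostic.  Returns (rho, p, significant) DataFrames of shape
    (metrics × impact periods).
    """
    common = metrics.index.intersection(impacts.index)
    if len(common) < 5:
        raise ValueError(f"need >= 5 cities; have {len(common)}")
    m, im = metrics.loc[common], impacts.loc[common]
    rho = pd.DataFrame(index=m.columns, columns=im.columns, dtype=float)
    pval = pd.DataFrame(index=m.columns, columns=im.columns, dtype=float)
    for mc in m.columns:
        for ic in im.columns:
            x, y = m[mc].values.astype(float), im[ic].values.astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("constant column in (%s, %s); correlation masked", mc, ic)
                continue
            r, p_approx = stats.spearmanr(x, y)
            if len(x) <= 9:
                p = _spearman_exact_p(x, y, r)
            else:
                p = float(p_approx)
            rho.loc[mc, ic] = float(r)
            pval.loc[mc, ic] = p
    significant = pval < alpha
    return rho, pval, significant


def city_metrics(
    domain_series: pd.Series,
    cube: DailyTemperatureCube,
    mask: AnalysisMask,
    curves: Mapping[str, object],
    age_structure: AgeStructure,
    reference_age: str = "65-74",
) -> dict[str, float]:
    """City characteristics used in the cohort correlation analysis:
    RR at the observed temperature extremes, warm days per year (days
    above the reference age group's MMT), mean UHI magnitude (all-day
    urban-minus-rural mean temperature), 85+/20–44 population ratio and
    annual mean temperature."""
    curve = curves[reference_age]
    rr_tmin, rr_tmax = curve.extreme_rrs()
    n_years = len(np.unique(domain_series.index.year))
    warm_days = float((domain_series.values > curve.mmt).sum()) / n_years
    flat = cube.values.reshape(cube.n_days, -1)
    mean_uhi = float(
        flat[:, mask.urban.ravel()].mean() - flat[:, mask.rural.ravel()].mean()
    )
    return {
        "rr_tmax": float(rr_tmax),
        "rr_tmin": float(rr_tmin),
        "warm_days_per_year": warm_days,
        "mean_uhi": mean_uhi,
        "age_ratio": age_structure.shares["85+"] / age_structure.shares["20-44"],
        "t_avg": float(domain_series.mean()),
    }
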