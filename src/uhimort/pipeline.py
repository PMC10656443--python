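"""End-to-end orchestration of the analysis stages.

Stages run in order — simulate → attribute → impact → economics →
report — each reading its inputs from, and writing its outputs to, a run
directory, so the CLI can re-run any stage on an existing run.  A
machine-readable manifest records the config hash, seed and library
versions; a fixed config yields identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import (
    AgeStructure,
    BaselineMortality,
    ExtremeDaySets,
    attribute_cube,
    esp2013_age_structure,
    find_extreme_days,
)
from .config import RunConfig
from .economics import (
    CurrencyBasis,
    LifeTable,
    ValuationParams,
    convert_valuation,
    economic_impact,
)
from .erf import AGE_GROUPS, ERFCurve, ERFEnsemble, PercentileCurve, calibrate_to_temperature
from .grids import GridSpec, build_analysis_mask
from . import io as uio
from .synthetic import CityArchetype, CityRecipe, generate_multicity_cohort
from .uhi import (
    age_standardize,
    aggregate_periods,
    assign_climate_groups,
    builtup_differential,
    city_metrics,
    cohort_profiles,
    correlation_matrix,
    daily_differential,
    ensemble_impacts,
    exposure_bias,
    imperviousness_profile,
    mc_confidence,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "attribute", "impact", "economics", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and entity."""

    def __init__(self, stage: str, entity: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {entity}: {cause}")
        self.stage = stage
        self.entity = entity


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _city_ids(config: RunConfig) -> list[str]:
    return [f"city-{i:02d}" for i in range(config.cohort.n_cities)]


def _recipe_from_config(config: RunConfig) -> CityRecipe:
    c = config.cohort
    return CityRecipe(
        grid=GridSpec(c.grid_rows, c.grid_cols),
        seed=config.seed,
        start_date=c.start_date,
        end_date=c.end_date,
        uhi_amplitude=c.uhi_amplitude,
        uhi_seasonal_modulation=c.uhi_seasonal_modulation,
        weather_autocorrelation=c.weather_autocorrelation,
        weather_sd=c.weather_sd,
        water_fraction=c.water_fraction,
        hill_height=c.hill_height,
        total_adults=c.total_adults,
        population_impervious_spearman=c.population_impervious_spearman,
        n_draws=c.n_draws,
        coefficient_sd=c.coefficient_sd,
    )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, out: Path) -> None:
    """Generate the synthetic cohort and write all model inputs."""
    base = _recipe_from_config(config)
    archetypes = [
        CityArchetype(a.name, a.koppen, a.overrides()) for a in config.cohort.archetypes
    ]
    cities = generate_multicity_cohort(
        config.cohort.n_cities, archetypes, master_seed=config.seed, base_recipe=base
    )
    meta = []
    for city in cities:
        d = out / "inputs" / city.city_id
        d.mkdir(parents=True, exist_ok=True)
        uio.write_cube(city.cube, d / "cube.nc")
        for layer in (city.land_class, city.imperviousness, city.elevation, city.population):
            uio.write_layer(layer, d / f"{layer.kind}.nc")
        uio.write_reference_series(d / "reference_series.csv", city.reference_series, city.city_id)
        rows = []
        for age, ens in city.erfs.items():
            for j, curve in enumerate(ens.draws):
                pct = np.linspace(0, 100, len(curve.knot_temperatures))
                rows.append(
                    pd.DataFrame(
                        {
                            "city_id": city.city_id,
                            "age_group": age,
                            "percentile": pct,
                            "log_rr": curve.log_rr_at_knots,
                            "draw_index": j,
                        }
                    )
                )
        uio.write_erf_table(d / "erfs.csv", pd.concat(rows, ignore_index=True))
        pd.DataFrame(
            {
                "city_id": city.city_id,
                "age_group": AGE_GROUPS,
                "share": [city.age_structure.shares[a] for a in AGE_GROUPS],
                "annual_deaths_per_100k": [city.baseline.rates[a] for a in AGE_GROUPS],
            }
        ).to_csv(d / "demography.csv", index=False)
        truth = pd.DataFrame([{"city_id": city.city_id, "koppen": city.koppen,
                               "uhi_amplitude": city.recipe.uhi_amplitude,
                               "annual_mean_temp": city.recipe.annual_mean_temp,
                               "seed": city.recipe.seed}])
        truth.to_csv(d / "truth.csv", index=False)
        meta.append({"city_id": city.city_id, "koppen": city.koppen})
    pd.DataFrame(meta).to_csv(out / "inputs" / "cities.csv", index=False)


def _load_city(config: RunConfig, out: Path, city_id: str):
    d = out / "inputs" / city_id
    if not d.exists():
        raise FileNotFoundError(f"missing inputs for {city_id}: {d}")
    cube = uio.read_cube(d / "cube.nc")
    layers = {
        kind: uio.read_layer(d / f"{kind}.nc")
        for kind in ("land_class", "imperviousness_pct", "elevation_m", "population_count")
    }
    ref = uio.read_reference_series(d / "reference_series.csv", city_id)
    erf_path = d / "erfs.csv"
    if not erf_path.exists():
        raise FileNotFoundError(f"missing ERF file: {erf_path}")
    erf_df = uio.read_erf_table(erf_path)
    demo = pd.read_csv(d / "demography.csv").set_index("age_group")
    structure = AgeStructure({a: float(demo.loc[a, "share"]) for a in AGE_GROUPS})
    baseline = BaselineMortality(
        {a: float(demo.loc[a, "annual_deaths_per_100k"]) for a in AGE_GROUPS}
    )
    ensembles: dict[str, ERFEnsemble] = {}
    for age, grp in erf_df.groupby("age_group"):
        draws = []
        for j, sub in grp.groupby("draw_index"):
            pc = PercentileCurve(age, sub["percentile"].values, sub["log_rr"].values)
            draws.append(calibrate_to_temperature(pc, ref))
        ensembles[age] = ERFEnsemble(central=draws[0], draws=draws)
    return cube, layers, ref, ensembles, structure, baseline


def stage_attribute(config: RunConfig, out: Path) -> None:
    """Mask, calibrate, attribute and difference each city; write daily
    impact series, masks and extreme-day sets."""
    for city_id in _city_ids(config):
        try:
            cube, layers, ref, ensembles, structure, baseline = _load_city(config, out, city_id)
            mask = build_analysis_mask(
                layers["land_class"], layers["elevation_m"], layers["population_count"],
                threshold=config.analysis.elevation_threshold_m,
            )
            extremes = find_extreme_days(
                cube, layers["population_count"], mask, config.analysis.extreme_fraction
            )
            curves = {a: ensembles[a].central for a in AGE_GROUPS}
            attr = attribute_cube(
                cube, curves, baseline, mask,
                day_classification=config.analysis.day_classification,
                domain_series=extremes.domain_series,
            )
            series = daily_differential(attr, structure)
            d = out / "attribution" / city_id
            d.mkdir(parents=True, exist_ok=True)
            uio.write_mask(mask, d / "mask.nc")
            frame = series["all"].copy()
            for age in AGE_GROUPS:
                frame[f"diff_total_{age}"] = series[age]["diff_total"]
                frame[f"diff_heat_{age}"] = series[age]["diff_heat"]
                frame[f"diff_cold_{age}"] = series[age]["diff_cold"]
            frame.rename_axis("date").to_csv(d / "daily_series.csv")
            pd.DataFrame(
                {
                    "date": extremes.domain_series.index.strftime("%Y-%m-%d"),
                    "domain_tmean_c": extremes.domain_series.values,
                    "is_heat_day": extremes.domain_series.index.isin(extremes.heat_days),
                    "is_cold_day": extremes.domain_series.index.isin(extremes.cold_days),
                }
            ).to_csv(d / "extreme_days.csv", index=False)
        except Exception as exc:  # noqa: BLE001 — abort with stage + entity
            raise StageError("attribute", city_id, exc) from exc


def _read_series(out: Path, city_id: str):
    d = out / "attribution" / city_id
    frame = pd.read_csv(d / "daily_series.csv", index_col="date", parse_dates=True)
    ext = pd.read_csv(d / "extreme_days.csv", parse_dates=["date"])
    dates = pd.DatetimeIndex(ext["date"])
    extremes = ExtremeDaySets(
        heat_days=dates[ext["is_heat_day"].values],
        cold_days=dates[ext["is_cold_day"].values],
        domain_series=pd.Series(ext["domain_tmean_c"].values, index=dates),
    )
    return frame, extremes


def stage_impact(config: RunConfig, out: Path) -> None:
    """Aggregate daily series to period summaries, propagate the ERF
    ensemble, and compute the spatial diagnostics."""
    from .uhi import ImpactSeries

    esp = esp2013_age_structure()
    summary_rows, metrics_rows, draw_frames, profiles = {}, {}, {}, {}
    koppen = pd.read_csv(out / "inputs" / "cities.csv").set_index("city_id")["koppen"].to_dict()
    for city_id in _city_ids(config):
        try:
            cube, layers, ref, ensembles, structure, baseline = _load_city(config, out, city_id)
            mask = build_analysis_mask(
                layers["land_class"], layers["elevation_m"], layers["population_count"],
                threshold=config.analysis.elevation_threshold_m,
            )
            frame, extremes = _read_series(out, city_id)
            frames = {"all": frame[[c for c in frame.columns if not any(a in c for a in AGE_GROUPS)]]}
            for age in AGE_GROUPS:
                frames[age] = pd.DataFrame(
                    {
                        "diff_total": frame[f"diff_total_{age}"],
                        "diff_heat": frame[f"diff_heat_{age}"],
                        "diff_cold": frame[f"diff_cold_{age}"],
                        "urban_total": np.nan, "rural_total": np.nan,
                    },
                    index=frame.index,
                )
            series = ImpactSeries(frames)
            summary = aggregate_periods(series, extremes)
            curves = {a: ensembles[a].central for a in AGE_GROUPS}
            attr = attribute_cube(
                cube, curves, baseline, mask,
                day_classification=config.analysis.day_classification,
                domain_series=extremes.domain_series,
            )
            row = summary.as_row()
            row["annual_net_std_age"] = age_standardize(
                {a: summary.per_age[a]["annual_net"] for a in AGE_GROUPS}, esp
            )
            row["exposure_bias_heat_pct"] = exposure_bias(
                attr, layers["population_count"], structure, extremes, "heat"
            )
            row["exposure_bias_cold_pct"] = exposure_bias(
                attr, layers["population_count"], structure, extremes, "cold"
            )
            bu_diff, bu_pct = builtup_differential(
                attr, layers["imperviousness_pct"], structure, extremes
            )
            row["builtup_heat_diff"] = bu_diff
            row["builtup_heat_pct"] = bu_pct
            for age in AGE_GROUPS:
                for key, val in summary.per_age[age].items():
                    row[f"{key}_{age}"] = val
            summary_rows[city_id] = row
            metrics_rows[city_id] = city_metrics(
                extremes.domain_series, cube, mask, curves, structure
            )
            draw_frames[city_id] = ensemble_impacts(
                cube, mask, ensembles, baseline, structure, extremes,
                bin_width=config.analysis.mc_bin_width,
            )
            profiles[city_id] = imperviousness_profile(
                attr, layers["imperviousness_pct"], structure, extremes,
                bin_width=config.analysis.imperviousness_bin_width,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("impact", city_id, exc) from exc
    d = out / "impact"
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(summary_rows).T.rename_axis("city_id").to_csv(d / "impact_summary.csv")
    pd.DataFrame(metrics_rows).T.rename_axis("city_id").to_csv(d / "city_metrics.csv")
    for city_id, df in draw_frames.items():
        df.to_csv(d / f"draws_{city_id}.csv")
    groups = assign_climate_groups(koppen)
    cohort_profiles(profiles, groups).to_csv(d / "cohort_profiles.csv", index=False)
    for city_id, prof in profiles.items():
        prof.assign(max_dimp=prof.attrs["max_dimp"]).to_csv(
            d / f"profile_{city_id}.csv", index=False
        )


def stage_economics(config: RunConfig, out: Path) -> None:
    """Monetary valuation of every city's annual differentials."""
    eco = config.economics
    vsl = convert_valuation(
        eco.vsl_base, CurrencyBasis(eco.vsl_ppp, eco.vsl_cpi_base, eco.cpi_target)
    )
    voly = convert_valuation(
        eco.voly_base, CurrencyBasis(1.0, eco.voly_cpi_base, eco.cpi_target)
    )
    valuation = ValuationParams(vsl, voly, eco.voly_low, eco.voly_high)
    life = LifeTable(dict(eco.life_expectancy))
    summary = pd.read_csv(out / "impact" / "impact_summary.csv", index_col="city_id")
    rows = {}
    for city_id, row in summary.iterrows():
        impact = economic_impact(
            heat_per_100k=row["heat_component"],
            cold_per_100k=row["cold_component"],
            per_age_heat={a: row[f"heat_component_{a}"] for a in AGE_GROUPS},
            per_age_cold={a: row[f"cold_component_{a}"] for a in AGE_GROUPS},
            valuation=valuation,
            life_table=life,
        )
        rows[city_id] = impact.as_row()
    d = out / "economics"
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).T.rename_axis("city_id").to_csv(d / "economics.csv")
    pd.DataFrame(
        [{"vsl_2021_eur": vsl, "voly_2021_eur": voly,
          "voly_low": eco.voly_low, "voly_high": eco.voly_high}]
    ).to_csv(d / "valuation_params.csv", index=False)


def stage_report(config: RunConfig, out: Path) -> None:
    """Cohort medians, Monte-Carlo confidence intervals, correlations."""
    d = out / "report"
    d.mkdir(parents=True, exist_ok=True)
    summary = pd.read_csv(out / "impact" / "impact_summary.csv", index_col="city_id")
    draws = {
        c: pd.read_csv(out / "impact" / f"draws_{c}.csv", index_col="draw")
        for c in _city_ids(config)
    }
    cohort = summary[
        ["annual_net", "heat_component", "cold_component",
         "heat_extreme_mean", "cold_extreme_mean", "heat_extreme_pct", "cold_extreme_pct"]
    ].agg(["median", lambda s: s.quantile(0.25), lambda s: s.quantile(0.75)])
    cohort.index = ["median", "q25", "q75"]
    cohort.to_csv(d / "cohort_summary.csv")

    mc_rows = []
    for col, summary_kind, level in (
        ("annual_net", "median", config.analysis.confidence_level_median),
        ("heat_extreme_mean", "median", config.analysis.confidence_level_median),
        ("cold_extreme_mean", "median", config.analysis.confidence_level_median),
        ("annual_net", "adverse_count", config.analysis.confidence_level_adverse),
    ):
        central = summary[col]
        per_draw = pd.DataFrame({c: draws[c][col] for c in draws})
        mc = mc_confidence(central, per_draw, level=level, summary=summary_kind)
        mc_rows.append(
            {"quantity": col, "summary": summary_kind, "level": level,
             "central": mc.central, "lower": mc.lower, "upper": mc.upper}
        )
    pd.DataFrame(mc_rows).to_csv(d / "mc_confidence.csv", index=False)

    metrics = pd.read_csv(out / "impact" / "city_metrics.csv", index_col="city_id")
    impacts = summary[
        ["annual_net", "heat_extreme_mean", "cold_extreme_mean",
         "seasonal_DJF", "seasonal_JJA"]
    ]
    if len(summary) >= 5:
        rho, pval, sig = correlation_matrix(metrics, impacts, config.analysis.correlation_alpha)
        rho.rename_axis("metric").to_csv(d / "correlations_rho.csv")
        pval.rename_axis("metric").to_csv(d / "correlations_p.csv")
        sig.rename_axis("metric").to_csv(d / "correlations_significant.csv")
    else:
        logger.info("fewer than 5 cities; correlation analysis skipped")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "attribute": stage_attribute,
    "impact": stage_impact,
    "economics": stage_economics,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in order and write the run manifest.

    Returns the run directory.  Any stage failure aborts with the stage
    name and the offending entity.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s ...", stage)
        _STAGE_FUNCS[stage](config, out)
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", stage, timings[stage])
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": list(stages),
        "timings_s": timings,
        "versions": {
            "uhimort": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config.model_dump(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
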