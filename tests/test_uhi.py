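import numpy as np
import pandas as pd
import pytest

from uhimort.attribution import (
    AgeStructure,
    BaselineMortality,
    ExtremeDaySets,
    attribute_cube,
    find_extreme_days,
)
from uhimort.erf import AGE_GROUPS
from uhimort.grids import AnalysisMask, CellStatus, DailyTemperatureCube, GridSpec, StaticLayer
from uhimort.synthetic import CityRecipe, generate_city
from uhimort.uhi import (
    age_standardize,
    aggregate_periods,
    assign_climate_groups,
    builtup_differential,
    correlation_matrix,
    daily_differential,
    ensemble_impacts,
    exposure_bias,
    imperviousness_profile,
    cohort_profiles,
    mc_confidence,
)

from conftest import flat_baseline, linear_curve, single_age_structure
from _oracles import spearman_rank_formula


def _two_cell_city(t_urban, t_rural, n_days=366, start="2016-01-01"):
    """1×2 grid: column 0 urban, column 1 rural, constant temperatures."""
    spec = GridSpec(1, 2)
    dates = pd.date_range(start, periods=n_days, freq="D")
    vals = np.tile(np.array([[t_urban, t_rural]]), (n_days, 1)).reshape(n_days, 1, 2)
    cube = DailyTemperatureCube(spec, dates, vals)
    mask = AnalysisMask(spec, np.array([[1, 0]]))
    return cube, mask


def _curves(mmt=18.0, rr_cold=1.5, rr_warm=1.5, lo=-20.0, hi=40.0):
    return {a: linear_curve(a, mmt, rr_cold, rr_warm, lo, hi) for a in AGE_GROUPS}


class TestDailyDifferential:
    def test_null_city_differential_zero(self):
        recipe = CityRecipe(grid=GridSpec(12, 12), uhi_amplitude=0.0, n_draws=1, seed=30)
        city = generate_city(recipe)
        from uhimort.grids import build_analysis_mask

        mask = build_analysis_mask(city.land_class, city.elevation, city.population)
        curves = {a: city.erfs[a].central for a in AGE_GROUPS}
        attr = attribute_cube(city.cube, curves, city.baseline, mask)
        series = daily_differential(attr, city.age_structure)
        assert np.abs(series["all"]["diff_total"].values).max() < 1e-12

    def test_hand_computed_two_cell_differential(self):
        # urban at MMT+2 with RR 1.5 there, rural at MMT (RR 1), baseline
        # 365/100k/yr in a 365-day year: diff = AF(1.5) × 1 = 1/3 per 100k/day
        curves = {
            a: linear_curve(a, 18.0, 1.5, 1.5, -20.0, 20.0) for a in AGE_GROUPS
        }
        cube, mask = _two_cell_city(20.0, 18.0, n_days=365, start="2015-01-01")
        attr = attribute_cube(cube, curves, flat_baseline(365.0), mask)
        series = daily_differential(attr, single_age_structure())
        expected = (1.5 - 1.0) / 1.5  # AF at RR 1.5, i.e. 1/3
        assert series["all"]["diff_total"].values == pytest.approx(expected, rel=1e-9)
        assert series["all"]["diff_heat"].values == pytest.approx(expected, rel=1e-9)
        assert series["all"]["diff_cold"].values == pytest.approx(0.0, abs=1e-12)

    def test_heat_plus_cold_equals_total_exactly(self, small_attr, small_city):
        series = daily_differential(small_attr, small_city.age_structure)
        for key in list(AGE_GROUPS) + ["all"]:
            f = series[key]
            np.testing.assert_allclose(
                f["diff_heat"] + f["diff_cold"], f["diff_total"], atol=1e-15
            )

    def test_antisymmetry_under_label_swap(self, small_city, small_mask):
        curves = {a: small_city.erfs[a].central for a in AGE_GROUPS}
        swapped = small_mask.status.copy()
        swapped[small_mask.urban] = CellStatus.RURAL_INCLUDED
        swapped[small_mask.rural] = CellStatus.URBAN_INCLUDED
        mask_sw = AnalysisMask(small_mask.spec, swapped)
        a1 = attribute_cube(small_city.cube, curves, small_city.baseline, small_mask)
        a2 = attribute_cube(small_city.cube, curves, small_city.baseline, mask_sw)
        s1 = daily_differential(a1, small_city.age_structure)
        s2 = daily_differential(a2, small_city.age_structure)
        np.testing.assert_array_equal(
            s1["all"]["diff_total"].values, -s2["all"]["diff_total"].values
        )

    def test_scale_equivariance_in_baseline(self, small_city, small_mask):
        curves = {a: small_city.erfs[a].central for a in AGE_GROUPS}
        c = 3.0
        scaled = BaselineMortality({a: c * small_city.baseline.rates[a] for a in AGE_GROUPS})
        s1 = daily_differential(
            attribute_cube(small_city.cube, curves, small_city.baseline, small_mask),
            small_city.age_structure,
        )
        s2 = daily_differential(
            attribute_cube(small_city.cube, curves, scaled, small_mask),
            small_city.age_structure,
        )
        np.testing.assert_allclose(
            s2["all"]["diff_total"], c * s1["all"]["diff_total"], rtol=1e-12
        )

    def test_empty_stratum_raises(self):
        cube, _ = _two_cell_city(20.0, 18.0, n_days=120)
        mask = AnalysisMask(GridSpec(1, 2), np.array([[1, 1]]))  # no rural
        attr = attribute_cube(cube, _curves(), flat_baseline(), mask)
        with pytest.raises(ValueError, match="rural"):
            daily_differential(attr, single_age_structure())


class TestAggregatePeriods:
    def _series_from(self, cube, mask, extremes, curves=None, baseline=None,
                     structure=None):
        attr = attribute_cube(cube, curves or _curves(), baseline or flat_baseline(), mask)
        return daily_differential(attr, structure or single_age_structure())

    def test_constant_differential_annual_sum(self):
        cube, mask = _two_cell_city(20.0, 18.0, n_days=365, start="2015-01-01")
        curves = {a: linear_curve(a, 18.0, 1.5, 1.5, -22.0, 22.0) for a in AGE_GROUPS}
        ext = find_extreme_days(
            cube, StaticLayer(GridSpec(1, 2), "population_count", np.ones((1, 2))), mask
        )
        series = self._series_from(cube, mask, ext, curves=curves)
        summary = aggregate_periods(series, ext)
        d = series["all"]["diff_total"].iloc[0]
        assert summary.annual_net == pytest.approx(365 * d, rel=1e-12)
        assert summary.heat_component + summary.cold_component == pytest.approx(
            summary.annual_net, abs=1e-9
        )

    def test_extreme_day_only_signal_direct_summation(self, small_city, small_mask,
                                                      small_extremes, small_attr):
        # annual net equals the direct sum of the daily series, including
        # when the signal is concentrated on extreme days
        series = daily_differential(small_attr, small_city.age_structure)
        summary = aggregate_periods(series, small_extremes)
        diff = series["all"]["diff_total"]
        expect = diff.groupby(diff.index.year).sum().mean()
        assert summary.annual_net == pytest.approx(expect, rel=1e-12)
        heat_days = small_extremes.heat_days
        assert summary.heat_extreme_mean == pytest.approx(
            diff[diff.index.isin(heat_days)].mean(), rel=1e-12
        )

    def test_seasons_partition_the_year(self, small_city, small_attr, small_extremes):
        series = daily_differential(small_attr, small_city.age_structure)
        summary = aggregate_periods(series, small_extremes)
        diff = series["all"]["diff_total"]
        n_years = len(np.unique(diff.index.year))
        season_of = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
                     6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}
        total = sum(
            summary.seasonal[s] * sum(1 for m in diff.index.month if season_of[m] == s)
            for s in ("DJF", "MAM", "JJA", "SON")
        )
        assert total / n_years == pytest.approx(summary.annual_net, rel=1e-9)

    def test_percent_consistent_with_absolute(self, small_city, small_attr, small_extremes):
        series = daily_differential(small_attr, small_city.age_structure)
        summary = aggregate_periods(series, small_extremes)
        f = series["all"]
        sub = f[f.index.isin(small_extremes.heat_days)]
        expect = 100.0 * sub["diff_total"].mean() / sub["rural_total"].mean()
        assert summary.heat_extreme_pct == pytest.approx(expect, abs=1e-9)

    def test_zero_rural_mean_flags_percent_missing(self):
        # rural cell pinned at the MMT: zero rural AN on every day
        cube, mask = _two_cell_city(20.0, 18.0, n_days=365, start="2015-01-01")
        curves = {a: linear_curve(a, 18.0, 1.5, 1.5, -22.0, 22.0) for a in AGE_GROUPS}
        ext = find_extreme_days(
            cube, StaticLayer(GridSpec(1, 2), "population_count", np.ones((1, 2))), mask
        )
        series = self._series_from(cube, mask, ext, curves=curves)
        summary = aggregate_periods(series, ext)
        assert np.isnan(summary.heat_extreme_pct)
        assert np.isfinite(summary.heat_extreme_mean)


class TestVectorizedAgainstBruteForce:
    def test_attribution_matches_loop(self):
        from _oracles import brute_force_attribution

        recipe = CityRecipe(
            grid=GridSpec(20, 20), seed=31, n_draws=1,
            start_date="2015-01-01", end_date="2015-12-31",
        )
        city = generate_city(recipe)
        # 30-day sub-cube keeps the scalar Python loop affordable
        sub = DailyTemperatureCube(
            city.cube.spec, city.cube.dates[151:181], city.cube.values[151:181]
        )
        from uhimort.grids import build_analysis_mask

        mask = build_analysis_mask(city.land_class, city.elevation, city.population)
        curves = {a: city.erfs[a].central for a in AGE_GROUPS}
        attr = attribute_cube(sub, curves, city.baseline, mask)
        for age in ("20-44", "85+"):
            oracle = brute_force_attribution(
                sub.values, sub.dates, curves[age], city.baseline.rates[age]
            )
            flat = oracle.reshape(sub.n_days, -1)[:, attr.cell_index]
            np.testing.assert_allclose(attr.an[age], flat, atol=1e-12)


class TestEnsembleImpacts:
    def test_histogram_path_matches_exact_central(self, small_city, small_mask,
                                                  small_extremes, small_attr):
        series = daily_differential(small_attr, small_city.age_structure)
        summary = aggregate_periods(series, small_extremes)
        ei = ensemble_impacts(
            small_city.cube, small_mask, small_city.erfs, small_city.baseline,
            small_city.age_structure, small_extremes,
        )
        assert ei.loc[0, "annual_net"] == pytest.approx(summary.annual_net, rel=2e-3, abs=1e-3)
        assert ei.loc[0, "heat_component"] == pytest.approx(summary.heat_component, rel=2e-3)
        assert ei.loc[0, "heat_extreme_mean"] == pytest.approx(
            summary.heat_extreme_mean, rel=2e-3
        )
        assert ei.loc[0, "cold_extreme_mean"] == pytest.approx(
            summary.cold_extreme_mean, rel=2e-3
        )

    def test_draws_spread_around_central(self, small_city, small_mask, small_extremes):
        ei = ensemble_impacts(
            small_city.cube, small_mask, small_city.erfs, small_city.baseline,
            small_city.age_structure, small_extremes,
        )
        assert ei.shape[0] == small_city.erfs["65-74"].n_draws
        assert ei["annual_net"].std() > 0


class TestSpatialDiagnostics:
    def test_uniform_imperviousness_single_bin(self):
        cube, mask = _two_cell_city(20.0, 20.0, n_days=120)
        attr = attribute_cube(cube, _curves(), flat_baseline(), mask)
        ext = find_extreme_days(
            cube, StaticLayer(GridSpec(1, 2), "population_count", np.ones((1, 2))), mask
        )
        imp = StaticLayer(GridSpec(1, 2), "imperviousness_pct", np.full((1, 2), 40.0))
        prof = imperviousness_profile(attr, imp, single_age_structure(), ext)
        assert len(prof) == 1
        assert prof["dimp_bin"].iloc[0] == 0.0
        assert prof["annual_net"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_stratified_means(self, small_city, small_mask, small_extremes, small_attr):
        prof = imperviousness_profile(
            small_attr, small_city.imperviousness, small_city.age_structure, small_extremes
        )
        # oracle: recompute one bin by hand
        from uhimort.uhi import _per_cell_aggregates

        cells = _per_cell_aggregates(small_attr, small_city.age_structure, small_extremes)
        imp = small_city.imperviousness.values.ravel()[small_attr.cell_index]
        rural_imp = imp[small_attr.rural_cols].mean()
        rural_ref = cells[small_attr.rural_cols]["annual"].mean()
        bin_low = prof["dimp_bin"].iloc[-1]
        sel = np.floor((imp - rural_imp) / 5.0) * 5.0 == bin_low
        expect = cells["annual"].values[sel].mean() - rural_ref
        assert prof["annual_net"].iloc[-1] == pytest.approx(expect, rel=1e-9)

    def test_cohort_filter_and_small_group_suppression(self):
        def prof(max_dimp):
            df = pd.DataFrame(
                {"dimp_bin": [0.0, 50.0], "annual_net": [0.0, 1.0],
                 "heat_extreme": [0.0, 0.1], "cold_extreme": [0.0, -0.1]}
            )
            df.attrs["max_dimp"] = max_dimp
            return df

        per_city = {f"c{i}": prof(95.0) for i in range(3)}
        per_city["c3"], per_city["c4"] = prof(40.0), prof(60.0)
        groups = {c: "Temperate" for c in per_city}
        out = cohort_profiles(per_city, groups, min_cities=4)
        # two cities filtered out by the max-Δimperviousness rule -> 3 left,
        # below the 4-city support threshold -> medians suppressed
        assert set(out["n_cities"]) == {3}
        assert out["annual_net"].isna().all()
        out2 = cohort_profiles(per_city, groups, min_cities=3)
        assert out2["annual_net"].notna().all()

    def test_builtup_differential_two_cell_hand_value(self):
        curves = {a: linear_curve(a, 18.0, 1.5, 1.5, -20.0, 20.0) for a in AGE_GROUPS}
        cube, mask = _two_cell_city(20.0, 18.0, n_days=120, start="2015-01-01")
        attr = attribute_cube(cube, curves, flat_baseline(365.0), mask)
        ext = find_extreme_days(
            cube, StaticLayer(GridSpec(1, 2), "population_count", np.ones((1, 2))), mask
        )
        imp = StaticLayer(GridSpec(1, 2), "imperviousness_pct", np.array([[95.0, 5.0]]))
        diff, pct = builtup_differential(attr, imp, single_age_structure(), ext)
        # urban cell at RR 1.5 -> AF 1/3 -> AN = 365/3/365 per day; rural 0
        assert diff == pytest.approx(1.0 / 3.0, rel=1e-9)
        assert np.isnan(pct)  # least built-up AN is exactly zero

    def test_builtup_missing_stratum(self, small_city, small_mask, small_extremes, small_attr):
        imp = StaticLayer(small_mask.spec, "imperviousness_pct",
                          np.full(small_mask.spec.shape, 50.0))
        diff, pct = builtup_differential(
            small_attr, imp, small_city.age_structure, small_extremes
        )
        assert np.isnan(diff) and np.isnan(pct)

    def test_exposure_bias_uniform_population_zero(self, small_city, small_mask,
                                                   small_extremes, small_attr):
        pop = StaticLayer(small_mask.spec, "population_count",
                          np.ones(small_mask.spec.shape))
        bias = exposure_bias(small_attr, pop, small_city.age_structure, small_extremes)
        assert bias == pytest.approx(0.0, abs=1e-9)

    def test_exposure_bias_point_mass_limit(self, small_city, small_mask,
                                            small_extremes, small_attr):
        an_all = sum(
            small_city.age_structure.shares[a] * small_attr.an[a] for a in AGE_GROUPS
        )
        u = small_attr.urban_cols
        per_cell = an_all[small_attr.dates.isin(small_extremes.heat_days)][:, u].mean(axis=0)
        target = int(np.argmax(per_cell))
        pop = np.zeros(small_mask.spec.n_cells)
        pop[small_attr.cell_index[np.flatnonzero(u)[target]]] = 1000.0
        layer = StaticLayer(small_mask.spec, "population_count",
                            pop.reshape(small_mask.spec.shape))
        bias = exposure_bias(small_attr, layer, small_city.age_structure, small_extremes)
        expect = 100.0 * (per_cell.max() - per_cell.mean()) / per_cell.mean()
        assert bias == pytest.approx(expect, rel=1e-9)

    def test_exposure_bias_positive_for_correlated_city(self, small_city, small_mask,
                                                        small_extremes, small_attr):
        bias = exposure_bias(
            small_attr, small_city.population, small_city.age_structure, small_extremes
        )
        assert bias > 0


class TestAgeStandardize:
    def test_identity_when_standard_equals_local(self, small_city):
        per_age = {a: float(i + 1) for i, a in enumerate(AGE_GROUPS)}
        local = small_city.age_structure
        from uhimort.attribution import aggregate_ages

        assert age_standardize(per_age, local) == pytest.approx(
            aggregate_ages(per_age, local), abs=0
        )

    def test_equal_values_invariant_under_any_weights(self):
        per_age = {a: 2.5 for a in AGE_GROUPS}
        from uhimort.attribution import esp2013_age_structure

        assert age_standardize(per_age, esp2013_age_structure()) == pytest.approx(2.5)

    def test_two_group_reweighting(self):
        shares = {a: 0.0 for a in AGE_GROUPS}
        shares["65-74"], shares["85+"] = 0.6, 0.4
        per_age = {a: 0.0 for a in AGE_GROUPS}
        per_age["65-74"], per_age["85+"] = 1.0, 2.0
        assert age_standardize(per_age, AgeStructure(shares)) == pytest.approx(1.4)


class TestClimateGroups:
    def test_singleton_merges_into_same_base_group(self):
        labels = {"murcia": "BWh"}
        labels.update({f"c{i}": "BSk" for i in range(6)})
        groups = assign_climate_groups(labels)
        assert set(groups.values()) == {"Arid"}
        assert len(groups) == 7

    def test_no_singletons_unchanged(self):
        labels = {"a": "Cfb", "b": "Cfb", "c": "Dfb", "d": "Dfb"}
        assert assign_climate_groups(labels) == labels

    def test_singleton_joins_c_base_group(self):
        labels = {"a": "Cfb", "b": "Cfb", "c": "Cfb", "d": "Csa"}
        groups = assign_climate_groups(labels)
        assert groups["d"] == "Temperate"
        assert groups["a"] == "Temperate"

    def test_isolated_singleton_keeps_base_class(self):
        labels = {"a": "Cfb", "b": "Cfb", "c": "ET"}
        groups = assign_climate_groups(labels)
        assert groups["c"] == "Polar"
        assert groups["a"] == "Cfb"


class TestCorrelationMatrix:
    def test_identical_columns_perfect_rho(self):
        rng = np.random.default_rng(40)
        x = rng.normal(size=8)
        metrics = pd.DataFrame({"m": x}, index=[f"c{i}" for i in range(8)])
        impacts = pd.DataFrame({"p": x, "q": -x}, index=metrics.index)
        rho, pval, sig = correlation_matrix(metrics, impacts)
        assert rho.loc["m", "p"] == pytest.approx(1.0)
        assert rho.loc["m", "q"] == pytest.approx(-1.0)
        assert sig.loc["m", "p"] and sig.loc["m", "q"]
        assert pval.loc["m", "p"] < 0.01

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(41)
        x, y = rng.normal(size=6), rng.normal(size=6)
        metrics = pd.DataFrame({"m": x}, index=[f"c{i}" for i in range(6)])
        impacts = pd.DataFrame({"p": y}, index=metrics.index)
        rho, _, _ = correlation_matrix(metrics, impacts)
        assert rho.loc["m", "p"] == pytest.approx(spearman_rank_formula(x, y), abs=1e-12)

    def test_constant_column_masked(self):
        metrics = pd.DataFrame({"m": np.ones(6)}, index=[f"c{i}" for i in range(6)])
        impacts = pd.DataFrame({"p": np.arange(6.0)}, index=metrics.index)
        rho, pval, sig = correlation_matrix(metrics, impacts)
        assert np.isnan(rho.loc["m", "p"])
        assert not sig.loc["m", "p"]

    def test_too_few_cities_rejected(self):
        df = pd.DataFrame({"m": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="5"):
            correlation_matrix(df, df)

    def test_exact_permutation_p_small_n(self):
        # n=6, perfect monotone relation: exact two-sided p = 2/6!
        x = np.arange(6.0)
        metrics = pd.DataFrame({"m": x}, index=[f"c{i}" for i in range(6)])
        impacts = pd.DataFrame({"p": x**3}, index=metrics.index)
        _, pval, _ = correlation_matrix(metrics, impacts)
        assert pval.loc["m", "p"] == pytest.approx(2 / 720, abs=1e-12)


class TestMCConfidence:
    def test_degenerate_ensemble_zero_width(self):
        central = pd.Series([1.0, -2.0, 0.5], index=["a", "b", "c"])
        draws = pd.DataFrame(np.tile([[1.0, -2.0, 0.5]], (50, 1)), columns=central.index)
        mc = mc_confidence(central, draws, level=0.9, summary="median")
        assert mc.lower == mc.upper == mc.central == 0.5

    def test_adverse_count_constant(self):
        central = pd.Series(np.r_[np.ones(3), -np.ones(7)])
        draws = pd.DataFrame(np.tile(central.values, (100, 1)))
        mc = mc_confidence(central, draws, level=0.9, summary="adverse_count")
        assert (mc.lower, mc.central, mc.upper) == (3.0, 3.0, 3.0)

    def test_bad_level_rejected(self):
        central = pd.Series([1.0, 2.0])
        draws = pd.DataFrame(np.ones((10, 2)))
        with pytest.raises(ValueError, match="level"):
            mc_confidence(central, draws, level=1.5)
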