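import numpy as np
import pandas as pd
import pytest

from uhimort import (
    AGE_GROUPS,
    AgeStructure,
    BaselineMortality,
    CityRecipe,
    ERFCurve,
    GridSpec,
    attribute_cube,
    build_analysis_mask,
    find_extreme_days,
    generate_city,
)


@pytest.fixture(scope="session")
def small_city():
    """A 20×20 three-year city with water and a hill, small ERF ensemble."""
    recipe = CityRecipe(grid=GridSpec(20, 20), seed=11, n_draws=8, hill_height=150.0)
    return generate_city(recipe)


@pytest.fixture(scope="session")
def small_mask(small_city):
    return build_analysis_mask(
        small_city.land_class, small_city.elevation, small_city.population
    )


@pytest.fixture(scope="session")
def small_extremes(small_city, small_mask):
    return find_extreme_days(small_city.cube, small_city.population, small_mask)


@pytest.fixture(scope="session")
def small_attr(small_city, small_mask):
    curves = {a: small_city.erfs[a].central for a in AGE_GROUPS}
    return attribute_cube(small_city.cube, curves, small_city.baseline, small_mask)


def linear_curve(
    age: str,
    mmt: float,
    rr_cold: float,
    rr_warm: float,
    t_lo: float,
    t_hi: float,
) -> ERFCurve:
    """V-shaped piecewise-linear log-RR curve with the MMT as a knot,
    aligned so the 0.1 °C MMT grid hits it exactly when (t_hi − t_lo)
    and (mmt − t_lo) are multiples of 0.1."""
    return ERFCurve(
        age_group=age,
        knot_temperatures=np.array([t_lo, mmt, t_hi]),
        log_rr_at_knots=np.array([np.log(rr_cold), 0.0, np.log(rr_warm)]),
        observed_range=(t_lo, t_hi),
        interpolation="linear",
    ).recentre()


def single_age_structure(age: str = "65-74") -> AgeStructure:
    return AgeStructure({a: (1.0 if a == age else 0.0) for a in AGE_GROUPS})


def flat_baseline(rate: float = 365.0) -> BaselineMortality:
    return BaselineMortality({a: rate for a in AGE_GROUPS})
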