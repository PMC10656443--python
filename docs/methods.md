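# Methods

## Overview

`uhimort` quantifies how the urban heat island (UHI) — the surplus of
near-surface air temperature in built-up areas over their rural
surroundings — changes temperature-related mortality risk, and what that
change is worth in monetary terms. The unit of analysis is a city
domain: a planar, equal-area raster of square cells (nominally 500 m)
carrying daily mean temperature, land class, imperviousness, elevation
and population, plus tabular demography and age-specific
exposure-response functions (ERFs).

The causal chain implemented is:

1. Every cell-day temperature is mapped to a relative mortality risk
   RR(t) per adult age group (20–44, 45–64, 65–74, 75–84, 85+) through a
   lag-cumulative ERF.
2. The attributable fraction AF = (RR − 1)/RR converts risk to the share
   of deaths attributable to non-optimal temperature, and the daily
   attributable number per 100,000 is AN = AF × (annual all-cause
   mortality rate)/(calendar-year length).
3. The UHI impact is the day-by-day difference between the unweighted
   spatial mean AN over included urban cells and the same mean over
   included rural cells, aggregated to annual nets, meteorological
   seasons and heat/cold extreme days, and split into heat and cold
   components by the age-specific minimum mortality temperature (MMT).
4. Uncertainty in the ERF coefficients is propagated by recomputing the
   city aggregates for each of the Monte-Carlo ERF draws and summarizing
   cohort statistics by empirical quantiles across draws.
5. Annual differentials are valued in euros per adult inhabitant per
   year under a value-of-statistical-life (VSL) accounting and,
   alternatively, through years of life lost (YLL) priced per life year
   (VOLY).

## Masking and spatial averages

Cells containing any water are excluded outright; this propagates
through dominant-class regridding (a coarse cell is water if any
constituent fine cell is, otherwise it takes the urban/rural majority,
ties going to rural). Land cells whose elevation differs by more than
100 m from the domain's population-weighted mean elevation (computed
over all land cells, before any exclusion) are also excluded — mountain
slopes inside a city domain are neither urban canopy nor representative
rural reference.

Urban and rural spatial means are *unweighted* by population: the
estimate answers "what does an individual inhabitant of the urban
(rural) zone experience on average", not "what does the average
person experience". Population weighting appears only in the
exposure-bias diagnostic, which reports by how many percent the urban
mean AN shifts when cells are weighted by where people actually live.

## Exposure-response functions

ERF coefficients arrive as log-RR on a grid of relative temperature
percentiles, together with a 1000-draw uncertainty ensemble. They are
translated to absolute temperature against the city's domain-average
daily temperature series: knot temperatures are empirical quantiles at
the curve's percentiles (linear interpolation between order statistics —
fixed as the single supported quantile rule so calibration is
bit-reproducible). Between knots, log-RR is interpolated with a
monotone-shape-preserving cubic (PCHIP), which cannot introduce spurious
risk dips between knots; a piecewise-linear mode exists for curves that
are linear by construction. Outside the observed range, RR is clamped to
its boundary value — risk is never extrapolated past the temperatures
actually observed.

The MMT is located by grid search over the observed range at 0.1 °C
resolution, ties broken toward the warmer candidate (conservative: it
classifies fewer days as warm). Curves are recentred so RR = 1 exactly
at the located MMT. Because the search grid is discrete, the continuous
interpolant can dip below 1 between grid points by up to roughly
(curvature) × (0.05 °C)²; the attribution stage therefore clamps RR in
[1 − 1e-4, 1) to 1 and treats anything lower as a contract violation.

A day at exactly the MMT is labelled cold; AF is zero there, so the
label is inert. Warm/cold classification is applied at the *cell* level
(each cell's own temperature against the age-specific MMT), consistent
with AF being computed per cell; a domain-level mode (classification by
the domain-mean temperature) is available behind a switch.

## Extreme days and periods

Heat (cold) extreme days are the warmest (coldest) 2% of days of the
analysis window, ranked by the domain population-weighted daily mean
temperature over included cells; k = round-half-up(fraction × n_days),
which yields 22 days per tail for a 2015–2017 window (1096 days). Ties
break toward the earlier date, making the selection deterministic and
invariant under monotone transformations of the series.

Annual nets are means over calendar years of within-year sums of the
daily differential; daily baselines divide the annual mortality rate by
the actual calendar-year length (366 in 2016). Seasons are
meteorological (DJF/MAM/JJA/SON) pooled across years, December attached
to the following winter. Heat + cold components partition the annual net
exactly because warm/cold labels partition cell-days.

## Monte-Carlo propagation

Central estimates use exact per-cell-day evaluation. For the draw
ensemble, each city's cell-days are first tabulated into 0.01 °C
temperature bins per stratum and day set (with 1/year-length weights),
and each draw's curve is then evaluated exactly at the bin centres; the
only approximation is the sub-bin discretization (≤ 0.005 °C, a
relative error of order 1e-4 on aggregates, verified against the exact
path in the test suite). This makes hundred-draw ensembles over
multi-year cubes essentially free without touching the central
estimates.

Cohort intervals are empirical quantiles across draws of the per-draw
cohort summary — the median impact across cities, or the count of cities
whose annual net differential is adverse (positive). The adverse-count
interval is reported at 90%; median-impact intervals default to 95% with
a config option, since only the adverse-count level is pinned by
convention.

## Economic valuation

The VSL of 3.6 million 2005-USD is converted to 2021 euros by
multiplying with the 2005 euro-area purchasing power parity (0.853
EUR/USD) and the euro-area CPI ratio 107.8/84.7, giving 3.91 million
2021-EUR (reported at 3 significant figures). The VOLY of 40,000
2010-EUR converts with CPI 107.8/93.1 to 46,000 2021-EUR (2 significant
figures), with bounding estimates 29,000–116,000 2021-EUR. Unrounded
values are carried internally. YLL weights per-age annual differentials
by remaining life expectancy; no discounting of future life years is
applied. The per-adult denominator is the adult (20+) population of the
analysis domain, since the youngest modelled group starts at 20.

## The synthetic-city generator

The generator emulates the study conditions so every downstream stage is
testable without large external inputs. Its temperature model is

    T(c, d) = T_bg(d) + ε(d) + A · (imp_c / 100) · m(d)

with `T_bg` a seasonal cosine (peak near 20 July) around the annual
mean, `ε` an AR(1) weather anomaly shared by all cells, `A` the UHI
amplitude at 100% imperviousness and `m(d)` a seasonal modulation of the
UHI (mean 1, stronger in summer). Defaults: 40×40 grid, 2015–2017, UHI
amplitude 2 °C, modulation 0.3, annual mean 11 °C, seasonal amplitude
8 °C, AR(1) autocorrelation 0.7, weather s.d. 3 °C, 5% water cells,
1,000,000 adults, adult age shares (0.40, 0.33, 0.13, 0.10, 0.04) and
annual baseline mortality (80, 530, 1800, 5500, 15500) per 100k for the
five age groups — European orders of magnitude. ERF shapes are U-curves
with age-dependent MMT (19 → 17 °C) and extreme RRs rising with age
(1.10–1.15 for 20–44 up to 1.8–2.0 for 85+); ensembles perturb (MMT,
cold log-RR, warm log-RR) with independent Gaussian noise (default
s.d. 0.1) and every draw is recentred so RR = 1 at its own MMT.

Design choices worth making explicit:

* **Shared weather anomaly.** ε is spatially uniform, so the
  imperviousness-driven offset is the *only* urban-rural temperature
  difference. This isolates the quantity under study and keeps the
  expected impact differential available in closed form.
* **Linear UHI in imperviousness.** Real UHI-imperviousness relations
  are nonlinear; linearity keeps the ground-truth oracle closed-form. A
  binary "plateau" option (100% inside the core, 0 outside) exists for
  tests that need a uniform urban offset.
* **Population copula.** Population is rank-correlated with
  imperviousness via a Gaussian copula with parameter 2·sin(π·ρ/6),
  hitting a target Spearman correlation (default 0.47) with lognormal
  marginals.
* **Bounded temperatures.** AR innovations are clamped at ±8 s.d., so
  generated temperatures provably stay inside
  annual mean ± seasonal amplitude ± 8 weather s.d. (+ UHI offset); the
  clamp triggers with probability ~1e-15 and is irrelevant to any
  moment.
* **Seeding.** One master seed; sub-streams (weather, water, population,
  ERF) derive from `SeedSequence(master, spawn_key=(city, stream))`, so
  cities and streams are independent and every output is bit-reproducible.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: synoptic weather systems and spatially
structured anomalies, humidity and wind modifiers of heat stress,
intra-urban vulnerability heterogeneity, day-of-week and holiday
mortality structure, and physically based urban canopy dynamics. Tests
against the generator validate the *estimator machinery* (masking,
attribution arithmetic, aggregation, uncertainty propagation,
valuation), not the epidemiological realism of any particular city.

## Numerical choices and degenerate inputs

* Quantile rule: linear interpolation between order statistics,
  everywhere.
* Dominant-class regrid ties (equal urban/rural counts, no water) go to
  rural.
* Empty Δimperviousness bins are missing values, never zeros; cities
  whose maximum urban-rural imperviousness difference is below 80% are
  excluded from cohort profile curves, and group medians supported by
  fewer than four cities are suppressed.
* A rural extreme-day mean of exactly zero makes the percent-vs-rural
  change undefined; it is flagged missing, not ±∞.
* Spearman p-values: exact permutation for n ≤ 9 cities, large-sample
  approximation otherwise; correlations with p ≥ 0.01 are masked, and
  constant columns are masked with a diagnostic.
* Köppen groups of size one merge into the same-base-letter group with
  most agreement in the remaining letters and the merged group is
  relabelled by its base class; a singleton with no same-base companion
  keeps its base-class label and is flagged.

## Problem sizes

The packaged demo cohort runs 10 cities on 40×40 grids over 2015–2017
with 100-draw ERF ensembles — about half a minute end-to-end on one CPU.
The closed-form recovery harness uses 20 weather seeds of a 14×14
plateau city; the interval-coverage harness uses 500 repetitions of a
7-city Gaussian setup. These sizes were chosen so the full test suite
gives tight statistical checks while remaining quick to iterate on;
every size is a parameter, and nothing in the implementation depends on
them.

## Known limitations

* ERF first-stage fitting (DLNM, meta-regression, kriging) is out of
  scope; coefficients are inputs.
* No lag redistribution of deaths across calendar days: curves are
  already lag-cumulative, so daily ANs are short-term cumulative
  attributions, not death-day counts.
* No harvesting/displacement modelling; no morbidity, productivity or
  energy costs in the valuation.
* The planar equal-area grid ignores map projection effects, which is
  adequate at city scale only.
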