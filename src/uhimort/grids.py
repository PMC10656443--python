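"""Gridded data model and spatial preprocessing for city-domain analyses.

The analysis operates on a planar, equal-area raster of square cells
(nominally 500 m).  All layers of one city share a :class:`GridSpec`;
cells are addressed row-major with 0-based indices and cell-centre
semantics.  No map projection or latitude correction is applied: at city
scale a metric grid is near-equal-area, so every cell carries the same
areal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "LandClass",
    "CellStatus",
    "GridSpec",
    "StaticLayer",
    "DailyTemperatureCube",
    "AnalysisMask",
    "regrid_dominant_class",
    "build_analysis_mask",
    "weighted_spatial_mean",
]

LAYER_KINDS = ("imperviousness_pct", "elevation_m", "population_count", "land_class")

Stratum = Literal["urban", "rural", "all"]


class LandClass(IntEnum):
    """Land-cover class of a cell (collapsed CORINE-style typology)."""

    RURAL = 0
    URBAN = 1
    WATER = 2


class CellStatus(IntEnum):
    """Analysis status of a cell after exclusion masking."""

    RURAL_INCLUDED = 0
    URBAN_INCLUDED = 1
    EXCLUDED_WATER = 2
    EXCLUDED_ELEVATION = 3


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis raster.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both at least 1.
    cell_size
        Cell edge length in metres (nominal 500).
    origin
        (x, y) of the lower-left corner in an abstract planar frame.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 500.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


def _check_shape(spec: GridSpec, values: np.ndarray, what: str) -> None:
    if values.shape != spec.shape:
        raise ValueError(f"{what} shape {values.shape} does not match grid {spec.shape}")


@dataclass
class StaticLayer:
    """A single static per-cell field (imperviousness, elevation, population
    or land class) on a :class:`GridSpec`."""

    spec: GridSpec
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; expected one of {LAYER_KINDS}")
        self.values = np.asarray(self.values)
        _check_shape(self.spec, self.values, f"{self.kind} layer")
        if self.kind == "land_class":
            codes = set(np.unique(self.values).tolist())
            allowed = {int(c) for c in LandClass}
            if not codes <= allowed:
                raise ValueError(f"invalid land-class codes {sorted(codes - allowed)}")
            self.values = self.values.astype(np.int8)
        else:
            self.values = self.values.astype(np.float64)
            if not np.all(np.isfinite(self.values)):
                raise ValueError(f"{self.kind} layer contains non-finite values")
            if self.kind == "imperviousness_pct" and (
                self.values.min() < 0 or self.values.max() > 100
            ):
                raise ValueError("imperviousness must lie in [0, 100]")
            if self.kind == "population_count" and self.values.min() < 0:
                raise ValueError("population counts must be non-negative")


@dataclass
class DailyTemperatureCube:
    """Daily mean near-surface air temperature (°C) per cell.

    ``values`` has shape ``(n_days, n_rows, n_cols)``; ``dates`` are
    consecutive calendar days with no gaps.
    """

    spec: GridSpec
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.dates):
            raise ValueError("cube values must be (n_days, n_rows, n_cols)")
        _check_shape(self.spec, self.values[0], "temperature slice")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("dates must be consecutive calendar days")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temperature cube contains non-finite values")

    @property
    def n_days(self) -> int:
        return len(self.dates)


@dataclass
class AnalysisMask:
    """Per-cell analysis status implementing the water and elevation
    exclusion rules; excluded cells carry zero weight downstream."""

    spec: GridSpec
    status: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status).astype(np.int8)
        _check_shape(self.spec, self.status, "mask")
        allowed = {int(s) for s in CellStatus}
        codes = set(np.unique(self.status).tolist())
        if not codes <= allowed:
            raise ValueError(f"invalid status codes {sorted(codes - allowed)}")

    @property
    def urban(self) -> np.ndarray:
        return self.status == CellStatus.URBAN_INCLUDED

    @property
    def rural(self) -> np.ndarray:
        return self.status == CellStatus.RURAL_INCLUDED

    @property
    def included(self) -> np.ndarray:
        return self.urban | self.rural

    def stratum_mask(self, stratum: Stratum) -> np.ndarray:
        if stratum == "urban":
            return self.urban
        if stratum == "rural":
            return self.rural
        if stratum == "all":
            return self.included
        raise ValueError(f"unknown stratum {stratum!r}")


def regrid_dominant_class(fine: StaticLayer, factor: int) -> StaticLayer:
    """Aggregate a fine land-class layer to a coarser grid.

    A coarse cell is ``WATER`` if *any* constituent fine cell is water
    (only grids containing no water features count as land); otherwise it
    takes the majority class among urban/rural fine cells, ties going to
    rural.
    """
    if fine.kind != "land_class":
        raise ValueError("dominant-class regridding applies to land_class layers")
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    nr, nc = fine.spec.shape
    if nr % factor or nc % factor:
        raise ValueError(f"grid {fine.spec.shape} not divisible by factor {factor}")
    blocks = fine.values.reshape(nr // factor, factor, nc // factor, factor)
    any_water = (blocks == LandClass.WATER).any(axis=(1, 3))
    n_urban = (blocks == LandClass.URBAN).sum(axis=(1, 3))
    n_rural = (blocks == LandClass.RURAL).sum(axis=(1, 3))
    coarse = np.where(n_urban > n_rural, LandClass.URBAN, LandClass.RURAL)
    coarse = np.where(any_water, LandClass.WATER, coarse).astype(np.int8)
    spec = GridSpec(nr // factor, nc // factor, fine.spec.cell_size * factor, fine.spec.origin)
    return StaticLayer(spec, "land_class", coarse)


def build_analysis_mask(
    class_layer: StaticLayer,
    elevation: StaticLayer,
    population: StaticLayer,
    threshold: float = 100.0,
) -> AnalysisMask:
    """Classify cells for analysis.

    Water cells are excluded outright.  The elevation reference is the
    population-weighted mean elevation over all land cells (computed
    *before* any elevation exclusion); land cells whose elevation differs
    from the reference by more than ``threshold`` metres are excluded.
    Remaining cells keep their urban/rural status.
    """
    if not (class_layer.spec == elevation.spec == population.spec):
        raise ValueError("layers must share one GridSpec")
    land = class_layer.values != LandClass.WATER
    w = population.values[land]
    if w.sum() <= 0:
        raise ValueError("degenerate weights: total population over land cells is zero")
    reference = float(np.sum(w * elevation.values[land]) / w.sum())
    status = np.where(
        class_layer.values == LandClass.URBAN,
        CellStatus.URBAN_INCLUDED,
        CellStatus.RURAL_INCLUDED,
    )
    status = np.where(
        np.abs(elevation.values - reference) > threshold,
        CellStatus.EXCLUDED_ELEVATION,
        status,
    )
    status = np.where(class_layer.values == LandClass.WATER, CellStatus.EXCLUDED_WATER, status)
    return AnalysisMask(class_layer.spec, status.astype(np.int8))


def weighted_spatial_mean(
    values: np.ndarray | StaticLayer,
    mask: AnalysisMask,
    stratum: Stratum = "all",
    weights: np.ndarray | StaticLayer | None = None,
) -> float:
    """Weighted mean of a per-cell field over the included cells of a
    stratum; ``weights=None`` means uniform (arithmetic mean)."""
    vals = values.values if isinstance(values, StaticLayer) else np.asarray(values)
    _check_shape(mask.spec, vals, "values")
    sel = mask.stratum_mask(stratum)
    if not sel.any():
        raise ValueError(f"stratum {stratum!r} has no included cells")
    if weights is None:
        return float(vals[sel].mean())
    w = weights.values if isinstance(weights, StaticLayer) else np.asarray(weights)
    _check_shape(mask.spec, w, "weights")
    wsel = w[sel]
    tot = wsel.sum()
    if tot <= 0:
        raise ValueError(f"stratum {stratum!r} has zero total weight")
    return float(np.sum(wsel * vals[sel]) / tot)
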