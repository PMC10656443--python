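"""Readers and writers for the on-disk formats.

Temperature cubes and static layers travel as NetCDF (classic format,
dimensions ``(time, y, x)`` for cubes and ``(y, x)`` for layers); all
tabular data are UTF-8 CSV with a header row and '.' decimal separator.
Round trips are value-exact for class layers and within float32-level
tolerance for continuous layers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import AnalysisMask, DailyTemperatureCube, GridSpec, StaticLayer

_ENGINE = "scipy"  # classic NetCDF3; no compiled netCDF4 dependency


def _spec_attrs(spec: GridSpec) -> dict:
    return {
        "cell_size": spec.cell_size,
        "origin_x": spec.origin[0],
        "origin_y": spec.origin[1],
    }


def _spec_from_attrs(attrs: dict, n_rows: int, n_cols: int) -> GridSpec:
    return GridSpec(
        n_rows,
        n_cols,
        float(attrs.get("cell_size", 500.0)),
        (float(attrs.get("origin_x", 0.0)), float(attrs.get("origin_y", 0.0))),
    )


def write_cube(cube: DailyTemperatureCube, path: str | Path) -> None:
    da = xr.DataArray(
        cube.values,
        dims=("time", "y", "x"),
        coords={"time": cube.dates},
        name="tmean_c",
        attrs={"units": "degC", "long_name": "daily mean near-surface air temperature"},
    )
    ds = xr.Dataset({"tmean_c": da}, attrs=_spec_attrs(cube.spec))
    ds.to_netcdf(path, engine=_ENGINE)


def read_cube(path: str | Path) -> DailyTemperatureCube:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        da = ds["tmean_c"].load()
        spec = _spec_from_attrs(ds.attrs, da.sizes["y"], da.sizes["x"])
        dates = pd.DatetimeIndex(da["time"].values).normalize()
        return DailyTemperatureCube(spec, dates, da.values.astype(np.float64))


def write_layer(layer: StaticLayer, path: str | Path) -> None:
    da = xr.DataArray(layer.values, dims=("y", "x"), name=layer.kind)
    ds = xr.Dataset({layer.kind: da}, attrs={**_spec_attrs(layer.spec), "kind": layer.kind})
    ds.to_netcdf(path, engine=_ENGINE)


def read_layer(path: str | Path) -> StaticLayer:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        kind = str(ds.attrs["kind"])
        da = ds[kind].load()
        spec = _spec_from_attrs(ds.attrs, da.sizes["y"], da.sizes["x"])
        return StaticLayer(spec, kind, da.values)


def write_mask(mask: AnalysisMask, path: str | Path) -> None:
    da = xr.DataArray(mask.status.astype(np.int32), dims=("y", "x"), name="cell_status")
    ds = xr.Dataset({"cell_status": da}, attrs=_spec_attrs(mask.spec))
    ds.to_netcdf(path, engine=_ENGINE)


def read_mask(path: str | Path) -> AnalysisMask:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        da = ds["cell_status"].load()
        spec = _spec_from_attrs(ds.attrs, da.sizes["y"], da.sizes["x"])
        return AnalysisMask(spec, da.values)


# ---------------------------------------------------------------------------
# tabular formats

def write_erf_table(path: str | Path, table: pd.DataFrame) -> None:
    """ERF coefficient CSV: (city_id, age_group, percentile, log_rr,
    draw_index); draw_index 0 is the central curve."""
    cols = ["city_id", "age_group", "percentile", "log_rr", "draw_index"]
    table[cols].to_csv(path, index=False)


def read_erf_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"city_id", "age_group", "percentile", "log_rr", "draw_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ERF table {path} missing columns {sorted(missing)}")
    return df


def write_reference_series(path: str | Path, series: pd.Series, city_id: str) -> None:
    """Reference-series CSV: (city_id, date, tmean_c)."""
    df = pd.DataFrame(
        {"city_id": city_id, "date": series.index.strftime("%Y-%m-%d"), "tmean_c": series.values}
    )
    df.to_csv(path, index=False)


def read_reference_series(path: str | Path, city_id: str | None = None) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["date"])
    if city_id is not None:
        df = df[df["city_id"] == city_id]
    return pd.Series(df["tmean_c"].values, index=pd.DatetimeIndex(df["date"]), name="tmean_c")
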