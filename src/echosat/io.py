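"""Readers and writers for the pipeline's on-disk formats.

Echograms and satellite scenes travel as NetCDF (a layout loosely
mirroring SONAR-netCDF4 / level-3 mapped products); tables (NASC cells,
feature rows, evaluation results, bottom lines) as UTF-8 CSV with a
header row, ISO-8601 timestamps and '.' decimals.  Every NetCDF file
carries a ``schema_version`` attribute; readers reject files written by
a newer schema.  CSV readers validate the exact column set.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import xarray as xr

from .echogram import Echogram
from .matchup import VARIABLE_UNITS, SatelliteScene

SCHEMA_VERSION = 1

_NC = dict(engine="scipy")  # NetCDF3 classic backend


def _check_schema(attrs, path):
    version = int(attrs.get("schema_version", 0))
    if version > SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema_version {version} is newer than supported {SCHEMA_VERSION}"
        )


def write_echogram(echogram: Echogram, path) -> None:
    ds = xr.Dataset(
        {
            "Sv": (("ping_time", "depth"), echogram.sv_db),
            "latitude": ("ping_time", echogram.latitudes),
            "longitude": ("ping_time", echogram.longitudes),
        },
        coords={"ping_time": echogram.ping_times, "depth": echogram.depth_m},
        attrs={
            "schema_version": SCHEMA_VERSION,
            "frequency_khz": echogram.frequency_khz,
            "missing_value": "NaN",
            "Sv_units": "dB re 1 m-1",
            "depth_units": "m below sea surface",
        },
    )
    ds.to_netcdf(path, **_NC)
    ds.close()


def read_echogram(path) -> Echogram:
    with xr.open_dataset(path, **_NC) as ds:
        _check_schema(ds.attrs, path)
        for name in ("Sv", "latitude", "longitude"):
            if name not in ds:
                raise ValueError(f"{path}: missing variable '{name}'")
        for dim in ("ping_time", "depth"):
            if dim not in ds.dims:
                raise ValueError(f"{path}: missing dimension '{dim}'")
        return Echogram(
            frequency_khz=int(ds.attrs["frequency_khz"]),
            ping_times=ds["ping_time"].values,
            latitudes=ds["latitude"].values,
            longitudes=ds["longitude"].values,
            depth_m=ds["depth"].values,
            sv_db=ds["Sv"].values,
        )


# ---------------------------------------------------------------------------
# Echoview-style Sv CSV (one ping per row: metadata columns then samples)


def write_sv_csv(echogram: Echogram, path) -> None:
    n = echogram.n_depths
    dz = echogram.depth_spacing
    meta = pd.DataFrame(
        {
            "ping_date": pd.DatetimeIndex(echogram.ping_times).strftime("%Y-%m-%d"),
            "ping_time": pd.DatetimeIndex(echogram.ping_times).strftime("%H:%M:%S.%f"),
            "latitude": echogram.latitudes,
            "longitude": echogram.longitudes,
            "depth_start": echogram.depth_m[0] - dz / 2.0,
            "depth_stop": echogram.depth_m[-1] + dz / 2.0,
            "sample_count": n,
            "frequency_khz": echogram.frequency_khz,
        }
    )
    samples = pd.DataFrame(
        echogram.sv_db, columns=[f"sv_{i + 1}" for i in range(n)]
    )
    pd.concat([meta, samples], axis=1).to_csv(path, index=False)


def read_sv_csv(path) -> Echogram:
    df = pd.read_csv(path)
    required = {"ping_date", "ping_time", "latitude", "longitude",
                "depth_start", "depth_stop", "sample_count", "frequency_khz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    n = int(df["sample_count"].iloc[0])
    sv_cols = [f"sv_{i + 1}" for i in range(n)]
    times = pd.to_datetime(
        df["ping_date"].astype(str) + " " + df["ping_time"].astype(str)
    ).to_numpy()
    lo = float(df["depth_start"].iloc[0])
    hi = float(df["depth_stop"].iloc[0])
    dz = (hi - lo) / n
    depth = lo + dz * (np.arange(n) + 0.5)
    return Echogram(
        frequency_khz=int(df["frequency_khz"].iloc[0]),
        ping_times=times,
        latitudes=df["latitude"].to_numpy(),
        longitudes=df["longitude"].to_numpy(),
        depth_m=depth,
        sv_db=df[sv_cols].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# satellite scenes


def write_scene(scene: SatelliteScene, path) -> None:
    ds = xr.Dataset(
        {scene.variable: (("lat", "lon"), scene.values)},
        coords={"lat": scene.lats, "lon": scene.lons},
        attrs={
            "schema_version": SCHEMA_VERSION,
            "variable": scene.variable,
            "units": VARIABLE_UNITS[scene.variable],
            "date": scene.date.isoformat(),
            "platform": scene.platform,
        },
    )
    ds.to_netcdf(path, **_NC)
    ds.close()


def read_scene(path) -> SatelliteScene:
    with xr.open_dataset(path, **_NC) as ds:
        _check_schema(ds.attrs, path)
        var = ds.attrs.get("variable")
        if var is None or var not in ds:
            raise ValueError(f"{path}: missing the scene variable")
        return SatelliteScene(
            variable=var,
            date=dt.date.fromisoformat(ds.attrs["date"]),
            platform=ds.attrs["platform"],
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            values=ds[var].values,
        )


def write_bathymetry(grid, path) -> None:
    from .matchup import BathymetryGrid  # noqa: F401 - type of `grid`

    ds = xr.Dataset(
        {"ocean_depth_m": (("lat", "lon"), grid.depth_m)},
        coords={"lat": grid.lats, "lon": grid.lons},
        attrs={"schema_version": SCHEMA_VERSION, "sign_convention": "positive-down"},
    )
    ds.to_netcdf(path, **_NC)
    ds.close()


def read_bathymetry(path):
    from .matchup import BathymetryGrid

    with xr.open_dataset(path, **_NC) as ds:
        _check_schema(ds.attrs, path)
        if "ocean_depth_m" not in ds:
            raise ValueError(f"{path}: missing variable 'ocean_depth_m'")
        return BathymetryGrid(
            ds["lat"].values, ds["lon"].values, ds["ocean_depth_m"].values
        )


def write_masks(masks: dict[str, np.ndarray], path) -> None:
    """Write named boolean sample masks (e.g. a FilterReport) as int8."""
    ds = xr.Dataset(
        {name: (("ping", "depth"), m.astype(np.int8)) for name, m in masks.items()},
        attrs={"schema_version": SCHEMA_VERSION},
    )
    ds.to_netcdf(path, **_NC)
    ds.close()


def read_masks(path) -> dict[str, np.ndarray]:
    with xr.open_dataset(path, **_NC) as ds:
        _check_schema(ds.attrs, path)
        return {name: ds[name].values.astype(bool) for name in ds.data_vars}


# ---------------------------------------------------------------------------
# CSV tables


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, expected_columns=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if expected_columns is not None:
        got, want = list(df.columns), list(expected_columns)
        if got != want:
            raise ValueError(f"{path}: columns {got} != expected {want}")
    return df
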