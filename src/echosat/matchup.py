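"""Satellite-to-sonar matchup and covariate assembly.

Builds the model feature table: 7-day windowed means of daily merged
Terra/Aqua ocean-colour scenes (chlorophyll-a, normalized fluorescence
line height, particulate organic carbon, SST) sampled at each NASC
bin's midpoint, plus geographic covariates (latitude, ocean depth,
distance from shore) and observation covariates (daytime, frequency,
depth layer, frequency x depth-layer interaction).  Rows with any
missing satellite covariate and rows with non-positive NASC are
excluded, with counters.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .integration import EARTH_RADIUS_M, great_circle_m

logger = logging.getLogger(__name__)

SATELLITE_VARIABLES = ("chlor_a", "nflh", "poc", "sst")

VARIABLE_UNITS = {
    "chlor_a": "mg m-3",
    "nflh": "mW cm-2 um-1 sr-1",
    "poc": "mg m-3",
    "sst": "degC",
}

PLATFORMS = ("terra", "aqua", "merged")

FEATURE_COLUMNS = [
    "cruise_id",
    "year",
    "bin_index",
    "frequency_khz",
    "depth_layer",
    "freq_depth",
    "daytime",
    "distance_from_shore_km",
    "latitude",
    "ocean_depth_m",
    "chlor_a",
    "nflh",
    "poc",
    "sst",
    "nasc",
    "log_nasc",
]


@dataclass
class SatelliteScene:
    """One daily level-3-style mapped raster of a single variable.

    ``lats``/``lons`` are cell-centre coordinates of a regular grid
    (nominally 1/24 degree ~ 4 km); ``values`` is (n_lat, n_lon) with
    NaN for missing cells.
    """

    variable: str
    date: dt.date
    platform: str
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if self.variable not in SATELLITE_VARIABLES:
            raise ValueError(f"unknown satellite variable {self.variable!r}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lats.size, self.lons.size):
            raise ValueError("values shape mismatch with lat/lon axes")
        for ax in (self.lats, self.lons):
            if ax.size > 1 and np.ptp(np.diff(ax)) > 1e-9:
                raise ValueError("grid spacing must be uniform")

    def _same_grid(self, other: "SatelliteScene") -> bool:
        return (
            self.lats.shape == other.lats.shape
            and self.lons.shape == other.lons.shape
            and np.allclose(self.lats, other.lats)
            and np.allclose(self.lons, other.lons)
        )


def merge_terra_aqua(scenes: list[SatelliteScene]) -> SatelliteScene:
    """Cellwise same-day mean of Terra and Aqua, ignoring missing cells."""
    if not scenes:
        raise ValueError("no scenes to merge")
    first = scenes[0]
    for s in scenes[1:]:
        if s.variable != first.variable or s.date != first.date:
            raise ValueError("scenes must share date and variable")
        if not first._same_grid(s):
            raise ValueError("scenes must share the grid")
    stack = np.stack([s.values for s in scenes])
    with np.errstate(all="ignore"):
        counts = np.isfinite(stack).sum(axis=0)
        merged = np.where(
            counts > 0, np.nansum(np.nan_to_num(stack), axis=0) / np.maximum(counts, 1), np.nan
        )
    return SatelliteScene(
        first.variable, first.date, "merged", first.lats, first.lons, merged
    )


def window_mean(
    daily_scenes: list[SatelliteScene],
    center_date: dt.date,
    half_width_days: int = 3,
) -> SatelliteScene:
    """Cellwise mean of daily merged scenes dated within +/- 3 days.

    A cell is missing only when it is missing on every day of the
    window; an empty window yields an all-missing scene (logged).
    """
    if not daily_scenes:
        raise ValueError("no daily scenes supplied")
    first = daily_scenes[0]
    in_window = [
        s
        for s in daily_scenes
        if abs((s.date - center_date).days) <= half_width_days
    ]
    if not in_window:
        logger.warning(
            "no %s scenes within +/-%d days of %s; all-missing window mean",
            first.variable,
            half_width_days,
            center_date,
        )
        values = np.full_like(first.values, np.nan)
    else:
        stack = np.stack([s.values for s in in_window])
        counts = np.isfinite(stack).sum(axis=0)
        values = np.where(
            counts > 0,
            np.nansum(np.nan_to_num(stack), axis=0) / np.maximum(counts, 1),
            np.nan,
        )
    return SatelliteScene(
        first.variable, center_date, "merged", first.lats, first.lons, values
    )


def sample_scene(scene: SatelliteScene, latitude: float, longitude: float) -> float:
    """Nearest-cell lookup (no interpolation); outside the extent -> NaN."""
    dlat = scene.lats[1] - scene.lats[0] if scene.lats.size > 1 else 1.0
    dlon = scene.lons[1] - scene.lons[0] if scene.lons.size > 1 else 1.0
    i = int(round((latitude - scene.lats[0]) / dlat))
    j = int(round((longitude - scene.lons[0]) / dlon))
    if not (0 <= i < scene.lats.size and 0 <= j < scene.lons.size):
        logger.debug("point (%.3f, %.3f) outside scene extent", latitude, longitude)
        return float("nan")
    return float(scene.values[i, j])


# ---------------------------------------------------------------------------
# geographic covariates


def _to_unit(lat, lon):
    lat, lon = np.radians(lat), np.radians(lon)
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


def distance_from_shore(
    latitude: float, longitude: float, coastline: list[np.ndarray]
) -> float:
    """Minimum great-circle distance (km) to a set of coastline polylines.

    Each polyline is an (n, 2) array of (lat, lon) vertices.  Uses the
    spherical cross-track distance where the point projects inside a
    segment, else the nearer endpoint.
    """
    if not coastline:
        raise ValueError("empty coastline")
    p = _to_unit(latitude, longitude)
    best = np.inf
    for line in coastline:
        line = np.asarray(line, dtype=float)
        verts = _to_unit(line[:, 0], line[:, 1])
        # vertex distances
        d_vert = np.arccos(np.clip(verts @ p, -1.0, 1.0))
        best = min(best, d_vert.min())
        for a, b in zip(verts[:-1], verts[1:]):
            n = np.cross(a, b)
            norm = np.linalg.norm(n)
            if norm < 1e-15:  # degenerate segment
                continue
            n = n / norm
            # cross-track angular distance to the great circle through a, b
            dxt = np.abs(np.arcsin(np.clip(n @ p, -1.0, 1.0)))
            # projection of p onto the great circle
            proj = p - (n @ p) * n
            proj = proj / np.linalg.norm(proj)
            seg = np.arccos(np.clip(a @ b, -1.0, 1.0))
            t_a = np.arccos(np.clip(a @ proj, -1.0, 1.0))
            t_b = np.arccos(np.clip(b @ proj, -1.0, 1.0))
            if t_a <= seg + 1e-12 and t_b <= seg + 1e-12:  # inside the segment
                best = min(best, dxt)
    return float(best * EARTH_RADIUS_M / 1000.0)


@dataclass
class BathymetryGrid:
    """Regular lat/lon raster of ocean depth, metres positive down."""

    lats: np.ndarray
    lons: np.ndarray
    depth_m: np.ndarray
    sign_convention: str = "positive-down"

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self._interp = RegularGridInterpolator(
            (self.lats, self.lons),
            self.depth_m,
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )


def ocean_depth(
    latitude, longitude, bathymetry: BathymetryGrid
) -> float | np.ndarray:
    """Bilinear interpolation of the bathymetry raster (positive down)."""
    pts = np.stack(
        [np.atleast_1d(np.asarray(latitude, float)), np.atleast_1d(np.asarray(longitude, float))],
        axis=-1,
    )
    out = bathymetry._interp(pts)
    if np.any(~np.isfinite(out)):
        logger.debug("ocean_depth: %d point(s) outside the bathymetry grid",
                     int((~np.isfinite(out)).sum()))
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# feature assembly


@dataclass
class MatchupCounters:
    """Reconciliation counters for the exclusion rules."""

    input_cells: int = 0
    dropped_missing_nasc: int = 0
    dropped_nonpositive_nasc: int = 0
    dropped_missing_satellite: int = 0
    rows_out: int = 0


def assemble_features(
    nasc_cells: pd.DataFrame,
    daily_scenes: dict[str, list[SatelliteScene]],
    coastline: list[np.ndarray],
    bathymetry: BathymetryGrid,
    half_width_days: int = 3,
) -> tuple[pd.DataFrame, MatchupCounters]:
    """Join NASC cells to their covariates; apply the exclusion filters.

    Satellite covariates are the 7-day window means sampled (nearest
    cell) at the bin midpoint, attached identically to every depth layer
    of the bin.  Rows whose NASC is missing or non-positive, or with any
    missing satellite covariate, are dropped and counted.
    """
    counters = MatchupCounters(input_cells=len(nasc_cells))
    df = nasc_cells.copy()

    missing_nasc = ~np.isfinite(df["nasc"].to_numpy(dtype=float))
    counters.dropped_missing_nasc = int(missing_nasc.sum())
    df = df[~missing_nasc]
    nonpos = df["nasc"].to_numpy(dtype=float) <= 0.0
    counters.dropped_nonpositive_nasc = int(nonpos.sum())
    df = df[~nonpos].reset_index(drop=True)

    # one window mean per (variable, date); sample at each cell midpoint
    window_cache: dict[tuple[str, dt.date], SatelliteScene] = {}
    sat_values = {v: np.full(len(df), np.nan) for v in SATELLITE_VARIABLES}
    for idx, row in df.iterrows():
        date = row["date"]
        if isinstance(date, str):
            date = dt.date.fromisoformat(date)
        elif isinstance(date, pd.Timestamp):
            date = date.date()
        for var in SATELLITE_VARIABLES:
            key = (var, date)
            if key not in window_cache:
                window_cache[key] = window_mean(
                    daily_scenes[var], date, half_width_days
                )
            sat_values[var][idx] = sample_scene(
                window_cache[key], row["mid_latitude"], row["mid_longitude"]
            )

    dist = np.array(
        [
            distance_from_shore(la, lo, coastline)
            for la, lo in zip(df["mid_latitude"], df["mid_longitude"])
        ]
    )
    depth = np.atleast_1d(
        ocean_depth(df["mid_latitude"].to_numpy(), df["mid_longitude"].to_numpy(), bathymetry)
    )

    out = pd.DataFrame(
        {
            "cruise_id": df["cruise_id"],
            "year": df["year"].astype(int),
            "bin_index": df["bin_index"].astype(int),
            "frequency_khz": df["frequency_khz"].astype(int),
            "depth_layer": df["depth_layer"],
            "freq_depth": df["frequency_khz"].astype(int).astype(str)
            + "_"
            + df["depth_layer"].astype(str),
            "daytime": df["daytime"].astype(bool),
            "distance_from_shore_km": dist,
            "latitude": df["mid_latitude"].astype(float),
            "ocean_depth_m": depth,
            "chlor_a": sat_values["chlor_a"],
            "nflh": sat_values["nflh"],
            "poc": sat_values["poc"],
            "sst": sat_values["sst"],
            "nasc": df["nasc"].astype(float),
        }
    )
    sat_missing = ~np.isfinite(out[list(SATELLITE_VARIABLES)].to_numpy()).all(axis=1)
    counters.dropped_missing_satellite = int(sat_missing.sum())
    out = out[~sat_missing].reset_index(drop=True)
    out["log_nasc"] = np.log(out["nasc"].to_numpy())
    counters.rows_out = len(out)
    logger.info(
        "assemble_features: %d cells -> %d rows (%d missing nasc, %d nasc<=0, "
        "%d missing satellite)",
        counters.input_cells,
        counters.rows_out,
        counters.dropped_missing_nasc,
        counters.dropped_nonpositive_nasc,
        counters.dropped_missing_satellite,
    )
    return out[FEATURE_COLUMNS], counters
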