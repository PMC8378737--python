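"""Core echogram container and dB/linear arithmetic.

An echogram is a ping x depth raster of volume backscattering strength
``S_V`` (dB re 1 m^-1) on a uniform depth grid, with per-ping time and
position.  Missing samples (removed noise, no data) are represented by
NaN throughout the package; a sample thresholded to zero energy during
echo integration is *not* missing — that distinction is handled in
:mod:`echosat.integration`.

Averaging across the dB boundary always happens in the linear domain
(``s_v = 10**(S_V/10)``): acoustic energy, not decibels, is additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SUPPORTED_FREQUENCIES_KHZ = (18, 38, 70, 120, 200)

#: Categorical tags for why a sample was masked.
MASK_REASONS = (
    "background",
    "impulsive",
    "transient",
    "attenuated",
    "validity",
    "below_bottom",
)

_DEPTH_SPACING_TOL = 1e-9


def db_to_linear(sv_db):
    """Convert volume backscattering strength ``S_V`` (dB) to linear ``s_v`` (m^-1).

    NaN (missing) propagates.  Total on finite input: ``10**(x/10)`` is
    strictly positive.
    """
    return np.power(10.0, np.asarray(sv_db, dtype=float) / 10.0)


def linear_to_db(s_v):
    """Convert linear backscattering coefficient ``s_v`` (m^-1) to dB.

    Zero maps to NaN (the repo-wide missing sentinel); negative input is
    corrupted linear-domain data and raises.
    """
    s_v = np.asarray(s_v, dtype=float)
    if np.any(s_v < 0):
        raise ValueError("negative linear backscatter: corrupted data")
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(s_v)
    out = np.where(np.isneginf(out), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class Echogram:
    """Single-frequency ping x depth raster of ``S_V``.

    Parameters
    ----------
    frequency_khz : int
        One of 18, 38, 70, 120, 200.
    ping_times : ndarray of datetime64[ns]
        Strictly increasing UTC timestamps, one per ping.
    latitudes, longitudes : ndarray
        Decimal degrees per ping.
    depth_m : ndarray
        Uniform grid of sample depths (bin centres) below the sea
        surface, metres, within [0, 750].
    sv_db : ndarray, shape (n_pings, n_depths)
        ``S_V`` in dB re 1 m^-1; NaN marks missing samples.
    """

    frequency_khz: int
    ping_times: np.ndarray
    latitudes: np.ndarray
    longitudes: np.ndarray
    depth_m: np.ndarray
    sv_db: np.ndarray

    def __post_init__(self):
        self.ping_times = np.asarray(self.ping_times, dtype="datetime64[ns]")
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.sv_db = np.asarray(self.sv_db, dtype=float)
        if int(self.frequency_khz) not in SUPPORTED_FREQUENCIES_KHZ:
            raise ValueError(
                f"unsupported frequency {self.frequency_khz} kHz; "
                f"supported: {SUPPORTED_FREQUENCIES_KHZ}"
            )
        self.frequency_khz = int(self.frequency_khz)
        n_pings, n_depths = len(self.ping_times), len(self.depth_m)
        if self.sv_db.shape != (n_pings, n_depths):
            raise ValueError(
                f"sv_db shape {self.sv_db.shape} != ({n_pings}, {n_depths})"
            )
        for name in ("latitudes", "longitudes"):
            if len(getattr(self, name)) != n_pings:
                raise ValueError(f"{name} length != n_pings")
        if n_pings > 1 and not np.all(np.diff(self.ping_times).astype(np.int64) > 0):
            raise ValueError("ping_times must be strictly increasing")
        if n_depths > 1:
            dz = np.diff(self.depth_m)
            if np.ptp(dz) > _DEPTH_SPACING_TOL or dz[0] <= 0:
                raise ValueError("depth grid must be uniform and increasing")
        if self.depth_m.size and (self.depth_m[0] < 0 or self.depth_m[-1] > 750):
            raise ValueError("depths must lie within [0, 750] m")
        if np.any(np.abs(self.latitudes) > 90) or np.any(np.abs(self.longitudes) > 180):
            raise ValueError("latitude/longitude out of range")

    # -- basic geometry -------------------------------------------------
    @property
    def n_pings(self) -> int:
        return len(self.ping_times)

    @property
    def n_depths(self) -> int:
        return len(self.depth_m)

    @property
    def depth_spacing(self) -> float:
        if self.n_depths < 2:
            raise ValueError("need >= 2 depth samples for a spacing")
        return float(self.depth_m[1] - self.depth_m[0])

    def copy(self) -> "Echogram":
        return replace(self, sv_db=self.sv_db.copy())

    def sv_linear(self) -> np.ndarray:
        """Linear-domain ``s_v`` matrix (NaN preserved)."""
        return db_to_linear(self.sv_db)

    def valid(self) -> np.ndarray:
        """Boolean matrix of non-missing samples."""
        return np.isfinite(self.sv_db)


@dataclass
class SampleMask:
    """Shape-matched boolean annotation of an echogram, with a reason tag."""

    mask: np.ndarray
    reason: str = "background"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.reason not in MASK_REASONS:
            raise ValueError(f"unknown mask reason {self.reason!r}")

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())


def apply_mask(echogram: Echogram, mask: SampleMask) -> Echogram:
    """Return a copy with masked samples set to missing; all others unchanged."""
    if mask.mask.shape != echogram.sv_db.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} != echogram shape {echogram.sv_db.shape}"
        )
    out = echogram.copy()
    out.sv_db[mask.mask] = np.nan
    return out


def _bin_edges(centres: np.ndarray) -> np.ndarray:
    spacing = centres[1] - centres[0] if len(centres) > 1 else 1.0
    return np.concatenate([centres - spacing / 2.0, [centres[-1] + spacing / 2.0]])


def resample_vertical(
    echogram: Echogram,
    n_bins: int,
    depth_range: tuple[float, float] = (0.0, 750.0),
) -> Echogram:
    """Rebin an echogram onto ``n_bins`` uniform depth bins over ``depth_range``.

    Each output sample is the mean of the covered source samples computed
    in the linear domain (overlap-fraction weighted), then converted back
    to dB.  Output bins with no valid covered source sample are missing.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if echogram.n_pings == 0 or echogram.n_depths == 0:
        raise ValueError("cannot resample an empty echogram")
    lo, hi = map(float, depth_range)
    src_edges = _bin_edges(echogram.depth_m)
    if src_edges[-1] <= lo or src_edges[0] >= hi:
        raise ValueError("source depth grid does not overlap the target range")

    tgt_edges = np.linspace(lo, hi, n_bins + 1)
    # overlap length of each (source bin, target bin) pair
    left = np.maximum(src_edges[:-1, None], tgt_edges[None, :-1])
    right = np.minimum(src_edges[1:, None], tgt_edges[None, 1:])
    weights = np.clip(right - left, 0.0, None)  # (n_src, n_tgt)

    lin = echogram.sv_linear()
    valid = np.isfinite(lin).astype(float)
    num = np.where(np.isfinite(lin), lin, 0.0) @ weights
    den = valid @ weights
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_lin = np.where(den > 0, num / den, np.nan)
    sv_db = np.where(
        np.isfinite(mean_lin) & (mean_lin > 0),
        10.0 * np.log10(np.where(mean_lin > 0, mean_lin, 1.0)),
        np.nan,
    )
    centres = 0.5 * (tgt_edges[:-1] + tgt_edges[1:])
    return replace(echogram, depth_m=centres, sv_db=sv_db)
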