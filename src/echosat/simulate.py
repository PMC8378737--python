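"""Synthetic survey generator with known ground truth.

Emulates a multi-year acoustic transect survey off a north-south coast:
east-west transects stacked south to north, pinging at 1.1 s intervals;
diel-vertically-migrating scattering layers (shallow at night, deep by
day) whose per-frequency strength follows the configured frequency
response; a sloping seafloor echo; TVG-shaped background noise; and
injected impulsive spikes, transient blobs, and attenuated ping runs
with exported ground-truth masks.  Satellite fields are generated on a
4 km (1/24 degree) grid with a configurable link between shallow-layer
biomass and the ocean-colour variables, so the information content of
the satellite covariates is a controlled quantity.

Every artifact is a pure function of :class:`SimConfig` (seed
included).  The biomass anomaly field is a sum of latitudinal harmonics
with year-specific phases, analytically detrended so it shares no
linear-latitude structure with the satellite fields' deterministic
gradients.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .echogram import Echogram
from .filters import VALID_MAX_DEPTH_M
from .integration import (
    DEPTH_LAYERS,
    NASC_SCALE,
    along_track_bins,
    is_daytime,
    solar_elevation,
)
from .matchup import (
    SATELLITE_VARIABLES,
    BathymetryGrid,
    SatelliteScene,
    assemble_features,
    merge_terra_aqua,
)

DEG_KM = 111.19  # km per degree of latitude on the 6371 km sphere


@dataclass(frozen=True)
class LayerSpec:
    """One scattering layer: Gaussian in depth, migrating day/night."""

    name: str
    day_depth_m: float
    night_depth_m: float
    sigma_m: float
    strength_db: dict  # frequency_khz -> peak S_V at unit biomass
    offshore_deepening_m_per_km: float = 0.0
    biomass_linked: bool = False


@dataclass(frozen=True)
class AnomalyScenario:
    """Covariate-shift test year: elevated biomass, shifted SST/chl."""

    biomass_log_shift: float = 1.5
    sst_shift_c: float = 2.0
    chl_log_shift: float = -0.3


def _default_layers() -> tuple[LayerSpec, ...]:
    return (
        LayerSpec(
            name="krill",
            day_depth_m=70.0,
            night_depth_m=20.0,
            sigma_m=10.0,
            strength_db={18: -84.0, 38: -80.0, 70: -74.0, 120: -68.0, 200: -66.0},
            offshore_deepening_m_per_km=0.3,
            biomass_linked=True,
        ),
        LayerSpec(
            name="fish",
            day_depth_m=340.0,
            night_depth_m=250.0,
            sigma_m=30.0,
            strength_db={18: -72.0, 38: -70.0, 70: -76.0, 120: -82.0, 200: -88.0},
            offshore_deepening_m_per_km=1.0,
            biomass_linked=False,
        ),
    )


@dataclass
class SimConfig:
    """All knobs of the synthetic survey; see module docstring."""

    seed: int = 0
    years: tuple = (2011, 2012, 2013, 2015)
    # cruise geometry
    n_transects: int = 10
    lat_span: tuple = (44.0, 47.6)
    coast_lon: float = -124.0
    transect_length_km: float = 28.0
    transect_gap_min: float = 30.0
    vessel_speed_mps: float = 5.1
    ping_interval_s: float = 1.1
    start_month_day: tuple = (6, 1)
    start_hour_utc: float = 0.0
    # echogram grid
    depth_range_m: tuple = (0.0, 750.0)
    n_depth: int = 1000
    frequencies: tuple = (18, 38, 70, 120, 200)
    # scattering
    layers: tuple = field(default_factory=_default_layers)
    diffuse_sv_db: float = -88.0
    dvm_elev_width_deg: float = 3.0
    # biomass anomaly field (log scale)
    biomass_amplitudes: tuple = (0.45, 0.35, 0.25)
    biomass_wavelengths_deg: tuple = (0.5, 0.3, 0.2)
    biomass_lon_amplitude: float = 0.2
    biomass_lon_wavelength_deg: float = 0.4
    # seafloor
    shelf_depth_m: float = 110.0
    slope_m_per_km: float = 22.0
    bottom_peak_db: float = -15.0
    bottom_sigma_m: float = 1.0
    bottom_tail_start_db: float = -18.0
    bottom_tail_decay_db_per_m: float = 1.5
    # noise and artifacts
    noise_1m_db: dict = field(
        default_factory=lambda: {18: -162.0, 38: -158.0, 70: -150.0, 120: -145.0, 200: -140.0}
    )
    noise_sd_db: float = 0.0
    impulsive_rate: float = 2e-4
    impulsive_gain_db: float = 15.0
    transient_rate_per_ping: float = 0.01
    transient_size: tuple = (2, 15)  # pings x samples
    transient_gain_db: float = 15.0
    attenuated_rate: float = 0.01
    attenuated_deficit_db: float = 20.0
    # satellite
    grid_spacing_deg: float = 1.0 / 24.0
    satellite_link_strength: float = 1.0
    satellite_noise_sd: float = 0.15
    satellite_missing_fraction: float = 0.15
    chl0_mg_m3: float = 0.8
    sst0_c: float = 14.0
    sst_lat_gradient_c_per_deg: float = -1.2
    # feature-table route
    obs_noise_sd_log: float = 0.5
    anomaly_year: int | None = None
    anomaly: AnomalyScenario = field(default_factory=AnomalyScenario)

    def depth_grid(self) -> np.ndarray:
        lo, hi = self.depth_range_m
        dz = (hi - lo) / self.n_depth
        return lo + dz * (np.arange(self.n_depth) + 0.5)


def _rng(config: SimConfig, *tags) -> np.random.Generator:
    words = [config.seed & 0x7FFFFFFF]
    for t in tags:
        words.append(t if isinstance(t, int) else zlib.crc32(str(t).encode()))
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# cruise track


@dataclass
class Track:
    """Per-year vessel track at ping resolution."""

    year: int
    times: np.ndarray
    latitudes: np.ndarray
    longitudes: np.ndarray

    @property
    def n_pings(self) -> int:
        return len(self.times)


def simulate_cruise(config: SimConfig) -> dict[int, Track]:
    """East-west transects stacked south to north, repeated per year.

    Timestamps advance at the ping interval along each transect, with a
    transit gap between transects; per-year latitude jitter makes the
    cruise tracks approximately (not exactly) overlapping.
    """
    if config.n_transects < 1:
        raise ValueError("need at least one transect")
    lat_lo, lat_hi = config.lat_span
    n_pings_t = int(np.ceil(config.transect_length_km * 1000.0
                            / (config.vessel_speed_mps * config.ping_interval_s)))
    tracks = {}
    for year in config.years:
        rng = _rng(config, year, "track")
        month, day = config.start_month_day
        t0 = np.datetime64(f"{year}-{month:02d}-{day:02d}T00:00:00", "ns") + (
            np.timedelta64(int(config.start_hour_utc * 3600e9), "ns")
        )
        times, lats, lons = [], [], []
        clock = t0
        for i in range(config.n_transects):
            base_lat = lat_lo + (i + 0.5) * (lat_hi - lat_lo) / config.n_transects
            base_lat += rng.normal(0.0, 0.03)
            s = np.arange(n_pings_t) * config.vessel_speed_mps * config.ping_interval_s
            if i % 2 == 1:
                s = s[::-1]  # eastbound return leg
            # gentle wiggle; amplitude scales with transect length so the
            # heading deviation (hence ping spacing) stays small
            drift = (4e-4 * config.transect_length_km) * np.sin(
                2.0 * np.pi * s / (config.transect_length_km * 1000.0)
                + rng.uniform(0, 2 * np.pi)
            )
            lat = base_lat + drift
            lon = config.coast_lon - 0.02 - (s / 1000.0) / (DEG_KM * np.cos(np.radians(base_lat)))
            t = clock + (np.arange(n_pings_t) * config.ping_interval_s * 1e9).astype(
                "timedelta64[ns]"
            )
            times.append(t)
            lats.append(lat)
            lons.append(lon)
            clock = t[-1] + np.timedelta64(int(config.transect_gap_min * 60e9), "ns")
        tracks[year] = Track(
            year=year,
            times=np.concatenate(times),
            latitudes=np.concatenate(lats),
            longitudes=np.concatenate(lons),
        )
    return tracks


# ---------------------------------------------------------------------------
# ground-truth fields


def _biomass_phases(config: SimConfig, year: int):
    rng = _rng(config, year, "biomass")
    lat_phases = rng.uniform(0, 2 * np.pi, size=len(config.biomass_amplitudes))
    lon_phase = rng.uniform(0, 2 * np.pi)
    # detrend the latitudinal harmonics over the padded span
    lat_ref = np.linspace(config.lat_span[0] - 0.3, config.lat_span[1] + 0.3, 2001)
    raw = np.zeros_like(lat_ref)
    for a, lam, ph in zip(
        config.biomass_amplitudes, config.biomass_wavelengths_deg, lat_phases
    ):
        raw += a * np.sin(2 * np.pi * lat_ref / lam + ph)
    slope, intercept = np.polyfit(lat_ref, raw, 1)
    return lat_phases, lon_phase, slope, intercept


def log_biomass(config: SimConfig, latitudes, longitudes, year: int) -> np.ndarray:
    """Log-scale biomass anomaly of the shallow (linked) layer.

    Zero-mean, detrended in latitude; the anomaly year adds the
    configured shift.
    """
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    lat_phases, lon_phase, slope, intercept = _biomass_phases(config, year)
    out = np.zeros_like(lat)
    for a, lam, ph in zip(
        config.biomass_amplitudes, config.biomass_wavelengths_deg, lat_phases
    ):
        out += a * np.sin(2 * np.pi * lat / lam + ph)
    out -= slope * lat + intercept
    out += config.biomass_lon_amplitude * np.sin(
        2 * np.pi * lon / config.biomass_lon_wavelength_deg + lon_phase
    )
    if config.anomaly_year is not None and year == config.anomaly_year:
        out = out + config.anomaly.biomass_log_shift
    return out


def bathymetry_m(config: SimConfig, latitudes, longitudes) -> np.ndarray:
    """Seafloor depth (m, positive down): shelf deepening offshore."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    offshore_km = np.clip(
        (config.coast_lon - lon) * DEG_KM * np.cos(np.radians(lat)), 0.0, None
    )
    return config.shelf_depth_m + config.slope_m_per_km * offshore_km


def make_coastline(config: SimConfig) -> list[np.ndarray]:
    """A meridian coastline polyline at the coast longitude."""
    lo, hi = config.lat_span
    return [
        np.array([[lo - 1.0, config.coast_lon], [hi + 1.0, config.coast_lon]])
    ]


def make_bathymetry_grid(config: SimConfig, spacing_deg: float = 0.05) -> BathymetryGrid:
    lo, hi = config.lat_span
    lats = np.arange(lo - 0.5, hi + 0.5, spacing_deg)
    lon_extent = config.transect_length_km / (DEG_KM * np.cos(np.radians(hi))) + 0.3
    lons = np.arange(config.coast_lon - lon_extent, config.coast_lon + 0.1, spacing_deg)
    grid = bathymetry_m(config, lats[:, None], lons[None, :])
    return BathymetryGrid(lats, lons, grid)


def _layer_centre(config, layer, elev_deg, offshore_km):
    """Layer centre depth per ping: logistic day/night transition."""
    frac_day = 1.0 / (1.0 + np.exp(-np.asarray(elev_deg) / config.dvm_elev_width_deg))
    c = layer.night_depth_m + (layer.day_depth_m - layer.night_depth_m) * frac_day
    return c + layer.offshore_deepening_m_per_km * offshore_km


# ---------------------------------------------------------------------------
# echograms


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    clean_sv_db: dict
    noise_sv_db: dict
    impulsive: dict
    transient: dict
    attenuated: dict
    eligible: dict
    bathymetry_m: np.ndarray
    log_biomass: np.ndarray


def _clean_field(config, track, freq, z, elev, offshore_km, logb, bottom):
    """Clean (noise- and artifact-free) linear s_v field for one frequency."""
    clean = np.zeros((track.n_pings, z.size))
    above_bottom = z[None, :] < bottom[:, None]
    clean += 10 ** (config.diffuse_sv_db / 10.0) * above_bottom
    for layer in config.layers:
        if freq not in layer.strength_db:
            continue
        amp = 10 ** (layer.strength_db[freq] / 10.0)
        if layer.biomass_linked:
            amp = amp * np.exp(logb)
        else:
            amp = amp * np.ones(track.n_pings)
        c = _layer_centre(config, layer, elev, offshore_km)
        shape = np.exp(-((z[None, :] - c[:, None]) ** 2) / (2.0 * layer.sigma_m**2))
        clean += amp[:, None] * shape * above_bottom
    # seafloor echo plus decaying sub-bottom reverberation tail (only
    # where the bottom is inside the recorded range)
    in_range = bottom < z[-1] + 5 * config.bottom_sigma_m
    if in_range.any():
        dz = z[None, :] - bottom[:, None]
        echo = 10 ** (config.bottom_peak_db / 10.0) * np.exp(
            -(dz**2) / (2.0 * config.bottom_sigma_m**2)
        )
        tail_db = config.bottom_tail_start_db - config.bottom_tail_decay_db_per_m * dz
        tail = np.where(dz > 0, 10 ** (tail_db / 10.0), 0.0)
        clean += np.where(in_range[:, None], np.maximum(echo, tail), 0.0)
    return clean


def simulate_echograms(
    config: SimConfig, track: Track
) -> tuple[dict[int, Echogram], GroundTruth]:
    """Render per-frequency echograms for one year's track.

    Returns the echograms (signal + noise + injected artifacts) and the
    ground truth: clean fields, the noise field, the injected artifact
    masks, per-ping bathymetry, and the biomass anomaly along the track.
    """
    from .filters import ABSORPTION_DB_PER_M

    z = config.depth_grid()
    elev = np.asarray(solar_elevation(track.times, track.latitudes, track.longitudes))
    offshore_km = np.clip(
        (config.coast_lon - track.longitudes) * DEG_KM * np.cos(np.radians(track.latitudes)),
        0.0,
        None,
    )
    logb = log_biomass(config, track.latitudes, track.longitudes, track.year)
    bottom = bathymetry_m(config, track.latitudes, track.longitudes)

    echograms, truth_clean, truth_noise = {}, {}, {}
    truth_imp, truth_tra, truth_att, truth_elig = {}, {}, {}, {}
    n = track.n_pings
    for freq in config.frequencies:
        rng = _rng(config, track.year, freq, "artifacts")
        clean = _clean_field(config, track, freq, z, elev, offshore_km, logb, bottom)
        r = np.maximum(z, 1.0)
        noise_db = (
            config.noise_1m_db[freq]
            + 20.0 * np.log10(r)
            + 2.0 * ABSORPTION_DB_PER_M[freq] * r
        )
        noise_db = np.broadcast_to(noise_db[None, :], clean.shape).copy()
        if config.noise_sd_db > 0:
            noise_db += rng.normal(0.0, config.noise_sd_db, size=clean.shape)
        noise_lin = 10 ** (noise_db / 10.0)
        sv = 10.0 * np.log10(clean + noise_lin)

        with np.errstate(divide="ignore"):
            clean_db = 10.0 * np.log10(np.where(clean > 0, clean, 1e-300))
        snr = clean_db - noise_db
        elig = (
            (snr >= 15.0)
            & (z[None, :] > 11.0)
            & (z[None, :] < VALID_MAX_DEPTH_M[freq] - 1.0)
            & (z[None, :] < bottom[:, None] - 20.0)  # clear of the bottom echo tail
        )

        # attenuated runs of 2-3 consecutive pings
        att_mask = np.zeros(n, dtype=bool)
        n_att = rng.binomial(n, config.attenuated_rate)
        guard = np.zeros(n, dtype=bool)
        placed = 0
        attempts = 0
        while placed < n_att and attempts < 20 * max(n_att, 1):
            attempts += 1
            run = int(rng.integers(2, 4))
            start = int(rng.integers(3, max(4, n - run - 3)))
            lo, hi = max(0, start - 7), min(n, start + run + 7)
            if guard[lo:hi].any():
                continue
            att_mask[start : start + run] = True
            guard[lo:hi] = True
            placed += run
        # transient blobs (kept off attenuated pings)
        bp, bs = config.transient_size
        tra_mask = np.zeros((n, z.size), dtype=bool)
        n_blobs = rng.binomial(n, config.transient_rate_per_ping)
        blob_ping_guard = np.zeros(n, dtype=bool)
        for _ in range(n_blobs):
            for _try in range(20):
                p = int(rng.integers(0, n - bp))
                if att_mask[max(0, p - 1) : p + bp + 1].any() or blob_ping_guard[
                    max(0, p - 3) : p + bp + 3
                ].any():
                    continue
                ok_cols = elig[p : p + bp].all(axis=0)
                run_ok = np.convolve(ok_cols.astype(int), np.ones(bs, dtype=int), "valid") == bs
                starts = np.flatnonzero(run_ok)
                if starts.size == 0:
                    continue
                j = int(rng.choice(starts))
                tra_mask[p : p + bp, j : j + bs] = True
                blob_ping_guard[p : p + bp] = True
                break
        # impulsive single-sample spikes
        elig_imp = elig.copy()
        att_halo = att_mask.copy()  # spike tests compare to neighbour pings
        att_halo[:-1] |= att_mask[1:]
        att_halo[1:] |= att_mask[:-1]
        elig_imp[att_halo] = False
        dilated = tra_mask.copy()  # keep spikes off blobs and their 1-cell halo
        dilated[:-1] |= tra_mask[1:]
        dilated[1:] |= tra_mask[:-1]
        dilated[:, :-1] |= dilated[:, 1:].copy()
        dilated[:, 1:] |= dilated[:, :-1].copy()
        elig_imp &= ~dilated
        flat_elig = np.flatnonzero(elig_imp)
        n_spikes = rng.binomial(flat_elig.size, config.impulsive_rate)
        imp_mask = np.zeros_like(tra_mask)
        if n_spikes > 0 and flat_elig.size:
            chosen = rng.choice(flat_elig, size=min(n_spikes, flat_elig.size), replace=False)
            pi, si = np.unravel_index(chosen, imp_mask.shape)
            taken = set()
            for p, s in zip(pi, si):
                if (p - 1, s) in taken or (p + 1, s) in taken:
                    continue
                taken.add((p, s))
                imp_mask[p, s] = True

        sv = sv + config.transient_gain_db * tra_mask
        sv = sv + config.impulsive_gain_db * imp_mask
        sv = sv - config.attenuated_deficit_db * att_mask[:, None]

        echograms[freq] = Echogram(
            frequency_khz=freq,
            ping_times=track.times,
            latitudes=track.latitudes,
            longitudes=track.longitudes,
            depth_m=z,
            sv_db=sv,
        )
        truth_clean[freq] = clean_db
        truth_noise[freq] = noise_db
        truth_imp[freq] = imp_mask
        truth_tra[freq] = tra_mask
        att_full = np.zeros_like(tra_mask)
        att_full[att_mask] = True
        truth_att[freq] = att_full
        truth_elig[freq] = elig

    truth = GroundTruth(
        clean_sv_db=truth_clean,
        noise_sv_db=truth_noise,
        impulsive=truth_imp,
        transient=truth_tra,
        attenuated=truth_att,
        eligible=truth_elig,
        bathymetry_m=bottom,
        log_biomass=logb,
    )
    return echograms, truth


# ---------------------------------------------------------------------------
# satellite scenes


def _satellite_grid(config: SimConfig):
    lo, hi = config.lat_span
    lats = np.arange(lo - 0.2, hi + 0.2, config.grid_spacing_deg)
    lon_extent = config.transect_length_km / (DEG_KM * np.cos(np.radians(hi))) + 0.2
    lons = np.arange(
        config.coast_lon - lon_extent, config.coast_lon + 0.1, config.grid_spacing_deg
    )
    return lats, lons


def simulate_satellite(
    config: SimConfig, year: int, dates: list[dt.date]
) -> tuple[dict[str, list[SatelliteScene]], dict]:
    """Daily Terra/Aqua scenes of the four variables for the given dates.

    Each field is a deterministic function of latitude and of the
    shallow-layer biomass anomaly (scaled by the configured link
    strength) plus Gaussian noise and random missing cells.  Returns the
    scenes and a ground-truth dict with the grid and biomass field.
    """
    lats, lons = _satellite_grid(config)
    lat2, lon2 = np.meshgrid(lats, lons, indexing="ij")
    logb = log_biomass(config, lat2, lon2, year)
    mid = 0.5 * (config.lat_span[0] + config.lat_span[1])
    beta = config.satellite_link_strength
    anomaly = config.anomaly_year is not None and year == config.anomaly_year

    base = {
        "chlor_a": np.exp(
            np.log(config.chl0_mg_m3)
            + 0.8 * beta * logb
            + (config.anomaly.chl_log_shift if anomaly else 0.0)
        ),
        "nflh": 0.15 + 0.05 * beta * logb,
        "poc": np.exp(np.log(100.0) + 0.5 * beta * logb),
        "sst": (
            config.sst0_c
            + config.sst_lat_gradient_c_per_deg * (lat2 - mid)
            + (config.anomaly.sst_shift_c if anomaly else 0.0)
        ),
    }
    noise_scale = {
        "chlor_a": ("log", config.satellite_noise_sd),
        "nflh": ("abs", 0.02),
        "poc": ("log", config.satellite_noise_sd),
        "sst": ("abs", 0.3),
    }
    scenes: dict[str, list[SatelliteScene]] = {v: [] for v in SATELLITE_VARIABLES}
    for date in dates:
        for platform in ("terra", "aqua"):
            rng = _rng(config, year, str(date), platform)
            for var in SATELLITE_VARIABLES:
                kind, sd = noise_scale[var]
                eps = rng.normal(0.0, sd, size=logb.shape)
                values = base[var] * np.exp(eps) if kind == "log" else base[var] + eps
                if config.satellite_missing_fraction > 0:
                    gone = rng.random(logb.shape) < config.satellite_missing_fraction
                    values = np.where(gone, np.nan, values)
                scenes[var].append(
                    SatelliteScene(var, date, platform, lats, lons, values)
                )
    truth = {"lats": lats, "lons": lons, "log_biomass": logb}
    return scenes, truth


def merged_daily_scenes(
    scenes: dict[str, list[SatelliteScene]]
) -> dict[str, list[SatelliteScene]]:
    """Collapse per-platform scenes into one merged scene per day."""
    out: dict[str, list[SatelliteScene]] = {}
    for var, lst in scenes.items():
        by_date: dict[dt.date, list[SatelliteScene]] = {}
        for s in lst:
            by_date.setdefault(s.date, []).append(s)
        out[var] = [merge_terra_aqua(group) for _, group in sorted(by_date.items())]
    return out


# ---------------------------------------------------------------------------
# analytic NASC truth and the desk-scale feature route


def true_layer_nasc(
    config: SimConfig,
    freq: int,
    layer_range: tuple[float, float],
    latitude: float,
    longitude: float,
    time,
    year: int,
) -> tuple[float, float]:
    """Closed-form NASC of the clean field over a depth layer.

    Gaussian layers integrate to ``amp * sigma * sqrt(2 pi)`` times the
    normal-CDF overlap with the layer; the integral is truncated at the
    bottom-exclusion depth (bottom - 5 m).  Returns (nasc, covered
    fraction of the layer).
    """
    lo, hi = layer_range
    elev = solar_elevation(time, latitude, longitude)
    offshore_km = max(
        (config.coast_lon - longitude) * DEG_KM * np.cos(np.radians(latitude)), 0.0
    )
    logb = float(log_biomass(config, np.array([latitude]), np.array([longitude]), year)[0])
    bottom = float(bathymetry_m(config, np.array([latitude]), np.array([longitude]))[0])
    top_excl = bottom - 5.0
    hi_eff = min(hi, top_excl)
    if hi_eff <= lo:
        return float("nan"), 0.0
    covered = (hi_eff - lo) / (hi - lo)
    integral = 10 ** (config.diffuse_sv_db / 10.0) * (hi_eff - lo)
    for layer in config.layers:
        if freq not in layer.strength_db:
            continue
        amp = 10 ** (layer.strength_db[freq] / 10.0)
        if layer.biomass_linked:
            amp *= np.exp(logb)
        c = float(_layer_centre(config, layer, elev, offshore_km))
        overlap = ndtr((hi_eff - c) / layer.sigma_m) - ndtr((lo - c) / layer.sigma_m)
        integral += amp * layer.sigma_m * np.sqrt(2.0 * np.pi) * overlap
    # mean-of-covered scaled to the full layer thickness (pipeline convention)
    nasc = NASC_SCALE * integral / covered if covered > 0 else float("nan")
    return float(nasc), float(covered)


def simulate_nasc_table(config: SimConfig, years=None) -> pd.DataFrame:
    """NASC cells from the analytic ground truth plus observation noise.

    The desk-scale stand-in for rendering, denoising and integrating
    ping-level echograms: tracks are binned into 4 km cells and each
    (frequency, layer) cell receives its closed-form clean-field NASC
    times a lognormal observation error.
    """
    years = list(config.years if years is None else years)
    tracks = simulate_cruise(config)
    rows = []
    for year in years:
        track = tracks[year]
        bins = along_track_bins(track.latitudes, track.longitudes)
        rng = _rng(config, year, "obs-noise")
        for b in np.unique(bins):
            sel = np.flatnonzero(bins == b)
            mid = sel[len(sel) // 2]
            t, la, lo_ = track.times[mid], track.latitudes[mid], track.longitudes[mid]
            day = bool(np.asarray(is_daytime(t, la, lo_)).ravel()[0])
            date = pd.Timestamp(t).date()
            for freq in config.frequencies:
                cutoff = VALID_MAX_DEPTH_M[freq]
                for name, (top, bot) in DEPTH_LAYERS.items():
                    if bot > cutoff:
                        continue
                    nasc, covered = true_layer_nasc(
                        config, freq, (top, bot), la, lo_, t, year
                    )
                    if covered < 0.1 or not np.isfinite(nasc):
                        nasc = float("nan")
                    else:
                        nasc *= float(np.exp(rng.normal(0.0, config.obs_noise_sd_log)))
                    rows.append(
                        {
                            "cruise_id": f"SIM{year}",
                            "year": year,
                            "bin_index": int(b),
                            "frequency_khz": freq,
                            "depth_layer": name,
                            "mid_latitude": float(la),
                            "mid_longitude": float(lo_),
                            "date": date,
                            "daytime": day,
                            "nasc": nasc,
                            "valid_fraction": float(covered),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_feature_table(config: SimConfig, years=None):
    """Full desk-scale feature table: NASC cells + satellite matchup.

    Returns (features, counters-per-year dict).
    """
    years = list(config.years if years is None else years)
    nasc = simulate_nasc_table(config, years)
    coastline = make_coastline(config)
    bathy = make_bathymetry_grid(config)
    frames, counters = [], {}
    for year in years:
        cells = nasc[nasc["year"] == year].reset_index(drop=True)
        dates = sorted(set(cells["date"]))
        window_dates = sorted(
            {d + dt.timedelta(days=o) for d in dates for o in range(-3, 4)}
        )
        scenes, _ = simulate_satellite(config, year, window_dates)
        daily = merged_daily_scenes(scenes)
        feats, ctr = assemble_features(cells, daily, coastline, bathy)
        frames.append(feats)
        counters[year] = ctr
    features = pd.concat(frames, ignore_index=True)
    return features, counters
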