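"""Acoustic denoising: background, impulsive, transient, attenuated, validity.

Five stages, applied in a fixed order:

1. background-noise subtraction with an SNR threshold (De Robertis-style
   minimum-cell noise estimate under time-varied gain, TVG),
2. impulsive-noise ("spike") masking against the two adjacent pings,
3. transient-noise adjustment against a 5-ping x 9-sample context window,
4. attenuated-ping masking against 3 pings of context either side,
5. frequency-depth validity cutoffs.

Each stage is a scikit-learn-style stateless transformer over
:class:`~echosat.echogram.Echogram` objects: ``transform`` returns the
cleaned echogram and stores the boolean :class:`SampleMask` of what it
flagged in ``mask_``.  The module-level functions are thin wrappers.
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .echogram import Echogram, SampleMask, apply_mask, db_to_linear

logger = logging.getLogger(__name__)


@contextmanager
def _quiet_allnan():
    """Silence numpy's all-NaN-slice RuntimeWarning (empty cells are expected)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield

#: Seawater absorption defaults, dB per metre (temperate surface water).
ABSORPTION_DB_PER_M = {18: 0.0026, 38: 0.0098, 70: 0.020, 120: 0.038, 200: 0.053}

#: Maximum depth (m) at which each frequency yields usable data.
VALID_MAX_DEPTH_M = {18: 750.0, 38: 750.0, 70: 500.0, 120: 275.0, 200: 150.0}

#: Data collection starts this far below the surface (bubble/ringdown zone).
MIN_VALID_DEPTH_M = 10.0


class _EchogramFilter(BaseEstimator):
    """Base class: stateless transformers with a post-transform ``mask_``."""

    def fit(self, echogram: Echogram, y=None):  # noqa: ARG002 - sklearn API
        return self

    def fit_transform(self, echogram: Echogram, y=None) -> Echogram:
        return self.fit(echogram).transform(echogram)


class BackgroundNoiseFilter(_EchogramFilter):
    """Estimate and subtract range-dependent background noise; mask low SNR.

    The noise estimate removes TVG (``20 log10 r + 2 a r``), averages
    power in cells of ``cell_pings x cell_samples`` (linear domain),
    takes the minimum over depth cells per ping block, and caps the
    result at ``max_noise_db``.  Noise is re-amplified by TVG and
    subtracted from the signal in the linear domain; samples whose
    post-subtraction SNR falls below ``snr_threshold_db`` are masked.
    """

    def __init__(
        self,
        snr_threshold_db: float = 10.0,
        cell_pings: int = 10,
        cell_samples: int = 20,
        absorption_db_per_m: float | None = None,
        max_noise_db: float = -125.0,
    ):
        self.snr_threshold_db = snr_threshold_db
        self.cell_pings = cell_pings
        self.cell_samples = cell_samples
        self.absorption_db_per_m = absorption_db_per_m
        self.max_noise_db = max_noise_db

    def transform(self, echogram: Echogram) -> Echogram:
        if (
            echogram.n_pings < self.cell_pings
            or echogram.n_depths < self.cell_samples
        ):
            raise ValueError("echogram smaller than one noise-averaging cell")
        alpha = self.absorption_db_per_m
        if alpha is None:
            alpha = ABSORPTION_DB_PER_M[echogram.frequency_khz]

        r = np.maximum(echogram.depth_m, 1.0)
        tvg = 20.0 * np.log10(r) + 2.0 * alpha * r  # (n_depths,)
        power_db = echogram.sv_db - tvg[None, :]
        power_lin = db_to_linear(power_db)

        n_pings, n_depths = power_lin.shape
        pb = -(-n_pings // self.cell_pings)  # ping blocks (ceil)
        db_ = -(-n_depths // self.cell_samples)  # depth cells
        cell_mean = np.full((pb, db_), np.nan)
        for i in range(pb):
            rows = power_lin[i * self.cell_pings : (i + 1) * self.cell_pings]
            for j in range(db_):
                cell = rows[:, j * self.cell_samples : (j + 1) * self.cell_samples]
                if np.isfinite(cell).any():
                    cell_mean[i, j] = np.nanmean(cell)
        with np.errstate(divide="ignore", invalid="ignore"), _quiet_allnan():
            cell_db = 10.0 * np.log10(cell_mean)
            noise_db_block = np.nanmin(cell_db, axis=1)  # per ping block
        noise_db_block = np.minimum(noise_db_block, self.max_noise_db)

        block_idx = np.arange(n_pings) // self.cell_pings
        noise_db = noise_db_block[block_idx][:, None] + tvg[None, :]
        self.noise_db_ = noise_db

        sv_lin = echogram.sv_linear()
        noise_lin = db_to_linear(noise_db)
        corr_lin = sv_lin - noise_lin
        with np.errstate(divide="ignore", invalid="ignore"):
            corr_db = 10.0 * np.log10(np.where(corr_lin > 0, corr_lin, np.nan))
        snr = corr_db - noise_db
        newly_bad = np.isfinite(echogram.sv_db) & ~(snr >= self.snr_threshold_db)
        corr_db = np.where(newly_bad, np.nan, corr_db)

        out = echogram.copy()
        out.sv_db = np.where(np.isfinite(echogram.sv_db), corr_db, np.nan)
        self.mask_ = SampleMask(newly_bad, reason="background")
        return out


class ImpulsiveNoiseFilter(_EchogramFilter):
    """Mask single-ping spikes: samples deviating by >= ``threshold_db`` in
    the same direction from both same-depth neighbours (edge pings are
    compared to their single neighbour)."""

    def __init__(self, threshold_db: float = 10.0):
        self.threshold_db = threshold_db

    def transform(self, echogram: Echogram) -> Echogram:
        if echogram.n_pings < 3:
            raise ValueError("impulsive-noise test needs >= 3 pings")
        sv = echogram.sv_db
        thr = self.threshold_db
        d_prev = np.full_like(sv, np.nan)
        d_next = np.full_like(sv, np.nan)
        d_prev[1:] = sv[1:] - sv[:-1]
        d_next[:-1] = sv[:-1] - sv[1:]
        with np.errstate(invalid="ignore"):
            up = (d_prev >= thr) & (d_next >= thr)
            dn = (d_prev <= -thr) & (d_next <= -thr)
            # edge pings: single-neighbour one-sided test
            up[0] = np.abs(d_next[0]) >= thr
            dn[0] = False
            up[-1] |= np.abs(d_prev[-1]) >= thr
            dn[-1] = False
        mask = (up | dn) & np.isfinite(sv)
        self.mask_ = SampleMask(mask, reason="impulsive")
        return apply_mask(echogram, self.mask_)


class TransientNoiseFilter(_EchogramFilter):
    """Adjust samples more than ``threshold_db`` above the context statistic
    (default median) of the surrounding ``window_pings x window_samples``
    window, excluding the centre.  Flagged samples are *replaced* by the
    context value, not removed; windows are truncated at edges."""

    def __init__(
        self,
        threshold_db: float = 10.0,
        window_pings: int = 5,
        window_samples: int = 9,
        context_percentile: float = 50.0,
        chunk_pings: int = 256,
    ):
        self.threshold_db = threshold_db
        self.window_pings = window_pings
        self.window_samples = window_samples
        self.context_percentile = context_percentile
        self.chunk_pings = chunk_pings

    def transform(self, echogram: Echogram) -> Echogram:
        wp, ws = self.window_pings, self.window_samples
        if echogram.n_pings < wp or echogram.n_depths < ws:
            raise ValueError("echogram smaller than the transient context window")
        hp, hs = wp // 2, ws // 2
        sv = echogram.sv_db
        padded = np.pad(sv, ((hp, hp), (hs, hs)), constant_values=np.nan)
        n_pings = sv.shape[0]
        context = np.empty_like(sv)
        for start in range(0, n_pings, self.chunk_pings):
            stop = min(start + self.chunk_pings, n_pings)
            win = np.lib.stride_tricks.sliding_window_view(
                padded[start : stop + 2 * hp], (wp, ws)
            ).copy()  # (chunk, n_depths, wp, ws)
            win[:, :, hp, hs] = np.nan  # exclude centre
            flat = win.reshape(win.shape[0], win.shape[1], -1)
            with np.errstate(all="ignore"), _quiet_allnan():
                if self.context_percentile == 50.0:
                    context[start:stop] = np.nanmedian(flat, axis=-1)
                else:
                    context[start:stop] = np.nanpercentile(
                        flat, self.context_percentile, axis=-1
                    )
        with np.errstate(invalid="ignore"):
            flagged = np.isfinite(sv) & np.isfinite(context) & (
                sv > context + self.threshold_db
            )
        out = echogram.copy()
        out.sv_db = np.where(flagged, context, sv)
        self.mask_ = SampleMask(flagged, reason="transient")
        return out


class AttenuatedSignalFilter(_EchogramFilter):
    """Mask whole pings whose linear-domain mean over a depth band is
    >= ``threshold_db`` below the pooled mean of ``n_context_pings``
    preceding and following pings."""

    def __init__(
        self,
        threshold_db: float = 10.0,
        n_context_pings: int = 3,
        band_m: tuple[float, float] | None = None,
    ):
        self.threshold_db = threshold_db
        self.n_context_pings = n_context_pings
        self.band_m = band_m

    def transform(self, echogram: Echogram) -> Echogram:
        nc = self.n_context_pings
        if echogram.n_pings < 2 * nc + 1:
            raise ValueError("attenuated-ping test needs >= 2*n_context+1 pings")
        band = self.band_m
        if band is None:
            band = (MIN_VALID_DEPTH_M, VALID_MAX_DEPTH_M[echogram.frequency_khz])
        in_band = (echogram.depth_m >= band[0]) & (echogram.depth_m < band[1])
        if not in_band.any():
            raise ValueError("attenuation band outside the depth grid")
        lin = echogram.sv_linear()[:, in_band]
        with np.errstate(all="ignore"), _quiet_allnan():
            ping_mean = np.nanmean(lin, axis=1)  # NaN when band fully masked

        n = echogram.n_pings
        mask_pings = np.zeros(n, dtype=bool)
        for i in range(n):
            if not np.isfinite(ping_mean[i]):
                logger.debug("attenuated-signal test skipped ping %d (empty band)", i)
                continue
            ctx = np.r_[ping_mean[max(0, i - nc) : i], ping_mean[i + 1 : i + 1 + nc]]
            ctx = ctx[np.isfinite(ctx)]
            if ctx.size == 0:
                continue
            deficit = 10.0 * np.log10(ctx.mean()) - 10.0 * np.log10(ping_mean[i])
            if deficit >= self.threshold_db:
                mask_pings[i] = True
        mask = np.zeros_like(echogram.sv_db, dtype=bool)
        mask[mask_pings, :] = np.isfinite(echogram.sv_db[mask_pings, :])
        self.mask_ = SampleMask(mask, reason="attenuated")
        self.flagged_pings_ = np.flatnonzero(mask_pings)
        return apply_mask(echogram, self.mask_)


class FrequencyValidityFilter(_EchogramFilter):
    """Mask samples beyond the frequency's usable depth and above the
    10 m surface-exclusion line."""

    def __init__(self, max_depth_m: dict[int, float] | None = None):
        self.max_depth_m = max_depth_m

    def transform(self, echogram: Echogram) -> Echogram:
        table = self.max_depth_m or VALID_MAX_DEPTH_M
        if echogram.frequency_khz not in table:
            raise ValueError(f"no validity cutoff for {echogram.frequency_khz} kHz")
        cutoff = table[echogram.frequency_khz]
        bad_depth = (echogram.depth_m > cutoff) | (echogram.depth_m < MIN_VALID_DEPTH_M)
        mask = np.broadcast_to(bad_depth[None, :], echogram.sv_db.shape).copy()
        mask &= np.isfinite(echogram.sv_db)
        self.mask_ = SampleMask(mask, reason="validity")
        return apply_mask(echogram, self.mask_)


# ---------------------------------------------------------------------------
# functional wrappers


def remove_background_noise(echogram, **kwargs):
    f = BackgroundNoiseFilter(**kwargs)
    out = f.transform(echogram)
    return out, f.mask_


def remove_impulsive_noise(echogram, **kwargs):
    f = ImpulsiveNoiseFilter(**kwargs)
    out = f.transform(echogram)
    return out, f.mask_


def remove_transient_noise(echogram, **kwargs):
    f = TransientNoiseFilter(**kwargs)
    out = f.transform(echogram)
    return out, f.mask_


def remove_attenuated_pings(echogram, **kwargs):
    f = AttenuatedSignalFilter(**kwargs)
    out = f.transform(echogram)
    return out, f.mask_


def apply_frequency_depth_validity(echogram, **kwargs):
    f = FrequencyValidityFilter(**kwargs)
    out = f.transform(echogram)
    return out, f.mask_


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class FilterReport:
    """Per-stage record of what the denoising pipeline removed/adjusted."""

    masks: dict[str, SampleMask] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage, m in self.masks.items():
            pings = int(m.mask.any(axis=1).sum())
            rows.append(
                {
                    "stage": stage,
                    "samples_flagged": m.n_flagged,
                    "pings_flagged": pings,
                }
            )
        return pd.DataFrame(rows, columns=["stage", "samples_flagged", "pings_flagged"])


#: Fixed stage order of the denoising pipeline.
STAGE_ORDER = ("background", "impulsive", "transient", "attenuated", "validity")


def denoise(
    echogram: Echogram,
    background: BackgroundNoiseFilter | None = None,
    impulsive: ImpulsiveNoiseFilter | None = None,
    transient: TransientNoiseFilter | None = None,
    attenuated: AttenuatedSignalFilter | None = None,
    validity: FrequencyValidityFilter | None = None,
) -> tuple[Echogram, FilterReport]:
    """Run the five denoising stages in their fixed order.

    Returns the cleaned echogram and a :class:`FilterReport` with the
    per-stage masks.  Deterministic: identical input yields bit-identical
    masks.
    """
    stages = {
        "background": background or BackgroundNoiseFilter(),
        "impulsive": impulsive or ImpulsiveNoiseFilter(),
        "transient": transient or TransientNoiseFilter(),
        "attenuated": attenuated or AttenuatedSignalFilter(),
        "validity": validity or FrequencyValidityFilter(),
    }
    report = FilterReport()
    out = echogram
    for name in STAGE_ORDER:
        out = stages[name].transform(out)
        report.masks[name] = stages[name].mask_
        logger.info(
            "denoise stage %-10s flagged %d samples", name, stages[name].mask_.n_flagged
        )
    return out, report
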