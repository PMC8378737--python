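"""Seafloor detection and bottom exclusion.

The seabed produces by far the strongest echo in a water-column
echogram; leaving it in would dominate echo integration.  The detector
here is a documented approximation of commercial "best bottom
candidate" pickers: after vertical median smoothing, the bottom on each
ping is the *shallowest* local maximum below a minimum search depth
whose smoothed S_V reaches the peak threshold (default -30 dB).  The
line is then excluded together with a 5 m backstep above it to absorb
detection imperfections and the acoustic dead zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .echogram import Echogram, SampleMask, apply_mask

_FLOOR_DB = -999.0  # stand-in for missing samples during peak search


@dataclass
class BottomLine:
    """Per-ping detected bottom depth (m); NaN where no bottom was found."""

    ping_times: np.ndarray
    bottom_depth_m: np.ndarray

    def __post_init__(self):
        self.bottom_depth_m = np.asarray(self.bottom_depth_m, dtype=float)

    def exclusion_depth_m(self, backstep_m: float = 5.0) -> np.ndarray:
        """Depth above which samples are kept (bottom minus backstep)."""
        return self.bottom_depth_m - backstep_m

    def fill_gaps(self) -> "BottomLine":
        """Linearly interpolate missing picks across ping index.

        Pings where no qualifying peak exists (e.g. attenuated pings
        whose seabed echo drops below the pick threshold) inherit the
        line of their neighbours — the usual line-editing practice.  No
        extrapolation beyond the first/last detection.
        """
        b = self.bottom_depth_m
        good = np.isfinite(b)
        if good.sum() < 2:
            return BottomLine(self.ping_times, b.copy())
        idx = np.arange(b.size)
        filled = b.copy()
        inner = (idx >= idx[good][0]) & (idx <= idx[good][-1])
        filled[~good & inner] = np.interp(idx[~good & inner], idx[good], b[good])
        return BottomLine(self.ping_times, filled)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ping_time": self.ping_times, "bottom_depth_m": self.bottom_depth_m}
        )


class BottomDetector(BaseEstimator):
    """Shallowest-qualifying-peak bottom picker (see module docstring)."""

    def __init__(
        self,
        peak_threshold_db: float = -30.0,
        min_search_depth_m: float = 20.0,
        smoothing_samples: int = 5,
    ):
        self.peak_threshold_db = peak_threshold_db
        self.min_search_depth_m = min_search_depth_m
        self.smoothing_samples = smoothing_samples

    def transform(self, echogram: Echogram) -> BottomLine:
        if self.smoothing_samples % 2 != 1:
            raise ValueError("smoothing_samples must be odd")
        if self.min_search_depth_m >= echogram.depth_m[-1]:
            raise ValueError("min_search_depth beyond the depth grid")
        sv = np.where(np.isfinite(echogram.sv_db), echogram.sv_db, _FLOOR_DB)
        smoothed = median_filter(
            sv, size=(1, self.smoothing_samples), mode="nearest"
        )
        searchable = echogram.depth_m > self.min_search_depth_m
        bottoms = np.full(echogram.n_pings, np.nan)
        for i in range(echogram.n_pings):
            profile = np.where(searchable, smoothed[i], _FLOOR_DB)
            # pad so maxima at the grid edges qualify as peaks
            padded = np.concatenate(([_FLOOR_DB], profile, [_FLOOR_DB]))
            peaks, _ = find_peaks(padded, height=self.peak_threshold_db)
            if peaks.size:
                bottoms[i] = echogram.depth_m[peaks[0] - 1]
        self.bottom_line_ = BottomLine(echogram.ping_times, bottoms)
        return self.bottom_line_

    # alias matching the estimator idiom for detectors
    fit_predict = transform


def detect_bottom(
    echogram: Echogram,
    peak_threshold_db: float = -30.0,
    min_search_depth_m: float = 20.0,
    smoothing_samples: int = 5,
) -> BottomLine:
    """Detect the seabed on each ping; absent bottom is a valid outcome."""
    return BottomDetector(
        peak_threshold_db, min_search_depth_m, smoothing_samples
    ).transform(echogram)


def mask_below_bottom(
    echogram: Echogram, bottom_line: BottomLine, backstep_m: float = 5.0
) -> tuple[Echogram, SampleMask]:
    """Mask all samples at or below (bottom - backstep) on detected pings."""
    if len(bottom_line.bottom_depth_m) != echogram.n_pings:
        raise ValueError("bottom line length != number of pings")
    limit = bottom_line.exclusion_depth_m(backstep_m)[:, None]  # (n_pings, 1)
    with np.errstate(invalid="ignore"):
        mask = echogram.depth_m[None, :] >= limit
    mask &= np.isfinite(echogram.sv_db)
    sample_mask = SampleMask(mask, reason="below_bottom")
    return apply_mask(echogram, sample_mask), sample_mask
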