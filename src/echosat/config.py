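"""Pipeline configuration: YAML key-value files with strict validation.

Every stage parameter defaults to the survey-processing values the
pipeline is built around (10 dB SNR, 5x9 transient window, -30 dB
bottom peak, 5 m backstep, -80 dB integration threshold, 4 km bins,
10/50/200/500/750 m layers, 7-day satellite window, 100 trees, node
size 5, 10 latitude folds).  Unknown keys are rejected with the list of
valid keys for their section.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from pathlib import Path

import yaml

from .simulate import SimConfig

logger = logging.getLogger(__name__)

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)} - {"layers", "anomaly"}

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "echosat_run",
    "simulate": {
        # modest demo-scale survey; every SimConfig scalar field may be set here
        "years": [2011, 2012, 2013, 2015],
        "n_transects": 3,
        "transect_length_km": 10.0,
        "ping_interval_s": 4.4,
        "frequencies": [18, 38, 120],
    },
    "denoise": {
        "snr_threshold_db": 10.0,
        "background_cell_pings": 10,
        "background_cell_samples": 20,
        "max_noise_db": -125.0,
        "impulsive_threshold_db": 10.0,
        "transient_threshold_db": 10.0,
        "transient_window_pings": 5,
        "transient_window_samples": 9,
        "attenuated_threshold_db": 10.0,
        "attenuated_context_pings": 3,
    },
    "seafloor": {
        "peak_threshold_db": -30.0,
        "min_search_depth_m": 20.0,
        "smoothing_samples": 5,
        "backstep_m": 5.0,
        "detection_frequency_khz": 38,
    },
    "integrate": {
        "bin_length_m": 4000.0,
        "sv_threshold_db": -80.0,
        "min_valid_fraction": 0.1,
    },
    "matchup": {
        "window_half_width_days": 3,
    },
    "model": {
        "n_trees": 100,
        "min_node_size": 5,
        "max_features": 1.0 / 3.0,
        "cv_folds": 10,
        "test_years": [2015],
    },
}


def _validate(section: dict, defaults: dict, path: str):
    for key, value in section.items():
        if key not in defaults:
            raise ValueError(
                f"unknown config key '{path}{key}'; valid keys: "
                f"{sorted(defaults)}"
            )
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            _validate(value, defaults[key], f"{path}{key}.")


def load_config(path=None, seed: int | None = None) -> dict:
    """Load a YAML config, merge over defaults, validate keys."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if "simulate" in user:
            unknown = set(user["simulate"]) - _SIM_FIELDS
            if unknown:
                raise ValueError(
                    f"unknown config key(s) {sorted(unknown)} in 'simulate'; "
                    f"valid keys: {sorted(_SIM_FIELDS)}"
                )
        _validate({k: v for k, v in user.items() if k != "simulate"}, DEFAULTS, "")
        for key, value in user.items():
            if isinstance(value, dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def sim_config(cfg: dict) -> SimConfig:
    """Build a SimConfig from the config's ``simulate`` section."""
    kwargs = {k: v for k, v in cfg["simulate"].items() if k in _SIM_FIELDS}
    for tup in ("years", "lat_span", "frequencies", "depth_range_m"):
        if tup in kwargs and isinstance(kwargs[tup], list):
            kwargs[tup] = tuple(kwargs[tup])
    kwargs["seed"] = cfg["seed"]
    return SimConfig(**kwargs)


def echo_config(cfg: dict, out_dir: Path) -> None:
    """Append the fully resolved config to the run log (parameter echo)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "echosat.log", "a") as fh:
        fh.write("# resolved configuration\n")
        fh.write(yaml.safe_dump(cfg, sort_keys=True))
        fh.write("\n")
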