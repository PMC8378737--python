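import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from echosat.echogram import Echogram  # noqa: E402


def make_echogram(
    sv,
    frequency_khz=38,
    depth_start=0.375,
    depth_spacing=0.75,
    lat0=45.0,
    lon0=-124.5,
):
    """Small echogram with trivial geometry around a fixed position."""
    sv = np.asarray(sv, dtype=float)
    n_pings, n_depths = sv.shape
    times = np.datetime64("2012-06-01T12:00:00", "ns") + (
        np.arange(n_pings) * 1_100_000_000
    ).astype("timedelta64[ns]")
    return Echogram(
        frequency_khz=frequency_khz,
        ping_times=times,
        latitudes=np.full(n_pings, lat0),
        longitudes=np.full(n_pings, lon0),
        depth_m=depth_start + depth_spacing * np.arange(n_depths),
        sv_db=sv,
    )


@pytest.fixture
def echogram_factory():
    return make_echogram


@pytest.fixture(scope="session")
def small_sim():
    """One short simulated transect with artifacts and ground truth."""
    from echosat.simulate import SimConfig, simulate_cruise, simulate_echograms

    cfg = SimConfig(seed=7, years=(2012,), n_transects=1, transect_length_km=2.0)
    track = simulate_cruise(cfg)[2012]
    echograms, truth = simulate_echograms(cfg, track)
    return cfg, track, echograms, truth
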