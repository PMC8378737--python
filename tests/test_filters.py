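import numpy as np
import pytest

from conftest import make_echogram
from echosat.echogram import db_to_linear
from echosat.filters import (
    AttenuatedSignalFilter,
    BackgroundNoiseFilter,
    FrequencyValidityFilter,
    ImpulsiveNoiseFilter,
    TransientNoiseFilter,
    denoise,
)


# ---------------------------------------------------------------------------
# background noise


def _noise_db(depth, noise_1m, alpha):
    r = np.maximum(depth, 1.0)
    return noise_1m + 20.0 * np.log10(r) + 2.0 * alpha * r


def test_background_linear_subtraction_oracle():
    """A -75 dB sample over -90 dB noise corrects to 10log10(10^-7.5 - 1e-9)."""
    alpha = 0.0098
    depth = 0.25 + 0.5 * np.arange(400)  # to 200 m
    noise_1m = -90.0 - 20.0 * np.log10(100.0) - 2.0 * alpha * 100.0
    noise = _noise_db(depth, noise_1m, alpha)
    sv = np.tile(noise, (30, 1))  # signal-free below the layer
    in_layer = (depth > 50) & (depth < 150)
    sv[:, in_layer] = -75.0
    eg = make_echogram(sv, depth_start=0.25, depth_spacing=0.5)
    out = BackgroundNoiseFilter(absorption_db_per_m=alpha).transform(eg)
    j = np.argmin(np.abs(depth - 100.0))
    assert out.sv_db[10, j] == pytest.approx(-75.140, abs=0.05)


def test_background_noop_when_no_noise():
    eg = make_echogram(np.full((20, 40), -70.0))
    f = BackgroundNoiseFilter(max_noise_db=-999.0)
    out = f.transform(eg)
    np.testing.assert_allclose(out.sv_db, eg.sv_db, atol=0.01)
    assert f.mask_.n_flagged == 0


def test_background_masks_low_snr():
    """Samples that are pure noise have SNR ~ 0 and must all be masked."""
    alpha = 0.0098
    depth = 0.25 + 0.5 * np.arange(400)
    noise = _noise_db(depth, -130.0, alpha)
    sv = np.tile(noise, (20, 1))
    shallow = depth < 50
    sv[:, shallow] = -60.0  # strong signal keeps shallow samples
    eg = make_echogram(sv, depth_start=0.25, depth_spacing=0.5)
    f = BackgroundNoiseFilter(absorption_db_per_m=alpha)
    out = f.transform(eg)
    assert np.isnan(out.sv_db[:, ~shallow]).all()
    assert np.isfinite(out.sv_db[:, shallow]).all()


def test_background_never_raises_sv():
    rng = np.random.default_rng(1)
    eg = make_echogram(rng.uniform(-90, -60, (30, 60)))
    out = BackgroundNoiseFilter().transform(eg)
    keep = np.isfinite(out.sv_db)
    assert (out.sv_db[keep] <= eg.sv_db[keep] + 1e-12).all()


def test_background_too_small_errors():
    eg = make_echogram(np.full((5, 10), -70.0))
    with pytest.raises(ValueError):
        BackgroundNoiseFilter(cell_pings=10, cell_samples=20).transform(eg)


# ---------------------------------------------------------------------------
# impulsive noise


@pytest.mark.parametrize(
    "centre, masked", [(-59.9, True), (-61.0, False), (-80.1, True), (-79.0, False)]
)
def test_impulsive_threshold(centre, masked):
    sv = np.full((5, 5), -70.0)
    sv[2, 2] = centre
    f = ImpulsiveNoiseFilter()
    f.transform(make_echogram(sv))
    assert bool(f.mask_.mask[2, 2]) is masked
    assert f.mask_.n_flagged == (1 if masked else 0)


def test_impulsive_requires_both_neighbours():
    sv = np.full((3, 5), -70.0)
    sv[1, 2] = -55.0
    sv[2, 2] = -55.0  # step, not a spike
    f = ImpulsiveNoiseFilter()
    f.transform(make_echogram(sv))
    assert not f.mask_.mask[1, 2]


def test_impulsive_constant_and_edge():
    f = ImpulsiveNoiseFilter()
    f.transform(make_echogram(np.full((5, 4), -70.0)))
    assert f.mask_.n_flagged == 0
    sv = np.full((3, 4), -70.0)
    sv[0, 1] = -50.0  # edge ping, single-neighbour test
    f.transform(make_echogram(sv))
    assert f.mask_.mask[0, 1]


# ---------------------------------------------------------------------------
# transient noise


def test_transient_adjusts_to_context_median():
    sv = np.full((5, 9), -70.0)
    sv[2, 4] = -50.0
    f = TransientNoiseFilter()
    out = f.transform(make_echogram(sv))
    assert f.mask_.mask[2, 4]
    assert out.sv_db[2, 4] == pytest.approx(-70.0)


def test_transient_below_threshold_retained():
    sv = np.full((5, 9), -70.0)
    sv[2, 4] = -61.0
    f = TransientNoiseFilter()
    out = f.transform(make_echogram(sv))
    assert f.mask_.n_flagged == 0
    assert out.sv_db[2, 4] == pytest.approx(-61.0)


def test_transient_blob_recovery(small_sim):
    cfg, track, echograms, truth = small_sim
    eg = BackgroundNoiseFilter().transform(echograms[38])
    eg = ImpulsiveNoiseFilter().transform(eg)
    f = TransientNoiseFilter()
    f.transform(eg)
    gt = truth.transient[38]
    assert gt.sum() > 0
    sens = (f.mask_.mask & gt).sum() / gt.sum()
    fp = (f.mask_.mask & ~gt).sum() / (~gt).sum()
    assert sens >= 0.95
    assert fp <= 0.001


# ---------------------------------------------------------------------------
# attenuated pings


def test_attenuated_ping_masked():
    sv = np.full((9, 200), -65.0)
    sv[4, :] = -80.0  # 15 dB below context
    f = AttenuatedSignalFilter(band_m=(10.0, 140.0))
    out = f.transform(make_echogram(sv))
    assert list(f.flagged_pings_) == [4]
    assert np.isnan(out.sv_db[4]).all()


def test_attenuated_homogeneous_unmasked():
    f = AttenuatedSignalFilter(band_m=(10.0, 140.0))
    f.transform(make_echogram(np.full((9, 200), -65.0)))
    assert f.mask_.n_flagged == 0


def test_attenuated_injected_recovery(small_sim):
    cfg, track, echograms, truth = small_sim
    eg = BackgroundNoiseFilter().transform(echograms[38])
    eg = ImpulsiveNoiseFilter().transform(eg)
    eg = TransientNoiseFilter().transform(eg)
    f = AttenuatedSignalFilter()
    f.transform(eg)
    gt_pings = np.flatnonzero(truth.attenuated[38].any(axis=1))
    assert gt_pings.size > 0
    assert set(gt_pings) == set(f.flagged_pings_)


# ---------------------------------------------------------------------------
# frequency-depth validity


def test_validity_cutoffs_200khz():
    sv = np.full((2, 1000), -70.0)
    eg = make_echogram(sv, frequency_khz=200)
    f = FrequencyValidityFilter()
    out = f.transform(eg)
    deep = eg.depth_m > 150.0
    shallow = eg.depth_m < 10.0
    assert np.isnan(out.sv_db[:, deep]).all()
    assert np.isnan(out.sv_db[:, shallow]).all()
    assert np.isfinite(out.sv_db[:, ~deep & ~shallow]).all()


def test_validity_counts_by_frequency():
    depth = 0.375 + 0.75 * np.arange(1000)
    for freq, cutoff in [(18, 750.0), (70, 500.0), (120, 275.0)]:
        eg = make_echogram(np.full((2, 1000), -70.0), frequency_khz=freq)
        f = FrequencyValidityFilter()
        f.transform(eg)
        expected = 2 * int(((depth > cutoff) | (depth < 10.0)).sum())
        assert f.mask_.n_flagged == expected


def test_validity_unknown_frequency_errors():
    eg = make_echogram(np.full((2, 20), -70.0), frequency_khz=38)
    with pytest.raises(ValueError):
        FrequencyValidityFilter(max_depth_m={18: 750.0}).transform(eg)


# ---------------------------------------------------------------------------
# pipeline properties


def test_filters_never_create_valid_samples(small_sim):
    cfg, track, echograms, truth = small_sim
    out, report = denoise(echograms[38])
    assert not (np.isfinite(out.sv_db) & ~np.isfinite(echograms[38].sv_db)).any()


def test_denoise_deterministic(small_sim):
    cfg, track, echograms, truth = small_sim
    out1, rep1 = denoise(echograms[38])
    out2, rep2 = denoise(echograms[38])
    np.testing.assert_array_equal(out1.sv_db, out2.sv_db)
    for stage in rep1.masks:
        np.testing.assert_array_equal(rep1.masks[stage].mask, rep2.masks[stage].mask)


def test_clean_echogram_yields_empty_artifact_masks():
    from echosat.simulate import SimConfig, simulate_cruise, simulate_echograms

    cfg = SimConfig(
        seed=3,
        years=(2012,),
        n_transects=1,
        transect_length_km=1.0,
        impulsive_rate=0.0,
        transient_rate_per_ping=0.0,
        attenuated_rate=0.0,
    )
    track = simulate_cruise(cfg)[2012]
    echograms, _ = simulate_echograms(cfg, track)
    _, report = denoise(echograms[38])
    for stage in ("impulsive", "transient", "attenuated"):
        assert report.masks[stage].n_flagged == 0


def test_filter_report_frame(small_sim):
    cfg, track, echograms, truth = small_sim
    _, report = denoise(echograms[38])
    frame = report.to_frame()
    assert list(frame["stage"]) == [
        "background", "impulsive", "transient", "attenuated", "validity",
    ]
    assert (frame["samples_flagged"] >= 0).all()
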