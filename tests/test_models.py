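import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import r2_score

from echosat.models import (
    FULL_FEATURES,
    REDUCED_FEATURES,
    ModelSpec,
    NascForest,
    compute_r2,
    fit_model,
    make_latitude_folds,
    pearson,
    run_spatial_cv,
    run_temporal_holdout,
)


def make_rows(n, seed=0, years=(2011, 2012, 2013), signal="none"):
    """Synthetic feature rows with controllable response structure."""
    rng = np.random.default_rng(seed)
    lat = rng.uniform(30.0, 50.0, n)
    df = pd.DataFrame(
        {
            "year": rng.choice(years, n),
            "frequency_khz": rng.choice([18, 38, 120], n),
            "depth_layer": rng.choice(["shallow", "mid"], n),
            "daytime": rng.random(n) < 0.5,
            "distance_from_shore_km": rng.uniform(5, 100, n),
            "latitude": lat,
            "ocean_depth_m": rng.uniform(100, 700, n),
            "chlor_a": rng.lognormal(0, 0.3, n),
            "nflh": rng.normal(0.15, 0.02, n),
            "poc": rng.lognormal(4.5, 0.3, n),
            "sst": rng.normal(14, 1.5, n),
        }
    )
    df["freq_depth"] = df.frequency_khz.astype(str) + "_" + df.depth_layer
    if signal == "latitude":
        df["log_nasc"] = np.sin(lat / 3.0) * 2.0 + lat / 10.0
    elif signal == "constant":
        df["log_nasc"] = 2.5
    else:
        df["log_nasc"] = rng.normal(2.0, 1.0, n)
    return df


# ---------------------------------------------------------------------------
# metrics


def test_r2_hand_examples():
    assert compute_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[0] == pytest.approx(1.0)
    r2_raw, r2_rep = compute_r2([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
    assert r2_raw == pytest.approx(0.5)
    assert r2_rep == pytest.approx(0.5)


def test_r2_negative_rounds_to_zero():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    r2_raw, r2_rep = compute_r2(y, y[::-1])
    assert r2_raw < 0
    assert r2_rep == 0.0


def test_r2_constant_y_is_missing():
    with pytest.warns(UserWarning):
        r2_raw, r2_rep = compute_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert np.isnan(r2_raw) and np.isnan(r2_rep)


def test_r2_matches_bruteforce_and_sklearn():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(2, 40))
        y = rng.normal(size=n)
        if np.ptp(y) == 0:
            continue
        yhat = rng.normal(size=n)
        raw, rep = compute_r2(y, yhat)
        brute = 1.0 - sum((a - b) ** 2 for a, b in zip(y, yhat)) / sum(
            (a - y.mean()) ** 2 for a in y
        )
        assert raw == pytest.approx(brute, abs=1e-12)
        assert raw == pytest.approx(r2_score(y, yhat), abs=1e-12)
        assert rep == max(0.0, raw)
        assert raw <= 1.0 and 0.0 <= rep <= 1.0


def test_pearson_affine_invariance_and_sign():
    y = np.array([0.3, 1.2, -0.5, 2.0, 0.0])
    assert pearson(y, 2.0 * y + 1.0) == pytest.approx(1.0, abs=1e-12)
    assert pearson(y, -y) == pytest.approx(-1.0, abs=1e-12)
    a, b = np.array([1.0, 2.0, 4.0]), np.array([0.5, 3.0, 1.0])
    assert pearson(3.0 * a - 2.0, 0.1 * b + 7.0) == pytest.approx(
        pearson(a, b), abs=1e-12
    )


def test_pearson_matches_scipy_oracle():
    rng = np.random.default_rng(9)
    for _ in range(100):
        n = int(rng.integers(2, 30))
        y, yhat = rng.normal(size=n), rng.normal(size=n)
        if np.ptp(y) == 0 or np.ptp(yhat) == 0:
            continue
        assert pearson(y, yhat) == pytest.approx(
            scipy.stats.pearsonr(y, yhat).statistic, abs=1e-12
        )
    # the spec's 4-point probe, checked against the independent oracle
    y4, p4 = np.array([0.0, 1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0, 0.0])
    assert pearson(y4, p4) == pytest.approx(
        scipy.stats.pearsonr(y4, p4).statistic, abs=1e-12
    )


def test_pearson_constant_warns_nan():
    with pytest.warns(UserWarning):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# latitude folds


def test_folds_uniform_coverage():
    rows = pd.DataFrame({"latitude": np.linspace(30.0, 50.0, 100)})
    fold = make_latitude_folds(rows, k=10)
    assert set(fold) == set(range(10))
    counts = np.bincount(fold, minlength=10)
    assert (counts > 0).all()


def test_folds_boundary_goes_to_higher_interval():
    rows = pd.DataFrame({"latitude": [30.0, 34.0, 36.5, 50.0]})
    fold = make_latitude_folds(rows, k=10)  # 2-degree folds from 30
    assert fold[1] == 2  # 34.0 on the [34, 36) boundary
    assert fold[3] == 9  # maximum goes to the top interval


def test_folds_partition():
    rng = np.random.default_rng(10)
    rows = pd.DataFrame({"latitude": rng.uniform(40, 48, 500)})
    fold = make_latitude_folds(rows, k=10)
    assert fold.shape == (500,)
    assert ((fold >= 0) & (fold <= 9)).all()
    # depends only on latitude
    fold2 = make_latitude_folds(rows.sample(frac=1.0, random_state=1).sort_index(), k=10)
    np.testing.assert_array_equal(fold, fold2)


def test_folds_identical_latitudes_error():
    with pytest.raises(ValueError):
        make_latitude_folds(pd.DataFrame({"latitude": [45.0] * 10}), k=10)


# ---------------------------------------------------------------------------
# model fitting


def test_constant_response_predicts_constant():
    rows = make_rows(200, signal="constant")
    model = fit_model(rows, ModelSpec(variant="full", seed=1))
    np.testing.assert_allclose(model.predict(rows), 2.5)


def test_fit_deterministic_given_seed():
    rows = make_rows(300, seed=2)
    probe = make_rows(50, seed=3)
    p1 = fit_model(rows, ModelSpec(variant="full", seed=5)).predict(probe)
    p2 = fit_model(rows, ModelSpec(variant="full", seed=5)).predict(probe)
    np.testing.assert_array_equal(p1, p2)


def test_noiseless_latitude_signal_recovered():
    rows = make_rows(2000, seed=4, signal="latitude")
    model = fit_model(rows, ModelSpec(variant="reduced", seed=0))
    raw, _ = compute_r2(rows["log_nasc"].to_numpy(), model.predict(rows))
    assert raw >= 0.95


def test_missing_covariate_raises():
    rows = make_rows(100)
    rows.loc[3, "sst"] = np.nan
    with pytest.raises(ValueError):
        fit_model(rows, ModelSpec(variant="full", seed=0))
    # the reduced variant never touches satellite columns
    fit_model(rows, ModelSpec(variant="reduced", seed=0))


def test_variant_feature_sets():
    assert set(FULL_FEATURES) - set(REDUCED_FEATURES) == {
        "chlor_a", "nflh", "poc", "sst",
    }
    with pytest.raises(ValueError):
        ModelSpec(variant="medium")


# ---------------------------------------------------------------------------
# holdout designs


def test_spatial_cv_shares_folds_and_seeds_across_variants():
    rows = make_rows(400, seed=6)
    out = run_spatial_cv(rows, k=5, seed=3, n_trees=20)
    for f in range(5):
        assert out.fingerprints[("full", f)] == out.fingerprints[("reduced", f)]
    assert set(out.results["variant"]) == {"full", "reduced"}
    assert (out.results["n"] >= 1).all()
    assert (out.results["r2_reported"].dropna() >= 0).all()
    assert (out.results["r2_raw"].dropna() <= 1.0 + 1e-12).all()


def test_spatial_cv_metrics_use_withheld_rows_only():
    rows = make_rows(400, seed=7)
    fold = make_latitude_folds(rows, k=5)
    for f in range(5):
        assert not (set(np.flatnonzero(fold == f)) & set(np.flatnonzero(fold != f)))
    n_by_fold = (
        run_spatial_cv(rows, k=5, seed=0, n_trees=10, variants=("full",))
        .results.groupby("holdout_unit")["n"]
        .sum()
    )
    np.testing.assert_array_equal(
        n_by_fold.sort_index().to_numpy(), np.bincount(fold, minlength=5)
    )


def test_temporal_holdout_disjoint_and_bias():
    rows = make_rows(600, seed=8)
    train = rows[rows.year != 2013].reset_index(drop=True)
    test = rows[rows.year == 2013].reset_index(drop=True)
    out = run_temporal_holdout(train, test, seed=0, n_trees=20)
    assert "bias" in out.results.columns
    np.testing.assert_allclose(
        out.results["bias"], out.results["mean_pred"] - out.results["mean_true"]
    )
    with pytest.raises(ValueError):
        run_temporal_holdout(rows, test, seed=0)


def test_temporal_holdout_iid_bias_near_zero():
    """With train and test drawn from one distribution, bias ~ 0."""
    biases = []
    for seed in range(5):
        rows = make_rows(800, seed=20 + seed, signal="latitude")
        rows["log_nasc"] += np.random.default_rng(seed).normal(0, 0.3, len(rows))
        train = rows[rows.year != 2013].reset_index(drop=True)
        test = rows[rows.year == 2013].reset_index(drop=True)
        out = run_temporal_holdout(train, test, seed=seed, n_trees=50,
                                   variants=("reduced",))
        biases.append(out.results["bias"].mean())
    assert abs(np.mean(biases)) <= 0.1
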