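"""Random-forest isoscape: covariate handling, selection, fitting and
quantile-forest uncertainty calibration."""

import numpy as np
import pandas as pd
import pytest

from toothtrack.grids import Grid
from toothtrack.isoscape import (CovariateStack, cross_validate,
                                 extract_covariates, filter_correlated,
                                 fit_isoscape, predict_sd_at,
                                 select_variables, validate_points)
from sklearn.ensemble import RandomForestRegressor


@pytest.fixture
def ramp_stack():
    n = 40
    ramp = Grid(np.linspace(0.0, 1.0, n * n).reshape(n, n), 2000.0)
    rng = np.random.default_rng(0)
    junk = Grid(rng.standard_normal((n, n)), 2000.0)
    return CovariateStack({"ramp": ramp, "junk": junk})


@pytest.fixture
def training(ramp_stack):
    rng = np.random.default_rng(7)
    n = 400
    ext = ramp_stack.template.extent
    samples = pd.DataFrame({
        "x": rng.uniform(ext[0], ext[1] - 1, n),
        "y": rng.uniform(ext[2], ext[3] - 1, n),
    })
    feats = extract_covariates(samples, ramp_stack)
    signal = 0.705 + 0.01 * np.sin(3.0 * feats["ramp"].to_numpy())
    return feats, signal


class TestExtractCovariates:
    def test_constant_grid_gives_identical_features(self):
        g = Grid(np.full((10, 10), 3.14), 1000.0)
        stack = CovariateStack({"c": g})
        samples = pd.DataFrame({"x": [500.0, 2500.0, 9000.0],
                                "y": [500.0, 2500.0, 9000.0]})
        feats = extract_covariates(samples, stack)
        np.testing.assert_allclose(feats["c"], 3.14)

    def test_cell_center_value_by_direct_indexing(self):
        vals = np.arange(100.0).reshape(10, 10)
        stack = CovariateStack({"r": Grid(vals, 1000.0)})
        # center of row 2 (from top), col 4: x = 4500, y = (10-1-2+0.5)*1000
        samples = pd.DataFrame({"x": [4500.0], "y": [7500.0]})
        feats = extract_covariates(samples, stack)
        assert feats["r"].iloc[0] == vals[2, 4]

    def test_outside_sites_dropped_and_counted(self):
        stack = CovariateStack({"c": Grid(np.zeros((10, 10)), 1000.0)})
        samples = pd.DataFrame({"x": [500.0, 2500.0, 1e6],
                                "y": [500.0, 2500.0, 1e6]})
        feats = extract_covariates(samples, stack)
        assert len(feats) == 2
        assert feats.attrs["n_dropped"] == 1


class TestFilterCorrelated:
    def test_duplicate_feature_dropped_once(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(200)
        df = pd.DataFrame({"a": a, "a_copy": a.copy(), "b": rng.standard_normal(200)})
        kept, dropped = filter_correlated(df)
        assert list(kept.columns) == ["a", "b"]
        assert dropped == ["a_copy"]

    def test_independent_features_both_survive(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.standard_normal(200),
                           "b": rng.standard_normal(200)})
        kept, dropped = filter_correlated(df)
        assert list(kept.columns) == ["a", "b"] and not dropped

    def test_constructed_r95_pair_loses_later_member(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(500)
        rho = 0.95
        b = rho * a + np.sqrt(1 - rho**2) * rng.standard_normal(500)
        df = pd.DataFrame({"a": a, "b": b})
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.9  # constructed oracle
        kept, dropped = filter_correlated(df)
        assert list(kept.columns) == ["a"] and dropped == ["b"]

    def test_anticorrelation_uses_absolute_value(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(300)
        df = pd.DataFrame({"a": a, "neg": -a})
        kept, dropped = filter_correlated(df)
        assert dropped == ["neg"]

    def test_constant_feature_dropped_with_warning(self):
        df = pd.DataFrame({"a": np.arange(50.0), "c": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            kept, dropped = filter_correlated(df)
        assert "c" in dropped


class TestSelectVariables:
    def test_planted_signal_recovered_junk_removed(self):
        rng = np.random.default_rng(5)
        n = 300
        a = rng.standard_normal(n)
        df = pd.DataFrame({f"junk{i}": rng.standard_normal(n) for i in range(5)})
        df.insert(0, "a", a)
        response = a + rng.normal(0, 0.01, n)
        kept = select_variables(df, response, seed=1, n_trees=200)
        assert kept[0] == "a"
        assert not any(k.startswith("junk") for k in kept)

    def test_single_feature_retained(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"only": rng.standard_normal(100)})
        response = df["only"].to_numpy() * 2.0
        assert select_variables(df, response, seed=2, n_trees=100) == ["only"]

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"a": rng.standard_normal(150),
                           "b": rng.standard_normal(150)})
        response = df["a"].to_numpy() + 0.1 * rng.standard_normal(150)
        assert (select_variables(df, response, seed=3)
                == select_variables(df, response, seed=3))


class TestFitIsoscape:
    def test_noiseless_learnable_signal_cv_above_90pct(self, training, ramp_stack):
        feats, signal = training
        cv = cross_validate(feats[["ramp"]], signal, n_trees=200, seed=1)
        assert cv.pct_var_explained > 90.0

    def test_quantile_sd_calibrated_under_homoscedastic_noise(self, training, ramp_stack):
        feats, signal = training
        rng = np.random.default_rng(11)
        noisy = signal + rng.normal(0, 0.001, signal.size)
        iso = fit_isoscape(feats, noisy, ramp_stack, n_trees=300, seed=2)
        sd = iso.sd_grid[~np.isnan(iso.sd_grid)]
        assert 0.0007 <= np.median(sd) <= 0.0013

    def test_predictions_bounded_by_training_range(self, training, ramp_stack):
        feats, signal = training
        iso = fit_isoscape(feats, signal, ramp_stack, n_trees=100, seed=3)
        vals = iso.mean_grid[~np.isnan(iso.mean_grid)]
        assert vals.min() >= signal.min() - 1e-12
        assert vals.max() <= signal.max() + 1e-12

    def test_sd_positive_and_monotone_in_pi_level(self, training, ramp_stack):
        feats, signal = training
        rng = np.random.default_rng(12)
        noisy = signal + rng.normal(0, 0.001, signal.size)
        X = feats.to_numpy()
        forest = RandomForestRegressor(n_estimators=150, random_state=0,
                                       min_samples_leaf=5, n_jobs=1).fit(X, noisy)
        q = X[:40]
        sd_narrow = predict_sd_at(forest, X, noisy, q, pi_level=0.5)
        sd_wide = predict_sd_at(forest, X, noisy, q, pi_level=0.9)
        assert np.all(sd_narrow > 0)
        assert np.all(sd_wide >= sd_narrow - 1e-15)

    def test_row_permutation_invariance(self, training, ramp_stack):
        feats, signal = training
        iso1 = fit_isoscape(feats, signal, ramp_stack, n_trees=60, seed=4)
        perm = np.random.default_rng(0).permutation(len(feats))
        iso2 = fit_isoscape(feats.iloc[perm].reset_index(drop=True), signal[perm],
                            ramp_stack, n_trees=60, seed=4)
        # same data, same seed handling -> statistically equivalent surfaces
        np.testing.assert_allclose(iso1.mean_grid, iso2.mean_grid, atol=5e-4)

    def test_constant_response_rejected(self, training, ramp_stack):
        feats, _ = training
        with pytest.raises(ValueError, match="constant"):
            fit_isoscape(feats, np.full(len(feats), 0.71), ramp_stack, n_trees=50)


class TestValidatePoints:
    def _iso(self, value=0.711):
        from toothtrack.grids import Isoscape
        return Isoscape(Grid(np.full((10, 10), value), 1000.0),
                        Grid(np.full((10, 10), 1e-4), 1000.0))

    def test_perfect_predictions(self):
        iso = self._iso()
        pts = pd.DataFrame({"x": [500.0, 1500.0, 2500.0, 3500.0],
                            "y": [500.0] * 4,
                            "ratio": [0.711, 0.711, 0.711, 0.711]})
        # R^2 undefined on constant prediction; use a gradient surface
        iso.mean.values[:] = np.linspace(0.705, 0.72, 100).reshape(10, 10)
        pts["ratio"] = iso.mean.lookup(pts["x"].to_numpy(), pts["y"].to_numpy())
        res = validate_points(iso, pts)
        assert res["rmse"] == pytest.approx(0.0, abs=1e-15)
        assert res["r2"] == pytest.approx(1.0)

    def test_constant_bias_separates_rmse_from_r2(self):
        iso = self._iso()
        iso.mean.values[:] = np.linspace(0.705, 0.72, 100).reshape(10, 10)
        pts = pd.DataFrame({"x": [500.0, 1500.0, 2500.0, 3500.0],
                            "y": [500.0] * 4})
        pts["ratio"] = iso.mean.lookup(pts["x"].to_numpy(), pts["y"].to_numpy()) + 0.001
        res = validate_points(iso, pts)
        assert res["rmse"] == pytest.approx(0.001, rel=1e-9)
        assert res["r2"] == pytest.approx(1.0)

    def test_rmse_matches_direct_formula(self):
        iso = self._iso()
        rng = np.random.default_rng(9)
        iso.mean.values[:] = rng.uniform(0.705, 0.72, (10, 10))
        x = rng.uniform(0, 9999, 20)
        y = rng.uniform(0, 9999, 20)
        obs = rng.uniform(0.705, 0.72, 20)
        pts = pd.DataFrame({"x": x, "y": y, "ratio": obs})
        res = validate_points(iso, pts)
        pred = iso.mean.lookup(x, y)
        assert res["rmse"] == pytest.approx(np.sqrt(np.mean((pred - obs) ** 2)), rel=1e-12)

    def test_too_few_points_rejected(self):
        iso = self._iso()
        with pytest.raises(ValueError):
            validate_points(iso, pd.DataFrame({"x": [1.0], "y": [1.0], "ratio": [0.71]}))
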