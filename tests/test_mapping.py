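import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from agrimeta import mapping as mp


class TestAggregate:
    def test_2x2_block_mean(self):
        g = mp.Grid(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = mp.aggregate_grid(g, 2)
        assert out.values == pytest.approx(np.array([[2.5]]))
        assert out.cell_size == 2.0

    def test_factor_one_identity(self, rng):
        g = mp.Grid(rng.standard_normal((5, 7)), cell_size=2.0)
        out = mp.aggregate_grid(g, 1)
        assert np.array_equal(out.values, g.values)
        assert out.cell_size == g.cell_size

    def test_global_mean_preserved(self, rng):
        g = mp.Grid(rng.standard_normal((8, 8)))
        out = mp.aggregate_grid(g, 4)
        assert out.values.mean() == pytest.approx(g.values.mean(), abs=1e-12)

    def test_missing_ignored_and_propagated(self):
        vals = np.array([[1.0, np.nan], [np.nan, np.nan]])
        out = mp.aggregate_grid(mp.Grid(vals), 2)
        assert out.values[0, 0] == pytest.approx(1.0)
        all_missing = mp.aggregate_grid(mp.Grid(np.full((2, 2), np.nan)), 2)
        assert np.isnan(all_missing.values[0, 0])

    def test_edge_blocks_use_available_cells(self):
        g = mp.Grid(np.arange(6.0).reshape(2, 3))
        out = mp.aggregate_grid(g, 2)
        assert out.shape == (1, 2)
        assert out.values[0, 1] == pytest.approx((2.0 + 5.0) / 2)

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            mp.aggregate_grid(mp.Grid(np.ones((2, 2))), 0)


class TestResample:
    def test_identity_target(self, rng):
        g = mp.Grid(rng.standard_normal((4, 4)), cell_size=5.0)
        out = mp.resample_grid(g, 5.0)
        assert np.array_equal(out.values, g.values)

    def test_constant_stays_constant(self):
        g = mp.Grid(np.full((9, 9), 3.7), cell_size=1.0)
        for target, method in [(2.5, "block_mean"), (3.0, "nearest")]:
            out = mp.resample_grid(g, target, method=method)
            assert np.allclose(out.values, 3.7)

    def test_integer_multiple_equals_aggregate(self, rng):
        g = mp.Grid(rng.standard_normal((6, 6)), cell_size=1.0)
        out = mp.resample_grid(g, 3.0, method="block_mean")
        agg = mp.aggregate_grid(g, 3)
        assert out.values == pytest.approx(agg.values, abs=1e-12)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            mp.resample_grid(mp.Grid(np.ones((2, 2)), cell_size=2.0), 1.0)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            mp.resample_grid(mp.Grid(np.ones((2, 2))), 0.0)


class TestRFEnsemble:
    def test_constant_response(self, rng):
        X = rng.standard_normal((30, 3))
        with pytest.warns(UserWarning):
            model = mp.fit_rf_ensemble(X, np.full(30, 2.5), trees=20, replicates=2, seed=0)
        assert model.predict(X) == pytest.approx(np.full(30, 2.5))

    def test_determinism(self, rng):
        X = rng.standard_normal((60, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        p1 = mp.fit_rf_ensemble(X, y, trees=25, replicates=3, seed=7).predict(X)
        p2 = mp.fit_rf_ensemble(X, y, trees=25, replicates=3, seed=7).predict(X)
        assert np.array_equal(p1, p2)

    def test_replicate_order_invariance(self, rng):
        X = rng.standard_normal((60, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        model = mp.fit_rf_ensemble(X, y, trees=25, replicates=4, seed=7)
        shuffled = mp.RFEnsemble(
            forests=model.forests[::-1], predictors=model.predictors,
            oob_r2=model.oob_r2, trees=model.trees, replicates=model.replicates,
        )
        assert model.predict(X) == pytest.approx(shuffled.predict(X), abs=1e-12)

    def test_strong_signal_recovery(self, rng):
        X = rng.standard_normal((500, 4))
        y = 2.0 * X[:, 0] + rng.normal(0, 0.01, 500)
        model = mp.fit_rf_ensemble(X[:400], y[:400], trees=100, replicates=2, seed=1)
        stats = mp.validate_pred_obs(model.predict(X[400:]), y[400:])
        assert stats.r2 > 0.9

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            mp.fit_rf_ensemble(rng.standard_normal((10, 2)), np.ones(10))

    def test_missing_rejected(self, rng):
        X = rng.standard_normal((30, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            mp.fit_rf_ensemble(X, np.ones(30))


class TestPermutationImportance:
    def test_constant_column_importance_zero(self, rng):
        X = np.column_stack([rng.standard_normal(100), np.ones(100)])
        y = X[:, 0] + rng.normal(0, 0.05, 100)
        model = mp.fit_rf_ensemble(X, y, trees=30, replicates=2, seed=0)
        imp = mp.permutation_importance(model, X, y, n_perm=9, seed=0, n_repeats=2)
        assert imp["importance"].iloc[1] == 0.0

    def test_driver_recovered(self, rng):
        X = rng.standard_normal((200, 4))
        y = 2.0 * X[:, 0] + rng.normal(0, 0.05, 200)
        model = mp.fit_rf_ensemble(X, y, trees=50, replicates=2, seed=0)
        imp = mp.permutation_importance(model, X, y, n_perm=39, seed=0, n_repeats=3)
        assert imp["importance"].idxmax() == "x0"
        assert imp.loc["x0", "p"] <= 0.05

    def test_noise_predictor_not_significant(self, rng):
        X = rng.standard_normal((150, 3))
        y = 1.5 * X[:, 0] + rng.normal(0, 0.1, 150)
        non_sig = 0
        for k in range(10):
            model = mp.fit_rf_ensemble(X, y, trees=30, replicates=1, seed=k)
            imp = mp.permutation_importance(model, X, y, n_perm=19, seed=k, n_repeats=2)
            non_sig += imp.loc["x2", "p"] > 0.05
        assert non_sig >= 9


class TestMahalanobis:
    def test_training_mean_unmasked(self, rng):
        T = rng.standard_normal((200, 3))
        d2 = mp.mahalanobis_sq(T.mean(axis=0, keepdims=True), T)
        assert d2[0] == pytest.approx(0.0, abs=1e-10)

    def test_extreme_outlier_masked(self, rng):
        T = rng.standard_normal((500, 3))
        layers = {
            f"x{j}": mp.Grid(np.array([[T[:, j].mean(), T[:, j].mean() + (10.0 if j == 0 else 0.0)]]))
            for j in range(3)
        }
        mask = mp.mahalanobis_mask(layers, T, alpha=0.95)
        assert mask.values[0, 0] == 0.0  # at the mean
        assert mask.values[0, 1] == 1.0  # 10 SD away

    def test_missing_cell_masked(self, rng):
        T = rng.standard_normal((100, 2))
        layers = {
            "a": mp.Grid(np.array([[0.0, np.nan]])),
            "b": mp.Grid(np.array([[0.0, 0.0]])),
        }
        mask = mp.mahalanobis_mask(layers, T)
        assert mask.values[0, 1] == 1.0

    def test_monotone_in_alpha(self, rng):
        T = rng.standard_normal((300, 3))
        P = rng.standard_normal((20, 20, 3))
        layers = {f"x{j}": mp.Grid(P[:, :, j]) for j in range(3)}
        masked = [
            mp.mahalanobis_mask(layers, T, alpha=a).values.sum() for a in (0.5, 0.8, 0.95, 0.99)
        ]
        assert masked == sorted(masked, reverse=True)

    def test_tail_rate_calibration(self, rng):
        # fresh draws from the training MVN are masked at ~ 1 - alpha
        d = 4
        T = rng.standard_normal((4000, d))
        P = rng.standard_normal((8000, d))
        d2 = mp.mahalanobis_sq(P, T)
        rate = np.mean(d2 > chi2.ppf(0.95, d))
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_singular_covariance_pseudo_inverse(self, rng):
        x = rng.standard_normal(100)
        T = np.column_stack([x, x])  # rank 1
        d2 = mp.mahalanobis_sq(T.mean(axis=0, keepdims=True), T)
        assert np.isfinite(d2[0])


class TestStandardize:
    def test_three_values(self):
        out = mp.standardize01(mp.Grid(np.array([[2.0, 4.0, 6.0]])))
        assert out.values == pytest.approx(np.array([[0.0, 0.5, 1.0]]))

    def test_min_zero_max_one(self, rng):
        out = mp.standardize01(mp.Grid(rng.standard_normal((6, 6))))
        assert np.nanmin(out.values) == pytest.approx(0.0)
        assert np.nanmax(out.values) == pytest.approx(1.0)

    def test_constant_grid_warns_zero(self):
        with pytest.warns(UserWarning):
            out = mp.standardize01(mp.Grid(np.full((3, 3), 5.0)))
        assert np.all(out.values == 0.0)

    def test_idempotent(self, rng):
        once = mp.standardize01(mp.Grid(rng.standard_normal((5, 5))))
        twice = mp.standardize01(once)
        assert twice.values == pytest.approx(once.values, abs=1e-12)

    def test_masked_cells_nan(self, rng):
        g = mp.Grid(rng.standard_normal((2, 2)))
        mask = g.with_values(np.array([[0.0, 1.0], [0.0, 0.0]]))
        out = mp.standardize01(g, mask)
        assert np.isnan(out.values[0, 1])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            mp.standardize01(mp.Grid(np.full((2, 2), np.nan)))


class TestValidation:
    def test_perfect_agreement(self, rng):
        x = rng.standard_normal(50)
        s = mp.validate_pred_obs(x, x)
        assert (s.slope, s.intercept, s.r2) == pytest.approx((1.0, 0.0, 1.0), abs=1e-12)

    def test_constant_offset(self, rng):
        x = rng.standard_normal(50)
        s = mp.validate_pred_obs(x, x + 2.0)
        assert s.slope == pytest.approx(1.0, abs=1e-10)
        assert s.intercept == pytest.approx(2.0, abs=1e-10)
        assert s.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal(80)
        y = 0.7 * x + rng.standard_normal(80)
        s = mp.validate_pred_obs(x, y)
        D = np.column_stack([np.ones(80), x])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        resid = y - D @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert s.intercept == pytest.approx(beta[0], abs=1e-10)
        assert s.slope == pytest.approx(beta[1], abs=1e-10)
        assert s.r2 == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mp.validate_pred_obs(np.ones(10), np.arange(10.0))


class TestScenarios:
    def test_equal_maps_equivalent(self, rng):
        g = mp.Grid(rng.uniform(0, 1, (4, 4)))
        out = mp.compare_scenarios(g, g.with_values(g.values.copy()))
        assert np.all(out.values == 0.0)

    def test_shifted_high_dependent(self, rng):
        low = mp.Grid(rng.uniform(0, 0.4, (4, 4)))
        high = low.with_values(low.values + 0.5)
        out = mp.compare_scenarios(low, high)
        assert np.all(out.values == 1.0)

    def test_antisymmetric(self, rng):
        low = mp.Grid(rng.uniform(0, 1, (5, 5)))
        high = mp.Grid(rng.uniform(0, 1, (5, 5)))
        a = mp.compare_scenarios(low, high)
        b = mp.compare_scenarios(high, low)
        assert a.values == pytest.approx(-b.values, abs=1e-12)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            mp.compare_scenarios(mp.Grid(np.ones((2, 2))), mp.Grid(np.ones((3, 3))))


class TestGridIO:
    def test_round_trip(self, tmp_path, rng):
        vals = rng.standard_normal((4, 5))
        vals[1, 2] = np.nan
        g = mp.Grid(vals, cell_size=2.5, origin=(10.0, -4.0))
        path = tmp_path / "grid.csv"
        mp.write_grid(g, path)
        back = mp.read_grid(path)
        assert back.cell_size == g.cell_size
        assert back.origin == g.origin
        np.testing.assert_allclose(back.values, g.values, atol=1e-15)

    def test_predict_grid_propagates_missing(self, rng):
        X = rng.standard_normal((60, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        model = mp.fit_rf_ensemble(X, y, trees=20, replicates=2, seed=0)
        a = rng.standard_normal((3, 3))
        a[0, 0] = np.nan
        layers = {"x0": mp.Grid(a), "x1": mp.Grid(rng.standard_normal((3, 3)))}
        pred = mp.predict_grid(model, layers)
        assert np.isnan(pred.values[0, 0])
        assert np.isfinite(pred.values[1, 1])
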