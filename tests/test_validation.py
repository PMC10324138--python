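import math

import numpy as np
import pytest

from pcmlab.validation import (
    gt_criteria,
    internal_metrics,
    leverage_ad,
    regression_metrics,
    theoretical_bounds,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: plain summation loops, no vectorization
# ---------------------------------------------------------------------------


def brute_force_metrics(y_obs, y_pred, y_train_mean, train_variance):
    n = len(y_obs)
    mean_obs = sum(y_obs) / n
    mean_pred = sum(y_pred) / n
    press = sum((o - p) ** 2 for o, p in zip(y_obs, y_pred))
    ss_obs = sum((o - mean_obs) ** 2 for o in y_obs)
    cov = sum((o - mean_obs) * (p - mean_pred) for o, p in zip(y_obs, y_pred))
    var_p = sum((p - mean_pred) ** 2 for p in y_pred)
    r2 = (cov / math.sqrt(ss_obs * var_p)) ** 2
    k = sum(o * p for o, p in zip(y_obs, y_pred)) / sum(p * p for p in y_pred)
    r2_0 = 1 - sum((o - k * p) ** 2 for o, p in zip(y_obs, y_pred)) / ss_obs
    return {
        "r2_test": r2,
        "k_slope": k,
        "r2_0_test": r2_0,
        "q2_f1": 1 - press / sum((o - y_train_mean) ** 2 for o in y_obs),
        "q2_f2": 1 - press / ss_obs,
        "q2_f3": 1 - (press / n) / train_variance,
        "rmse_test": math.sqrt(press / n),
        "mae": sum(abs(o - p) for o, p in zip(y_obs, y_pred)) / n,
    }


class TestRegressionMetrics:
    def test_perfect_prediction_limits(self, rng):
        y = rng.normal(7, 1, size=20)
        rep = regression_metrics(y, y.copy(), y_train_mean=7.0, train_variance=1.0)
        assert rep.r2_test == pytest.approx(1.0, abs=1e-12)
        assert rep.r2_0_test == pytest.approx(1.0, abs=1e-12)
        assert rep.q2_f2 == pytest.approx(1.0, abs=1e-12)
        assert rep.k_slope == pytest.approx(1.0, abs=1e-12)
        assert rep.rmse_test == 0.0
        assert rep.mae == 0.0
        assert rep.criteria_pass["overall"]

    def test_hand_computed_example(self):
        rep = regression_metrics(
            np.array([6.0, 7.0, 8.0]),
            np.array([6.5, 7.0, 7.5]),
            y_train_mean=7.0,
            train_variance=1.0,
        )
        assert rep.rmse_test == pytest.approx(math.sqrt(1 / 6), abs=1e-12)
        assert rep.mae == pytest.approx(1 / 3, abs=1e-12)
        assert rep.k_slope == pytest.approx(148 / 147.5, abs=1e-12)

    def test_null_model_q2f2_zero(self, rng):
        y = rng.normal(size=15)
        pred = np.full(15, y.mean())
        rep = regression_metrics(y, pred, y_train_mean=0.0, train_variance=1.0)
        assert rep.q2_f2 == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            y = rng.normal(7, 1.2, size=n)
            pred = y + rng.normal(0, 0.6, size=n)
            mean_tr = float(rng.normal(7, 0.3))
            var_tr = float(rng.uniform(0.5, 2.0))
            rep = regression_metrics(y, pred, mean_tr, var_tr)
            oracle = brute_force_metrics(list(y), list(pred), mean_tr, var_tr)
            for key, expected in oracle.items():
                assert getattr(rep, key) == pytest.approx(expected, abs=1e-10), key

    def test_metric_inequalities(self, rng):
        y = rng.normal(size=30)
        pred = y + rng.normal(0, 0.5, size=30)
        rep = regression_metrics(y, pred, 0.0, 1.0)
        assert rep.mae <= rep.rmse_test
        assert rep.rmse_test >= 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics(np.ones(5), np.arange(5.0), 0.0, 1.0)


class TestGTCriteria:
    def test_slope_boundary_fails(self, rng):
        y = rng.normal(7, 1, size=20)
        rep = regression_metrics(y, y.copy(), 7.0, 1.0)
        rep.k_slope = 1.2
        flags = gt_criteria(rep)
        assert not flags["k_slope"]
        assert not flags["overall"]

    def test_reference_magnitudes_pass(self):
        # a ratio of a few 1e-4 with slope within a few 1e-4 of unity passes
        rep = regression_metrics(
            np.array([6.0, 7.0, 8.0, 6.5, 7.5]),
            np.array([6.0, 7.0, 8.0, 6.5, 7.5]),
            7.0,
            1.0,
        )
        rep.r2_test, rep.r2_0_test, rep.k_slope = 0.62, 0.62 * (1 - 0.0003), 1.0005
        flags = gt_criteria(rep)
        assert flags["r2_ratio"] and flags["k_slope"] and flags["overall"]
        assert rep.criterion_ratio == pytest.approx(0.0003, abs=1e-9)

    def test_zero_r2_fails_with_reason(self):
        rep = regression_metrics(
            np.array([6.0, 7.0, 8.0]), np.array([6.5, 7.0, 7.5]), 7.0, 1.0
        )
        rep.r2_test = 0.0
        flags = gt_criteria(rep)
        assert not flags["r2_ratio"]
        assert "reason" in str(flags)


class TestTheoreticalBounds:
    def test_sigma_zero_exact(self, rng):
        y = rng.normal(7, 1, size=50)
        b = theoretical_bounds(y, sigma=0.0, n_sim=50, seed=1)
        assert b.r2_0_max_mean == pytest.approx(1.0, abs=1e-15)
        assert b.rmse_min_mean == pytest.approx(0.0, abs=1e-15)

    def test_rmse_floor_tracks_sigma(self, rng):
        y = rng.normal(7, 1, size=94)
        b = theoretical_bounds(y, sigma=0.5, n_sim=1000, seed=2)
        assert b.rmse_min_mean == pytest.approx(0.5, rel=0.05)

    def test_monotone_in_sigma(self, rng):
        y = rng.normal(7, 1, size=60)
        bounds = [theoretical_bounds(y, sigma=s, n_sim=400, seed=3) for s in (0.2, 0.5, 0.8)]
        r2_means = [b.r2_0_max_mean for b in bounds]
        rmse_means = [b.rmse_min_mean for b in bounds]
        assert r2_means[0] > r2_means[1] > r2_means[2]
        assert rmse_means[0] < rmse_means[1] < rmse_means[2]

    def test_deterministic_under_seed(self, rng):
        y = rng.normal(size=30)
        a = theoretical_bounds(y, sigma=0.4, n_sim=100, seed=9)
        b = theoretical_bounds(y, sigma=0.4, n_sim=100, seed=9)
        assert a.to_dict() == b.to_dict()


class TestLeverageAD:
    def test_single_column_hat_values(self):
        X = np.array([[1.0], [0.0], [-1.0]])
        ad = leverage_ad(X, X, np.zeros(3))
        np.testing.assert_allclose(ad.leverage, [0.5, 0.0, 0.5], atol=1e-12)
        assert ad.train_leverage_sum == pytest.approx(1.0, abs=1e-12)
        assert ad.design_rank == 1

    def test_h_star_arithmetic(self, rng):
        X = rng.standard_normal((100, 10))
        ad = leverage_ad(X, X, rng.normal(size=100))
        assert ad.h_star == pytest.approx(0.3, abs=1e-15)

    def test_trace_equals_rank_even_when_deficient(self, rng):
        base = rng.standard_normal((40, 3))
        X = np.column_stack([base, base[:, 0] + base[:, 1]])  # rank 3, p = 4
        ad = leverage_ad(X, X, rng.normal(size=40))
        assert ad.design_rank == 3
        assert ad.train_leverage_sum == pytest.approx(3.0, abs=1e-8)

    def test_flags_consistent_with_thresholds(self, rng):
        Xt = rng.standard_normal((50, 4))
        Xq = np.vstack([Xt, 10 * np.ones((1, 4))])  # one far-outside point
        res = rng.normal(0, 1, size=51)
        res[0] = 10.0  # force one residual outlier
        ad = leverage_ad(Xt, Xq, res, training_residuals=res[:50])
        for h, s, flag in zip(ad.leverage, ad.std_residual, ad.flags):
            if abs(s) > 3:
                assert flag == "outlier"
            elif h > ad.h_star:
                assert flag == "influential"
            else:
                assert flag == "inside"
        assert "outlier" in ad.flags
        assert ad.flags[-1] in ("influential", "outlier")


class TestInternalMetrics:
    def test_pooled_oof_r2(self, rng):
        y = rng.normal(size=40)
        oof = y + rng.normal(0, 0.3, size=40)
        r2, rmse = internal_metrics(y, oof)
        assert r2 == pytest.approx(float(np.corrcoef(y, oof)[0, 1]) ** 2, abs=1e-12)
        assert rmse == pytest.approx(float(np.sqrt(np.mean((y - oof) ** 2))), abs=1e-12)
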