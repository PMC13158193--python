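import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nprescribe.models import ModelConfig, fit_yield_model
from nprescribe.preprocess import FeatureMatrix
from nprescribe.uncertainty import (
    CalibrationError,
    IntervalMethodConfig,
    MCDropoutMLP,
    baseline_intervals,
    calibrate,
    conformal_interval,
    conformal_quantile,
    empirical_coverage,
)


def brute_force_quantile(scores, alpha):
    """Smallest score threshold whose rank satisfies the finite-sample
    correction — independent enumeration oracle."""
    scores = sorted(scores)
    n = len(scores)
    r = math.ceil((n + 1) * (1 - alpha))
    if r > n:
        return scores[-1]
    for s in scores:
        if sum(x <= s for x in scores) >= r:
            return s
    return scores[-1]


def _fm(X, y):
    import pandas as pd

    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X=X,
        columns=[f"f{j}" for j in range(X.shape[1])],
        is_onehot=np.zeros(X.shape[1], bool),
        y=np.asarray(y, dtype=float),
        n_rate=X[:, 0],
        index=pd.RangeIndex(len(X)),
    )


class TestConformalQuantile:
    @pytest.mark.parametrize(
        "scores,alpha,expected",
        [
            (list(range(1, 10)), 0.10, 9.0),
            (list(range(1, 100)), 0.10, 90.0),
            ([2, 4, 7, 9], 0.50, 7.0),
        ],
    )
    def test_order_statistic_examples(self, scores, alpha, expected):
        assert conformal_quantile(scores, alpha) == expected

    def test_rank_overflow_falls_back_to_max(self):
        assert conformal_quantile([3.0, 1.0], 0.05) == 3.0

    def test_empty_scores_rejected(self):
        with pytest.raises(CalibrationError):
            conformal_quantile([], 0.1)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 51))
            scores = rng.exponential(1.0, size=n)
            for alpha in (0.5, 0.1, 0.05):
                assert conformal_quantile(scores, alpha) == pytest.approx(
                    brute_force_quantile(list(scores), alpha)
                )

    @given(
        st.lists(st.floats(0, 100), min_size=1, max_size=40),
        st.sampled_from([0.25, 0.1, 0.05]),
    )
    def test_monotone_in_coverage(self, scores, alpha):
        q_lo = conformal_quantile(scores, alpha * 2)
        q_hi = conformal_quantile(scores, alpha)
        assert q_hi >= q_lo


class TestConformalInterval:
    def test_symmetric_expansion(self):
        lo, hi = conformal_interval(10.0, 2.0)
        assert (lo, hi) == (8.0, 12.0)

    def test_degenerate_quantile(self):
        lo, hi = conformal_interval(np.array([1.0, 5.0]), 0.0)
        assert np.array_equal(lo, hi)

    def test_constant_width_across_points(self, rng):
        yhat = rng.normal(size=50)
        lo, hi = conformal_interval(yhat, 1.3)
        assert np.allclose(hi - lo, 2.6)

    def test_nesting_across_levels(self, rng):
        scores = rng.exponential(1.0, 200)
        q90 = conformal_quantile(scores, 0.10)
        q95 = conformal_quantile(scores, 0.05)
        assert q95 >= q90


class TestEmpiricalCoverage:
    def test_fraction_inside(self):
        y = np.arange(10.0)
        report = empirical_coverage(y - 1, np.where(y < 9, y + 1, y - 0.5), y)
        assert report["coverage"] == 0.9

    def test_infinite_intervals_cover_everything(self, rng):
        y = rng.normal(size=20)
        report = empirical_coverage(np.full(20, -np.inf), np.full(20, np.inf), y)
        assert report["coverage"] == 1.0

    def test_groupwise_summaries(self):
        y = np.zeros(10)
        lo = np.full(10, -1.0)
        hi = np.r_[np.full(5, 1.0), np.array([1, 1, 1, 1, -0.5])]
        groups = ["a"] * 5 + ["b"] * 5
        report = empirical_coverage(lo, hi, y, groups)
        assert report["per_group"]["a"] == 1.0
        assert report["per_group"]["b"] == 0.8
        assert report["worst_group_coverage"] == 0.8
        assert report["mean_group_coverage"] == pytest.approx(0.9)


class TestCalibratedPipelineCoverage:
    def test_coverage_guarantee_on_exchangeable_data(self, rng):
        """Split conformal achieves at least nominal coverage (up to a 3-sigma
        binomial margin) when calibration and test are drawn identically."""
        for alpha in (0.10, 0.05):
            hits = []
            for seed in range(5):
                local = np.random.default_rng(seed)
                X = local.normal(size=(900, 3))
                y = X[:, 0] ** 2 + local.normal(0, 0.5, 900)
                fm_tr = _fm(X[:300], y[:300])
                fm_cal = _fm(X[300:600], y[300:600])
                fm_te = _fm(X[600:], y[600:])
                model = fit_yield_model(
                    ModelConfig(family="tree_ensemble", n_trees=40, seed=seed), fm_tr
                )
                cal = calibrate(model, fm_cal, alpha)
                yhat = model.predict(fm_te)
                rep = empirical_coverage(yhat - cal.q, yhat + cal.q, fm_te.y)
                hits.append(rep["coverage"])
            n_test = 300
            margin = 3 * np.sqrt(alpha * (1 - alpha) / n_test)
            assert np.mean(hits) >= (1 - alpha) - margin


class TestBaselineIntervals:
    def test_quantile_regression_orders_endpoints(self, rng):
        X = rng.normal(size=(400, 2))
        y = X[:, 0] + rng.normal(0, 1 + 0.5 * np.abs(X[:, 1]), 400)
        fm = _fm(X, y)
        lo, hi = baseline_intervals(
            IntervalMethodConfig(method="quantile_regression"), fm, fm, alpha=0.10
        )
        assert np.all(lo <= hi)

    def test_ensemble_zero_dispersion_gives_degenerate_interval(self):
        X = np.ones((60, 1))
        y = np.full(60, 5.0)
        fm = _fm(X, y)
        lo, hi = baseline_intervals(
            IntervalMethodConfig(method="ensemble", ensemble_members=5),
            fm,
            fm,
            alpha=0.10,
            model_cfg=ModelConfig(family="ridge", ridge_alpha=1e-8),
        )
        assert np.allclose(lo, 5.0, atol=1e-6)
        assert np.allclose(hi, 5.0, atol=1e-6)

    def test_dropout_width_shrinks_with_rate(self, rng):
        X = rng.normal(size=(300, 3))
        y = X[:, 0] + rng.normal(0, 0.3, 300)
        fm = _fm(X, y)
        widths = {}
        for p in (1e-5, 0.4):
            lo, hi = baseline_intervals(
                IntervalMethodConfig(method="dropout", dropout_rate=p, epochs=30),
                fm,
                fm,
                alpha=0.10,
            )
            widths[p] = float(np.mean(hi - lo))
        assert widths[1e-5] < widths[0.4]
        assert widths[1e-5] < 0.05 * np.std(y)

    def test_unknown_method_rejected(self, rng):
        fm = _fm(rng.normal(size=(10, 1)), np.zeros(10))
        with pytest.raises(CalibrationError):
            baseline_intervals(
                IntervalMethodConfig(method="conformal"), fm, fm, alpha=0.1
            )


class TestMCDropoutMLP:
    def test_learns_a_simple_function(self, rng):
        X = rng.uniform(-1, 1, size=(400, 2))
        y = 3 * X[:, 0]
        net = MCDropoutMLP(epochs=60, p_drop=0.1, seed=0).fit(X, y)
        draws = net.predict_stochastic(X, n_passes=30, seed=1)
        rmse = np.sqrt(np.mean((draws.mean(axis=0) - y) ** 2))
        assert rmse < 0.5 * np.std(y)

    def test_stochastic_passes_vary(self, rng):
        X = rng.normal(size=(100, 2))
        net = MCDropoutMLP(epochs=10, p_drop=0.3, seed=0).fit(X, X[:, 0])
        draws = net.predict_stochastic(X[:10], n_passes=10, seed=2)
        assert np.std(draws, axis=0).max() > 0
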