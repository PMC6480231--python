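import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from tunnelear.risk import (
    BOUNDARIES,
    LevelIntervals,
    LogisticBoundary,
    LogisticFit,
    SeparationError,
    ThresholdSet,
    build_intervals,
    derive_threshold_set,
    fit_logistic,
    logistic_risk,
    relative_t2_t4_error,
    threshold_from_fit,
)


class TestLogisticRisk:
    def test_midpoint_is_exactly_half(self):
        fit = LogisticFit(alpha=2.017, beta=0.345, p_value=0.025)
        assert logistic_risk(fit.alpha / fit.beta, fit) == pytest.approx(0.5, abs=1e-12)

    def test_low_exposure_low_risk(self):
        fit = LogisticFit(alpha=3.0, beta=0.5, p_value=0.01)
        assert logistic_risk(0.0, fit) < 0.5

    def test_published_i3_t1_threshold_sits_at_half_risk(self, reference):
        fits, thresholds = reference
        # risk at the published threshold 5.84 under the published coefficients
        assert logistic_risk(thresholds["I3"].t1, fits["I3"]["T1"]) == pytest.approx(
            0.5, abs=0.01
        )

    def test_strictly_increasing(self):
        fit = LogisticFit(alpha=2.0, beta=0.3, p_value=0.01)
        xs = np.linspace(-10, 30, 200)
        risks = logistic_risk(xs, fit)
        assert np.all(np.diff(risks) > 0)
        assert np.all((risks > 0) & (risks < 1))

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            LogisticFit(alpha=1.0, beta=-0.1, p_value=0.5)


class TestThresholdFromFit:
    def test_published_i3_coefficients(self):
        assert threshold_from_fit(
            LogisticFit(2.017, 0.345, 0.025)
        ) == pytest.approx(5.85, abs=0.005)
        assert threshold_from_fit(
            LogisticFit(2.190, 0.107, 0.0)
        ) == pytest.approx(20.47, abs=0.005)

    def test_zero_intercept(self):
        assert threshold_from_fit(LogisticFit(0.0, 1.0, 0.5)) == 0.0


class TestThresholdSet:
    @pytest.mark.parametrize(
        "t2, t4, expected_tc",
        [(78.87, 82.74, 80.81), (32.31, 33.63, 32.97), (8.98, 9.10, 9.04)],
    )
    def test_tc_is_mean_of_t2_t4(self, t2, t4, expected_tc):
        ts = ThresholdSet(t1=1.0, t2=t2, t3=1000.0, t4=t4)
        assert ts.tc == pytest.approx(expected_tc, abs=0.005)

    def test_inconsistent_tc_rejected(self):
        with pytest.raises(ValueError, match="tc"):
            ThresholdSet(t1=1.0, t2=10.0, t3=100.0, t4=12.0, tc=13.0)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            ThresholdSet(t1=50.0, t2=10.0, t3=100.0, t4=12.0)

    def test_relative_error(self):
        i1 = ThresholdSet(t1=46.61, t2=78.87, t3=139.87, t4=82.74)
        assert relative_t2_t4_error(i1) == pytest.approx(4.8, abs=0.05)
        i3 = ThresholdSet(t1=5.84, t2=8.98, t3=20.45, t4=9.10)
        assert relative_t2_t4_error(i3) == pytest.approx(1.33, abs=0.01)
        equal = ThresholdSet(t1=1.0, t2=5.0, t3=10.0, t4=5.0)
        assert relative_t2_t4_error(equal) == 0.0

    def test_derive_from_fits(self):
        fits = [
            LogisticFit(5.0, 1.0, 0.01, boundary_id="T1"),
            LogisticFit(10.0, 1.0, 0.01, boundary_id="T2"),
            LogisticFit(20.0, 1.0, 0.01, boundary_id="T3"),
            LogisticFit(11.0, 1.0, 0.01, boundary_id="T4"),
        ]
        ts = derive_threshold_set(fits)
        assert (ts.t1, ts.t2, ts.t3, ts.t4, ts.tc) == (5.0, 10.0, 20.0, 11.0, 10.5)

    def test_derive_requires_all_boundaries(self):
        fits = [LogisticFit(5.0, 1.0, 0.01, boundary_id="T1")]
        with pytest.raises(ValueError, match="boundary"):
            derive_threshold_set(fits)


class TestLevelIntervals:
    def test_published_i1_intervals(self, reference):
        _, thresholds = reference
        table = build_intervals(thresholds["I1"]).as_table()
        assert table["ideal"] == (0.0, 46.61)
        assert table["good"] == (46.61, 80.81)
        assert table["bad"] == (80.81, 139.87)
        assert table["worse"][0] == 139.87 and np.isinf(table["worse"][1])

    def test_partition_covers_positive_axis(self):
        iv = LevelIntervals(t1=1.0, tc=2.0, t3=3.0)
        values = np.concatenate([np.linspace(1e-6, 10, 1000), [1.0, 2.0, 3.0]])
        labels = iv.classify(values)
        assert set(np.unique(labels)) <= {"ideal", "good", "bad", "worse"}
        # lower-closed boundaries
        assert list(iv.classify([0.999, 1.0])) == ["ideal", "good"]
        assert list(iv.classify([2.0, 3.0])) == ["bad", "worse"]

    def test_degenerate_edges_rejected(self):
        with pytest.raises(ValueError):
            LevelIntervals(t1=2.0, tc=2.0, t3=3.0)


class TestReferenceTables:
    def test_published_coefficients(self, reference):
        fits, _ = reference
        fit = fits["I1"]["T1"]
        assert (fit.alpha, fit.beta, fit.p_value) == (5.504, 0.118, 0.002)

    def test_published_thresholds(self, reference):
        _, thresholds = reference
        assert thresholds["I2"].tc == 32.97
        assert thresholds["I1"].t3 == 139.87

    def test_all_fits_significant(self, reference):
        fits, _ = reference
        assert all(
            fits[ind][b].p_value < 0.05 for ind in fits for b in BOUNDARIES
        )

    def test_immutability(self, reference):
        fits, thresholds = reference
        with pytest.raises(Exception):
            fits["I1"]["T1"].alpha = 0.0
        with pytest.raises(Exception):
            thresholds["I1"].t1 = 0.0


def neg_log_likelihood(params, x, y):
    alpha, beta = params
    p = expit(beta * x - alpha)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


class TestFitLogistic:
    def test_symmetric_data_zero_intercept(self):
        x = np.tile([-1.0, 1.0], 50)
        y = np.tile([0.0, 1.0], 50)
        # perfectly separated two-point data is refused; jitter the overlap
        rng = np.random.default_rng(0)
        x = np.concatenate([x, [-0.5, 0.5, 0.5, -0.5]])
        y = np.concatenate([y, [1.0, 0.0, 1.0, 0.0]])
        fit = fit_logistic(x, y)
        assert abs(fit.alpha) < 0.2

    def test_parameter_recovery_within_wald_intervals(self):
        rng = np.random.default_rng(11)
        alpha, beta, n = 5.5, 0.12, 500
        x = rng.uniform(0, 100, n)
        y = (rng.random(n) < expit(beta * x - alpha)).astype(float)
        est = LogisticBoundary().fit(x, y)
        assert abs(est.alpha_ - alpha) <= 1.96 * est.alpha_se_
        assert abs(est.beta_ - beta) <= 1.96 * est.beta_se_

    def test_matches_direct_likelihood_maximisation(self):
        """Newton/IRLS fit equals a Nelder–Mead maximisation of the
        Bernoulli log-likelihood written independently of the solver."""
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 60, 80)
        y = (rng.random(80) < expit(0.2 * x - 4.0)).astype(float)
        fit = fit_logistic(x, y)
        res = minimize(
            neg_log_likelihood,
            x0=[1.0, 0.05],
            args=(x, y),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000},
        )
        assert fit.alpha == pytest.approx(res.x[0], abs=1e-4)
        assert fit.beta == pytest.approx(res.x[1], abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_logistic([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_complete_separation_refused_with_diagnostic(self):
        x = np.concatenate([np.linspace(0, 1, 20), np.linspace(2, 3, 20)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        with pytest.raises(SeparationError, match="separation"):
            fit_logistic(x, y)

    def test_estimator_predict_proba(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 50, 200)
        y = (rng.random(200) < expit(0.3 * x - 6.0)).astype(float)
        est = LogisticBoundary().fit(x, y)
        proba = est.predict_proba([est.threshold_])
        assert proba.shape == (1, 2)
        assert proba[0, 1] == pytest.approx(0.5, abs=1e-9)
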