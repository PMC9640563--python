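import numpy as np
import pytest
import statsmodels.api as sm

from vftrend.regression_models import (
    HUBER_K,
    DegenerateDataError,
    FitResult,
    ModelKind,
    SingularDesignError,
    fit_exponential,
    fit_logistic,
    fit_m_robust,
    fit_model,
    fit_olslr,
    fit_pointwise,
    fit_quadratic,
    huber_objective,
    predict,
)
from vftrend.synthetic_data import make_fixture


def ols_oracle(x, y):
    """Direct 2x2 normal-equation solve."""
    n = len(x)
    A = np.array([[np.sum(x * x), np.sum(x)], [np.sum(x), n]])
    rhs = np.array([np.sum(x * y), np.sum(y)])
    return np.linalg.solve(A, rhs)


def quad_oracle(x, y):
    """Direct 3x3 normal-equation solve on the Vandermonde design."""
    V = np.vander(x, 3)
    return np.linalg.solve(V.T @ V, V.T @ y)


class TestOlslr:
    def test_exact_line(self):
        fit = fit_olslr([0, 1, 2], [30, 29, 28])
        assert fit.params == pytest.approx((-1.0, 30.0))

    def test_two_point_constant(self):
        fit = fit_olslr([0, 1], [5, 5])
        assert fit.params == pytest.approx((0.0, 5.0))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.uniform(0, 8, 5)
            y = rng.uniform(0, 40, 5)
            if np.ptp(x) < 1e-3:
                continue
            np.testing.assert_allclose(fit_olslr(x, y).params, ols_oracle(x, y),
                                       atol=1e-10)

    def test_degenerate_x_raises(self):
        with pytest.raises(SingularDesignError):
            fit_olslr([1.0, 1.0, 1.0], [1, 2, 3])


class TestQuadratic:
    def test_exact_parabola(self):
        x = np.array([0.0, 1, 2, 3])
        fit = fit_quadratic(x, x ** 2 - 2 * x + 1)
        assert fit.params == pytest.approx((1.0, -2.0, 1.0))

    def test_three_points_interpolated_exactly(self):
        x = np.array([0.0, 1.0, 2.5])
        y = np.array([3.0, 7.0, 1.0])
        fit = fit_quadratic(x, y)
        np.testing.assert_allclose(predict(fit, x), y, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.uniform(0, 8, 6)
            y = rng.uniform(0, 40, 6)
            np.testing.assert_allclose(fit_quadratic(x, y).params,
                                       quad_oracle(x, y), atol=1e-8)

    def test_fewer_than_three_distinct_x_raises(self):
        with pytest.raises(SingularDesignError):
            fit_quadratic([0.0, 0.0, 1.0], [1, 2, 3])


class TestMRobust:
    def test_equals_ols_on_exact_line(self):
        x = np.arange(5, dtype=float)
        y = 30 - 1.2 * x
        robust = fit_m_robust(x, y)
        ols = fit_olslr(x, y)
        assert robust.params == pytest.approx(ols.params, abs=1e-12)

    def test_downweights_gross_outlier(self):
        x = np.array([0.0, 1, 2, 3, 4])
        y = np.array([30.0, 29, 28, 27, 6])  # last test grossly depressed
        slope_rob = fit_m_robust(x, y).params[0]
        slope_ols = fit_olslr(x, y).params[0]
        assert abs(slope_rob - (-1.0)) < abs(slope_ols - (-1.0))

    def test_matches_ols_when_no_residual_exceeds_huber_band(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 6, 9)
        for _ in range(20):
            y = 25 - 0.5 * x + rng.normal(0, 0.5, x.size)
            fit = fit_m_robust(x, y)
            r = y - (fit.params[0] * x + fit.params[1])
            if np.all(np.abs(r) <= HUBER_K * fit.scale):
                np.testing.assert_allclose(fit.params, fit_olslr(x, y).params,
                                           atol=1e-6)

    def test_huber_objective_not_worse_than_ols(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            x = np.sort(rng.uniform(0, 8, 8))
            y = 30 - x + rng.normal(0, 1, 8)
            y[rng.integers(0, 8)] -= rng.uniform(5, 20)
            robust = fit_m_robust(x, y)
            ols = fit_olslr(x, y)
            obj_rob = huber_objective(x, y, robust.params, robust.scale)
            obj_ols = huber_objective(x, y, ols.params, robust.scale)
            assert obj_rob <= obj_ols + 1e-9

    def test_agrees_with_statsmodels_rlm(self):
        """Independent cross-check against RLM with the same Huber recipe."""
        x = np.array([0.0, 0.6, 1.3, 1.9, 2.5, 3.1, 3.8, 4.4])
        y = np.array([30.0, 29.1, 28.6, 27.9, 12.0, 26.4, 25.2, 24.9])
        fit = fit_m_robust(x, y)
        rlm = sm.RLM(y, sm.add_constant(x),
                     M=sm.robust.norms.HuberT(t=HUBER_K)).fit()
        assert fit.params[0] == pytest.approx(rlm.params[1], abs=1e-3)
        assert fit.params[1] == pytest.approx(rlm.params[0], abs=1e-3)


class TestNonlinearModels:
    def test_exponential_recovers_generating_parameters(self):
        x = np.arange(5, dtype=float)
        y = np.exp(-0.1 * x + 3.0)
        fit = fit_exponential(x, y)
        assert fit.params == pytest.approx((-0.1, 3.0), abs=1e-6)

    def test_exponential_constant(self):
        x = np.arange(4, dtype=float)
        fit = fit_exponential(x, np.full(4, np.exp(2.0)))
        assert fit.params == pytest.approx((0.0, 2.0), abs=1e-6)

    def test_exponential_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_exponential([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])

    def test_exponential_objective_not_worse_than_initializer(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 7, 10)
        for _ in range(10):
            y = np.clip(np.exp(-0.15 * x + 2.5) + rng.normal(0, 2, x.size), 0, 40)
            fit = fit_exponential(x, y)
            p0 = np.polyfit(x, np.log(np.maximum(y, 0.1)), 1)
            sse_fit = np.sum((np.exp(fit.params[0] * x + fit.params[1]) - y) ** 2)
            sse_init = np.sum((np.exp(p0[0] * x + p0[1]) - y) ** 2)
            assert sse_fit <= sse_init + 1e-9

    def test_logistic_midpoint_constant(self):
        x = np.arange(5, dtype=float)
        fit = fit_logistic(x, np.full(5, 20.0))
        assert fit.params == pytest.approx((0.0, 0.0), abs=1e-8)
        assert predict(fit, 10.0) == pytest.approx(20.0)

    def test_logistic_recovers_generating_parameters(self):
        x = np.arange(7, dtype=float)
        y = 40.0 / (1.0 + np.exp(0.5 * x - 2.0))
        fit = fit_logistic(x, y)
        assert fit.params == pytest.approx((0.5, -2.0), abs=1e-4)

    def test_logistic_objective_not_worse_than_initializer(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 7, 10)
        for _ in range(10):
            y = np.clip(40 / (1 + np.exp(0.4 * x - 1.5)) + rng.normal(0, 2, x.size),
                        0, 40)
            fit = fit_logistic(x, y)
            yp = y / 40
            ypc = np.clip(yp, 0.01, 0.99)
            p0 = np.polyfit(x, -np.log(ypc / (1 - ypc)), 1)
            sse_fit = np.sum((1 / (1 + np.exp(fit.params[0] * x + fit.params[1])) - yp) ** 2)
            sse_init = np.sum((1 / (1 + np.exp(p0[0] * x + p0[1])) - yp) ** 2)
            assert sse_fit <= sse_init + 1e-9


class TestPredict:
    def test_line_evaluation(self):
        fit = FitResult(ModelKind.OLSLR, (-1.0, 30.0))
        assert predict(fit, 3.0) == 27.0

    def test_floor_truncation_with_clamp(self):
        fit = FitResult(ModelKind.OLSLR, (-10.0, 5.0))
        assert predict(fit, 2.0, clamp=True) == 0.0
        assert predict(fit, 2.0, clamp=False) == -15.0

    def test_exponential_and_logistic_bounded_without_clamp(self):
        x = np.linspace(-50, 50, 101)
        exp_fit = FitResult(ModelKind.EXPONENTIAL, (-0.5, 3.0))
        log_fit = FitResult(ModelKind.LOGISTIC, (0.7, -2.0))
        assert np.all(predict(exp_fit, x) >= 0)
        out = predict(log_fit, x)
        assert np.all(out >= 0) and np.all(out <= 40)


class TestPointwise:
    def test_noise_free_linear_recovers_all_slopes(self, noise_free_cohort):
        prepared, truth, _ = noise_free_cohort
        series = prepared[0]
        i = truth.eye_ids.index(series.eye_id)
        pw = fit_pointwise(series, 5, ModelKind.OLSLR)
        slopes = np.array([f.params[0] for f in pw.fits])
        np.testing.assert_allclose(slopes, truth.point_slopes[i], atol=1e-9)

    @pytest.mark.parametrize("model", list(ModelKind))
    def test_constant_eye_predicts_constant(self, model):
        series = make_fixture("constant", level=25.0)
        pw = fit_pointwise(series, 5, model)
        np.testing.assert_allclose(pw.predict(10.0), 25.0, atol=1e-6)

    def test_location_matches_manual_fit(self, small_noisy_cohort):
        prepared, _, _ = small_noisy_cohort
        series = prepared[0]
        pw = fit_pointwise(series, 7, ModelKind.OLSLR)
        x = series.times()[:7]
        y = series.sensitivity_matrix()[:7, 7]
        manual = fit_olslr(x, y)
        assert pw.fits[7].params == pytest.approx(manual.params, abs=1e-10)

    def test_window_bounds_enforced(self, small_noisy_cohort):
        prepared, _, _ = small_noisy_cohort
        with pytest.raises(ValueError):
            fit_pointwise(prepared[0], 4, ModelKind.OLSLR)
        with pytest.raises(ValueError):
            fit_pointwise(prepared[0], 13, ModelKind.OLSLR)

    def test_blind_locations_predict_the_floor_for_exponential(self):
        series = make_fixture("constant", level=0.0)
        pw = fit_pointwise(series, 5, ModelKind.EXPONENTIAL)
        np.testing.assert_allclose(pw.predict(5.0), 0.0, atol=1e-6)


def test_fitters_are_deterministic():
    rng = np.random.default_rng(9)
    x = np.sort(rng.uniform(0, 7, 8))
    y = np.clip(28 - 0.8 * x + rng.normal(0, 2, 8), 0, 40)
    for model in ModelKind:
        a = fit_model(model, x, y)
        b = fit_model(model, x, y)
        assert a.params == b.params
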