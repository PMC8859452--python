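"""Penalized spline smoother: oracle limits, REML selection, linearity."""

import numpy as np
import pandas as pd
import pytest

from suvtraj import PenalizedSplineRegressor, RateFunction, evaluate_rate, fit_rate_function
from suvtraj.exceptions import DegenerateDesignError, DomainError, InsufficientDataError
from suvtraj.spline import (
    build_knots,
    design_matrix,
    greville_abscissae,
    reml_score,
    second_difference_penalty,
    select_smoothing,
)


def quadratic_rate(x):
    # logistic-derived rate: r (S - A)(K - S)/(K - A) with r=0.3, A=0.8, K=1.9
    return 0.3 * (x - 0.8) * (1.9 - x) / 1.1


def slopes_frame(x, y):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(x))],
            "level": x,
            "rate": y,
            "interval_length": np.ones(len(x)),
        }
    )


class TestFitOracles:
    def test_constant_data_reproduced(self):
        x = np.linspace(0.8, 2.0, 41)
        est = PenalizedSplineRegressor().fit(x, np.full(41, 0.05))
        grid = np.linspace(0.8, 2.0, 200)
        np.testing.assert_allclose(est.predict(grid), 0.05, atol=1e-6)

    def test_noise_free_quadratic_recovered(self):
        x = np.linspace(0.85, 1.85, 200)
        y = quadratic_rate(x)
        est = PenalizedSplineRegressor().fit(x, y)
        assert np.max(np.abs(est.predict(x) - y)) < 0.002

    def test_lambda_infinity_equals_ols_line(self, rng):
        x = rng.uniform(0.8, 1.9, 200)
        y = quadratic_rate(x) + rng.normal(0, 0.02, 200)
        est = PenalizedSplineRegressor(lam=1e8).fit(x, y)
        line = np.polyval(np.polyfit(x, y, 1), x)
        assert np.max(np.abs(est.predict(x) - line)) < 1e-3

    def test_lambda_zero_interpolates_distinct_points(self):
        x = np.linspace(0.8, 1.9, 15)
        y = 0.05 * np.sin(3 * x)
        est = PenalizedSplineRegressor(lam=1e-10, knot_strategy="unique").fit(x, y)
        assert np.max(np.abs(est.predict(x) - y)) < 1e-6

    def test_insufficient_and_degenerate_designs(self):
        with pytest.raises(InsufficientDataError):
            fit_rate_function(slopes_frame(np.arange(5.0), np.arange(5.0)))
        with pytest.raises(DegenerateDesignError):
            fit_rate_function(slopes_frame(np.ones(20), np.ones(20)))


class TestSmoothingSelection:
    def _design(self, x):
        knots = build_knots(x, 40)
        B = design_matrix(x, knots)
        D = second_difference_penalty(greville_abscissae(knots))
        return B, D

    def test_pure_noise_shrinks_to_null_space(self, rng):
        x = rng.uniform(0.8, 1.9, 500)
        y = rng.normal(0, 1.0, 500)
        est = PenalizedSplineRegressor().fit(x, y)
        assert est.edf_ <= 4.0

    def test_efs_and_grid_agree(self, rng):
        x = rng.uniform(0.8, 1.9, 400)
        y = quadratic_rate(x) + rng.normal(0, 0.02, 400)
        B, D = self._design(x)
        lam_e, info_e = select_smoothing(B, y, D, method="efs")
        lam_g, info_g = select_smoothing(B, y, D, method="grid")
        assert abs(info_e["reml"] - info_g["reml"]) / abs(info_g["reml"]) < 1e-3

    def test_efs_matches_independent_fine_grid(self, rng):
        """Fixed-point REML optimum agrees with a brute-force scan of the
        restricted likelihood recomputed here."""
        x = rng.uniform(0.8, 1.9, 300)
        y = quadratic_rate(x) + rng.normal(0, 0.03, 300)
        B, D = self._design(x)
        lam, info = select_smoothing(B, y, D, method="efs")
        S = D.T @ D
        grid = np.logspace(-8, 12, 600)
        scores = [reml_score(l, B, y, S) for l in grid]
        best = min(scores)
        assert (info["reml"] - best) / abs(best) < 1e-2

    def test_signal_gets_more_edf_than_noise(self, rng):
        x = rng.uniform(0.8, 1.9, 400)
        strong = PenalizedSplineRegressor().fit(
            x, 0.3 * np.sin(6 * x) + rng.normal(0, 0.005, 400)
        )
        noise = PenalizedSplineRegressor().fit(x, rng.normal(0, 0.3, 400))
        assert strong.edf_ > noise.edf_
        assert strong.edf_ >= 2.0 and noise.edf_ >= 2.0


class TestLinearSmoother:
    def test_additivity_in_response(self, rng):
        x = rng.uniform(0.8, 1.9, 150)
        y1 = quadratic_rate(x)
        y2 = rng.normal(0, 0.05, 150)
        lam = 3.7
        fit = lambda y: PenalizedSplineRegressor(lam=lam).fit(x, y).coef_
        np.testing.assert_allclose(fit(y1 + y2), fit(y1) + fit(y2), atol=1e-10)

    def test_row_order_invariance(self, rng):
        x = rng.uniform(0.8, 1.9, 150)
        y = quadratic_rate(x) + rng.normal(0, 0.02, 150)
        perm = rng.permutation(150)
        a = PenalizedSplineRegressor().fit(x, y)
        b = PenalizedSplineRegressor().fit(x[perm], y[perm])
        grid = np.linspace(0.8, 1.9, 50)
        np.testing.assert_allclose(a.predict(grid), b.predict(grid), atol=1e-8)


class TestEvaluation:
    def fitted(self):
        x = np.linspace(0.8, 1.9, 100)
        slopes = slopes_frame(x, quadratic_rate(x))
        return fit_rate_function(slopes)

    def test_clamp_below_domain(self):
        f = self.fitted()
        assert f(0.5) == pytest.approx(f(f.domain[0]))

    def test_error_mode_raises(self):
        f = self.fitted()
        with pytest.raises(DomainError):
            evaluate_rate(f, 0.5, extrapolation="error")

    def test_linear_mode_continues_slope(self):
        f = self.fitted()
        lo = f.domain[0]
        v = evaluate_rate(f, lo - 0.01, extrapolation="linear")
        approx_slope = (f(lo + 1e-4) - f(lo)) / 1e-4
        assert v == pytest.approx(f(lo) - 0.01 * approx_slope, abs=1e-4)

    def test_evaluation_equals_basis_matrix_product(self):
        f = self.fitted()
        grid = np.linspace(f.domain[0], f.domain[1], 400)
        direct = design_matrix(grid, f.knots) @ f.coefficients
        np.testing.assert_allclose(f(grid), direct, atol=1e-12)

    def test_json_round_trip(self, tmp_path):
        f = self.fitted()
        p = tmp_path / "rate.json"
        f.to_json(p)
        g = RateFunction.from_json(p)
        grid = np.linspace(*f.domain, 100)
        np.testing.assert_allclose(f(grid), g(grid), atol=0)
        assert g.lam == f.lam and g.edf == f.edf
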