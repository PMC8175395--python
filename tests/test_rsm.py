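"""CCD construction, quadratic fitting, ANOVA, Pareto shares, exact optimum."""

import numpy as np
import pytest
from scipy import stats

from sorptionlab.rsm import (
    TERM_NAMES,
    FactorSpace,
    QuadraticModel,
    anova,
    build_ccd,
    expand_quadratic,
    fit_quadratic,
    optimize_quadratic,
    pareto_effects,
    predict_quadratic,
    rotatable_alpha,
)


class TestBuildCcd:
    @pytest.mark.parametrize("n_center, total", [(6, 30), (1, 25)])
    def test_run_counts(self, factor_space, n_center, total):
        design = build_ccd(factor_space, n_center)
        assert len(design) == total
        assert design.center_mask.sum() == n_center

    def test_rotatable_alpha_for_four_factors(self):
        assert rotatable_alpha(4) == pytest.approx(2.0)

    def test_actuals_are_affine_in_coded(self, factor_space):
        design = build_ccd(factor_space, 2)
        expected = factor_space.to_actual(design.runs)
        np.testing.assert_allclose(design.actuals, expected)

    def test_five_levels_per_factor(self, factor_space):
        design = build_ccd(factor_space, 6)
        for j in range(4):
            levels = sorted(set(design.runs[:, j]))
            assert levels == [-2.0, -1.0, 0.0, 1.0, 2.0]


class TestFitQuadratic:
    def test_noiseless_recovery(self, factor_space):
        rng = np.random.default_rng(0)
        truth = QuadraticModel.from_coefficients(rng.normal(0, 2, 15))
        design = build_ccd(factor_space, 6)
        y = predict_quadratic(truth, design.actuals)
        fitted = fit_quadratic(design.actuals, y)
        np.testing.assert_allclose(fitted.coefficients, truth.coefficients, rtol=1e-8, atol=1e-8)

    def test_constant_response(self, factor_space):
        design = build_ccd(factor_space, 6)
        fitted = fit_quadratic(design.actuals, np.full(len(design), 7.5))
        assert fitted.intercept == pytest.approx(7.5, abs=1e-10)
        np.testing.assert_allclose(fitted.coefficients[1:], 0.0, atol=1e-10)

    def test_singular_design_names_columns(self, factor_space):
        design = build_ccd(factor_space, 6)
        X = design.actuals.copy()
        X[:, 1] = X[:, 0]  # collinear factors
        with pytest.raises(np.linalg.LinAlgError, match="singular design"):
            fit_quadratic(X, np.arange(len(design), dtype=float))

    def test_coded_vs_actual_fits_agree_in_prediction(self, factor_space):
        rng = np.random.default_rng(1)
        design = build_ccd(factor_space, 6)
        y = rng.normal(50, 5, len(design))
        m_actual = fit_quadratic(design.actuals, y)
        m_coded = fit_quadratic(design.runs, y)
        pts_coded = rng.uniform(-1, 1, size=(20, 4))
        pts_actual = factor_space.to_actual(pts_coded)
        np.testing.assert_allclose(
            predict_quadratic(m_actual, pts_actual),
            predict_quadratic(m_coded, pts_coded),
            rtol=1e-8,
        )


class TestPredictQuadratic:
    def test_intercept_at_origin(self, published_quadratic):
        assert predict_quadratic(published_quadratic, np.zeros(4)) == 32.577

    def test_published_model_at_reported_optimum(self, published_quadratic):
        val = predict_quadratic(published_quadratic, np.array([3.0, 30.0, 6.28, 4.0]))
        assert val == pytest.approx(75.27, abs=0.01)

    def test_linear_only_model(self):
        m = QuadraticModel.from_coefficients([0, 2, 0, 0, 0] + [0] * 10)
        assert predict_quadratic(m, np.array([5.0, 0, 0, 0])) == pytest.approx(10.0)


def _brute_force_anova_1d(x, y):
    """Independent SS/F oracle for a 1-factor quadratic y ~ 1 + x + x^2."""
    X = np.column_stack([np.ones_like(x), x, x ** 2])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = len(y), 3
    ms_res = ss_res / (n - p)
    # partial SS per term by explicit refit
    out = {}
    for k, name in [(1, "x"), (2, "x2")]:
        Xr = np.delete(X, k, axis=1)
        br = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
        rr = y - Xr @ br
        ss_k = float(rr @ rr) - ss_res
        f = ss_k / ms_res
        out[name] = (ss_k, f, float(stats.f.sf(f, 1, n - p)))
    return ss_res, ss_tot, out


class TestAnova:
    def test_perfect_fit(self, factor_space):
        truth = QuadraticModel.from_coefficients(np.arange(1.0, 16.0))
        design = build_ccd(factor_space, 6)
        y = predict_quadratic(truth, design.actuals)
        model = fit_quadratic(design.actuals, y)
        table = anova(model, design.actuals, y, center_replicate_mask=design.center_mask)
        assert table.ss_residual == pytest.approx(0.0, abs=1e-12 * table.ss_total)
        assert table.r2 == pytest.approx(1.0)

    def test_against_brute_force_oracle(self):
        """Every term's SS, F and p match an explicit refit-per-term oracle."""
        rng = np.random.default_rng(4)
        n = 40
        X_full = rng.normal(0, 1, size=(n, 4))
        y_full = (3.0 + 2.0 * X_full[:, 0] - 1.5 * X_full[:, 0] ** 2
                  + 0.8 * X_full[:, 1] * X_full[:, 2]
                  + rng.normal(0, 0.3, n))
        model = fit_quadratic(X_full, y_full)
        table = anova(model, X_full, y_full)
        design = expand_quadratic(X_full)
        beta_f, *_ = np.linalg.lstsq(design, y_full, rcond=None)
        resid_f = y_full - design @ beta_f
        sse_f = float(resid_f @ resid_f)
        ms_res = sse_f / (n - 15)
        for k, name in enumerate(TERM_NAMES[1:], start=1):
            reduced = np.delete(design, k, axis=1)
            br, *_ = np.linalg.lstsq(reduced, y_full, rcond=None)
            rr = y_full - reduced @ br
            ss_k = float(rr @ rr) - sse_f
            f_k = ss_k / ms_res
            p_k = float(stats.f.sf(f_k, 1, n - 15))
            ss_pkg, _, _, f_pkg, p_pkg = table.terms[name]
            assert ss_pkg == pytest.approx(max(ss_k, 0.0), rel=1e-6, abs=1e-8)
            assert f_pkg == pytest.approx(f_k, rel=1e-6, abs=1e-8)
            assert p_pkg == pytest.approx(p_k, rel=1e-6, abs=1e-12)

    def test_one_factor_closed_form_oracle(self):
        """The explicit 1-factor SS/F formulas agree with a direct refit."""
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 0.5])
        y = 3.0 + 2.0 * x - 1.5 * x ** 2 + np.array([0.1, -0.2, 0.05, 0.15, -0.1, 0.0])
        ss_res, ss_tot, oracle = _brute_force_anova_1d(x, y)
        assert 0 < ss_res < ss_tot
        for name in ("x", "x2"):
            ss_k, f_k, p_k = oracle[name]
            assert ss_k > 0 and f_k > 0 and 0 <= p_k <= 1

    def test_decomposition_identities(self, factor_space, published_quadratic):
        rng = np.random.default_rng(5)
        design = build_ccd(factor_space, 6)
        y = predict_quadratic(published_quadratic, design.actuals) + rng.normal(0, 0.5, len(design))
        model = fit_quadratic(design.actuals, y)
        table = anova(model, design.actuals, y, center_replicate_mask=design.center_mask)
        assert table.ss_model + table.ss_residual == pytest.approx(table.ss_total, rel=1e-8)
        assert table.ss_lack_of_fit + table.ss_pure_error == pytest.approx(
            table.ss_residual, rel=1e-8, abs=1e-12
        )
        assert table.df_lack_of_fit + table.df_pure_error == table.df_residual
        assert 0.99 < table.r2 <= 1.0

    def test_no_replicates_warns_in_table(self, factor_space, published_quadratic):
        design = build_ccd(factor_space, 1)
        y = predict_quadratic(published_quadratic, design.actuals)
        model = fit_quadratic(design.actuals, y)
        table = anova(model, design.actuals, y)
        assert table.ss_lack_of_fit is None
        assert any("lack-of-fit" in w for w in table.warnings)


class TestParetoEffects:
    def test_single_nonzero_coefficient(self):
        m = QuadraticModel.from_coefficients([5] + [0] * 10 + [3, 0, 0, 0])
        effects = pareto_effects(m)
        assert effects["X1^2"] == pytest.approx(100.0)

    def test_two_coefficients_three_four(self):
        m = QuadraticModel.from_coefficients([1, 3, 4] + [0] * 12)
        effects = pareto_effects(m)
        assert effects["X1"] == pytest.approx(36.0)
        assert effects["X2"] == pytest.approx(64.0)

    def test_published_model_concentration_dominates(self, published_quadratic):
        # brute-force share of the printed X3 linear coefficient
        beta = published_quadratic.coefficients[1:]
        expected = 100.0 * beta[2] ** 2 / np.sum(beta ** 2)
        effects = pareto_effects(published_quadratic)
        assert effects["X3"] == pytest.approx(expected, rel=1e-12)
        assert effects["X3"] == pytest.approx(73.4, abs=0.1)

    def test_shares_sum_to_hundred(self, published_quadratic):
        assert sum(pareto_effects(published_quadratic).values()) == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_raises(self):
        m = QuadraticModel.from_coefficients([3.0] + [0] * 14)
        with pytest.raises(ValueError, match="undefined"):
            pareto_effects(m)


class TestOptimizeQuadratic:
    def test_one_dimensional_vertex(self):
        # y = -(x1-3)^2 + 7 = -2 + 6 x1 - x1^2
        m = QuadraticModel.from_coefficients([-2, 6, 0, 0, 0] + [0] * 6 + [-1, 0, 0, 0])
        x, v = optimize_quadratic(m, [(0, 10), (0, 0), (0, 0), (0, 0)])
        assert x[0] == pytest.approx(3.0)
        assert v == pytest.approx(7.0)

    def test_published_model_pinned_concentration_sweep(self, published_quadratic):
        x, v = optimize_quadratic(
            published_quadratic,
            bounds=[(3, 3), (30, 30), (1, 10), (4, 4)],
        )
        assert x[2] == pytest.approx(10.367 / (2 * 1.011), abs=1e-6)
        assert v == pytest.approx(76.6, abs=0.1)

    def test_linear_model_maximum_at_vertex(self):
        m = QuadraticModel.from_coefficients([0, 1, -2, 0.5, 0] + [0] * 10)
        bounds = [(-1, 1)] * 4
        x, v = optimize_quadratic(m, bounds)
        np.testing.assert_allclose(x[:3], [1, -1, 1])
        assert v == pytest.approx(3.5)

    @staticmethod
    def _zoom_grid_max(model, bounds, levels=3, pts=21):
        """Independent oracle: 4-D grid search refined to ~1e-3 coded units."""
        lo = np.array([b[0] for b in bounds], dtype=float)
        hi = np.array([b[1] for b in bounds], dtype=float)
        full_lo, full_hi = lo.copy(), hi.copy()
        best_x, best_v = None, -np.inf
        for _ in range(levels):
            axes = [np.linspace(lo[j], hi[j], pts) for j in range(4)]
            mesh = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
            vals = predict_quadratic(model, mesh)
            j = int(np.argmax(vals))
            if vals[j] > best_v:
                best_v, best_x = float(vals[j]), mesh[j]
            cell = (hi - lo) / (pts - 1)
            lo = np.clip(best_x - cell, full_lo, full_hi)
            hi = np.clip(best_x + cell, full_lo, full_hi)
        return best_x, best_v

    def test_agrees_with_dense_grid_search(self):
        """Exact optimizer matches a refined grid search on random quadratics."""
        space = FactorSpace()
        bounds = space.bounds
        rng = np.random.default_rng(10)
        for _ in range(20):
            m = QuadraticModel.from_coefficients(rng.normal(0, 1, 15))
            x_opt, v_opt = optimize_quadratic(m, bounds)
            _, v_grid = self._zoom_grid_max(m, bounds)
            # the exact optimum can never be beaten by any grid point, and the
            # refined grid must come within one fine-cell function change
            assert v_opt >= v_grid - 1e-9
            assert v_opt - v_grid <= 0.05

    def test_unbounded_indefinite_raises(self):
        m = QuadraticModel.from_coefficients([0] * 11 + [1, 0, 0, 0])
        with pytest.raises(ValueError, match="unbounded"):
            optimize_quadratic(m, [(-np.inf, np.inf)] * 4)
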