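"""Constrained fits, hysteresis statistics, and Arrhenius recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ch4hyst.errors import (
    ConstraintError,
    DegenerateFitError,
    InsufficientDataError,
    UndefinedAreaError,
)
from ch4hyst.hysteresis import (
    BOLTZMANN_EV,
    BranchFit,
    compare_functional_forms,
    constrained_polyfit,
    constrained_polyfit_kkt,
    eval_curve,
    fit_alternative_intercept,
    fit_arrhenius,
    fit_branch,
    hysteresis_area,
    hysteresis_mean,
)

polyval = np.polynomial.polynomial.polyval


class TestConstrainedPolyfit:
    def test_data_on_constrained_line(self):
        coef = constrained_polyfit([1, 2, 3], [2, 4, 6], 1, [(0.0, 0.0)])
        assert coef[0] == pytest.approx(0.0, abs=1e-12)
        assert coef[1] == pytest.approx(2.0, rel=1e-12)

    def test_single_point_closed_form(self):
        """Degree 2 with both anchors: a = sum(x'y')/sum(x'^2) gives -0.8 for (5, 30)."""
        coef = constrained_polyfit([5.0], [30.0], 2, [(0.0, 0.0), (10.0, 20.0)])
        assert coef[2] == pytest.approx(-0.8, rel=1e-9)
        assert polyval(5.0, coef) == pytest.approx(30.0, rel=1e-9)
        assert polyval(0.0, coef) == pytest.approx(0.0, abs=1e-9)
        assert polyval(10.0, coef) == pytest.approx(20.0, rel=1e-9)

    def test_conflicting_constraints(self):
        with pytest.raises(ConstraintError):
            constrained_polyfit([1.0], [1.0], 2, [(0.0, 0.0), (0.0, 1.0)])

    def test_duplicate_consistent_constraint_deduped(self):
        coef = constrained_polyfit([1, 2, 3], [2, 4, 6], 1, [(0.0, 0.0), (0.0, 0.0)])
        assert coef[1] == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("degree,n_fix", [(1, 1), (2, 1), (2, 2), (3, 2), (5, 2)])
    def test_agrees_with_lagrange_oracle(self, degree, n_fix):
        rng = np.random.default_rng(42 + degree * 10 + n_fix)
        for _ in range(20):
            x = rng.uniform(-5, 5, size=12)
            y = rng.normal(0, 3, size=12)
            xf = rng.uniform(-5, 5, size=n_fix)
            while len(np.unique(np.round(xf, 6))) < n_fix:
                xf = rng.uniform(-5, 5, size=n_fix)
            fixed = list(zip(xf, rng.normal(0, 3, size=n_fix)))
            a = constrained_polyfit(x, y, degree, fixed)
            b = constrained_polyfit_kkt(x, y, degree, fixed)
            np.testing.assert_allclose(a, b, rtol=1e-7, atol=1e-7)

    @given(
        st.integers(min_value=1, max_value=5),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_constraints_always_satisfied(self, degree, seed):
        rng = np.random.default_rng(seed)
        n_fix = int(rng.integers(1, min(degree + 1, 2) + 1))
        x = rng.uniform(-4, 4, size=10)
        y = rng.normal(0, 2, size=10)
        xf = np.linspace(-3, 3, n_fix) + rng.normal(0, 0.1, n_fix)
        yf = rng.normal(0, 2, size=n_fix)
        coef = constrained_polyfit(x, y, degree, list(zip(xf, yf)))
        for x0, y0 in zip(xf, yf):
            assert polyval(x0, coef) == pytest.approx(y0, rel=1e-9, abs=1e-9)

    def test_degree_too_low_for_constraints(self):
        with pytest.raises(ValueError):
            constrained_polyfit([1.0], [1.0], 0, [(0.0, 0.0), (1.0, 1.0)])


class TestFitBranch:
    def test_exact_model_recovery(self):
        T = np.arange(2.0, 20.0, 2.0)
        truth = BranchFit(0.5, 20.0, 100.0, "earlier", len(T), 0.0)
        F = eval_curve(truth, T)
        fit = fit_branch(T, F, 20.0, 100.0)
        assert fit.a_hys == pytest.approx(0.5, abs=1e-10)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_linear_data_gives_zero_curvature(self):
        T = np.linspace(1, 15, 30)
        fit = fit_branch(T, 5.0 * T, 15.0, 75.0)
        assert fit.a_hys == pytest.approx(0.0, abs=1e-10)

    def test_noisy_fit_matches_grid_search_oracle(self):
        """The closed-form a_hys lands on the SSE minimum of a brute-force grid."""
        rng = np.random.default_rng(7)
        T = rng.uniform(1, 19, size=80)
        truth = BranchFit(-0.3, 20.0, 100.0, "later", 80, 0.0)
        F = eval_curve(truth, T) + rng.normal(0, 5.0, size=80)
        fit = fit_branch(T, F, 20.0, 100.0)

        grid = np.linspace(-2.0, 2.0, 4001)
        sse = [
            np.sum((eval_curve(BranchFit(a, 20.0, 100.0, "later", 80, 0.0), T) - F) ** 2)
            for a in grid
        ]
        a_grid = grid[int(np.argmin(sse))]
        assert abs(fit.a_hys - a_grid) <= (grid[1] - grid[0])
        assert abs(fit.a_hys - (-0.3)) < 0.1  # well inside the noise band

    def test_equivalent_to_constrained_polyfit(self):
        rng = np.random.default_rng(3)
        T = rng.uniform(0.5, 18, size=40)
        F = rng.normal(50, 20, size=40)
        fit = fit_branch(T, F, 18.0, 90.0)
        coef = constrained_polyfit(T, F, 2, [(0.0, 0.0), (18.0, 90.0)])
        assert fit.a_hys == pytest.approx(coef[2], rel=1e-9)

    def test_nonpositive_tmax_rejected(self):
        with pytest.raises(ValueError):
            fit_branch([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], -1.0, 5.0)

    def test_empty_branch_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_branch([], [], 10.0, 5.0)


class TestEvalCurve:
    def test_forced_intercept_and_anchor(self):
        fit = BranchFit(0.73, 17.0, 42.0, "earlier", 10, 0.0)
        assert eval_curve(fit, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert eval_curve(fit, 17.0) == pytest.approx(42.0, rel=1e-12)

    def test_hand_evaluated_polynomial(self):
        # a=1, t_max=10, f_at_tmax=100: linear coefficient (100/10 - 10) = 0
        fit = BranchFit(1.0, 10.0, 100.0, "full", 5, 0.0)
        assert eval_curve(fit, 5.0) == pytest.approx(25.0)

    @given(
        st.floats(min_value=-2, max_value=2),
        st.floats(min_value=1, max_value=40),
        st.floats(min_value=-500, max_value=500),
    )
    @settings(max_examples=50, deadline=None)
    def test_anchor_invariance(self, a, t_max, f_at_tmax):
        """Every branch fit passes through (0,0) and (t_max, f_at_tmax) exactly."""
        fit = BranchFit(a, t_max, f_at_tmax, "full", 1, 0.0)
        scale = max(abs(f_at_tmax), 1.0)
        assert abs(eval_curve(fit, 0.0)) <= 1e-9 * scale
        assert abs(eval_curve(fit, t_max) - f_at_tmax) <= 1e-9 * scale


class TestHysteresisArea:
    def test_identical_curves_zero(self):
        f1 = BranchFit(0.4, 12.0, 60.0, "earlier", 5, 0.0)
        f2 = BranchFit(0.4, 12.0, 60.0, "later", 5, 0.0)
        assert hysteresis_area(f1, f2) == 0.0

    def test_worked_closed_form(self):
        fe = BranchFit(1.0, 10.0, 100.0, "earlier", 5, 0.0)
        fl = BranchFit(-1.0, 10.0, 100.0, "later", 5, 0.0)
        assert hysteresis_area(fe, fl) == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_antisymmetry(self):
        fe = BranchFit(0.7, 15.0, 80.0, "earlier", 5, 0.0)
        fl = BranchFit(-0.2, 15.0, 80.0, "later", 5, 0.0)
        assert hysteresis_area(fe, fl) == pytest.approx(-hysteresis_area(fl, fe))

    def test_numerator_matches_numeric_integration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t_max = rng.uniform(5, 30)
            f_tm = rng.uniform(10, 300)
            a_e, a_l = rng.uniform(-1, 1, size=2)
            fe = BranchFit(a_e, t_max, f_tm, "earlier", 5, 0.0)
            fl = BranchFit(a_l, t_max, f_tm, "later", 5, 0.0)
            grid = np.linspace(0, t_max, 100_000)
            numeric = np.trapezoid(eval_curve(fl, grid) - eval_curve(fe, grid), grid)
            closed = (a_e - a_l) * t_max**3 / 6.0
            assert closed == pytest.approx(numeric, rel=1e-6, abs=1e-9)

    def test_scale_equivariance(self):
        """Scaling all fluxes by c>0 leaves H_A unchanged and scales H_mu by c."""
        fe = BranchFit(0.5, 20.0, 100.0, "earlier", 5, 0.0)
        fl = BranchFit(-0.1, 20.0, 100.0, "later", 5, 0.0)
        c = 3.7
        fe_s = BranchFit(0.5 * c, 20.0, 100.0 * c, "earlier", 5, 0.0)
        fl_s = BranchFit(-0.1 * c, 20.0, 100.0 * c, "later", 5, 0.0)
        assert hysteresis_area(fe_s, fl_s) == pytest.approx(hysteresis_area(fe, fl), rel=1e-12)
        Fe, Fl = np.array([10.0, 20.0]), np.array([30.0, 50.0])
        assert hysteresis_mean(c * Fe, c * Fl) == pytest.approx(c * hysteresis_mean(Fe, Fl))

    def test_temperature_shift_is_not_an_invariance(self):
        """The 0 degC anchor is physical: shifting the driver changes H_A."""
        rng = np.random.default_rng(2)
        T = rng.uniform(2, 18, 40)
        Fe = 2.0 * T + 0.1 * T**2 + rng.normal(0, 2, 40)
        Fl = 3.0 * T + rng.normal(0, 2, 40)
        def h(offset):
            t = T + offset
            t_max, f_tm = 20.0 + offset, 100.0
            return hysteresis_area(
                fit_branch(t, Fe, t_max, f_tm, "earlier"),
                fit_branch(t, Fl, t_max, f_tm, "later"),
            )
        assert h(0.0) != pytest.approx(h(5.0), rel=1e-3)

    def test_undefined_when_both_curves_zero(self):
        fe = BranchFit(0.0, 10.0, 0.0, "earlier", 5, 0.0)
        fl = BranchFit(0.0, 10.0, 0.0, "later", 5, 0.0)
        with pytest.raises(UndefinedAreaError):
            hysteresis_area(fe, fl)

    def test_measured_max_normalization_toggle(self):
        fe = BranchFit(1.0, 10.0, 100.0, "earlier", 5, 0.0)
        fl = BranchFit(-1.0, 10.0, 100.0, "later", 5, 0.0)
        ha = hysteresis_area(fe, fl, normalization="measured_max", measured_abs_max=200.0)
        assert ha == pytest.approx(1.0 / 6.0, rel=1e-12)

    def test_interior_vertex_enters_denominator(self):
        # later curve peaks inside (0, t_max) above the anchor flux
        fe = BranchFit(0.0, 10.0, 10.0, "earlier", 5, 0.0)
        fl = BranchFit(-2.0, 10.0, 10.0, "later", 5, 0.0)
        # F_l(T) = -2T^2 + 21T has vertex at T=5.25, F=55.125
        ha = hysteresis_area(fe, fl)
        expected = (0.0 - (-2.0)) * 1000.0 / 6.0 / (55.125 * 10.0)
        assert ha == pytest.approx(expected, rel=1e-12)


class TestHysteresisMean:
    def test_arithmetic_and_swap(self):
        early = np.full(10, 30.0)
        later = np.full(12, 50.0)
        assert hysteresis_mean(early, later) == pytest.approx(20.0)
        assert hysteresis_mean(later, early) == pytest.approx(-20.0)
        assert hysteresis_mean(early, early) == 0.0

    def test_empty_branch_rejected(self):
        with pytest.raises(DegenerateFitError):
            hysteresis_mean([], [1.0])


class TestAlternativeIntercept:
    def test_mean_near_zero_constraint(self):
        T = np.linspace(1, 19, 30)
        truth = BranchFit(0.4, 20.0, 100.0, "full", 30, 0.0, intercept=5.0)
        F = eval_curve(truth, T)
        fit, fallback = fit_alternative_intercept(T, F, 20.0, 100.0, [4.0, 6.0])
        assert not fallback
        assert fit.intercept == pytest.approx(5.0)
        assert fit.a_hys == pytest.approx(0.4, abs=1e-10)
        assert eval_curve(fit, 0.0) == pytest.approx(5.0)

    def test_fallback_to_origin(self):
        T = np.linspace(1, 19, 30)
        fit, fallback = fit_alternative_intercept(T, 5 * T, 20.0, 100.0, [])
        assert fallback
        assert fit.intercept == 0.0


class TestArrhenius:
    def test_exact_generative_recovery(self):
        T = np.arange(278.0, 301.0)
        F = np.exp(30.0 - 1.0 / (BOLTZMANN_EV * T))
        fit = fit_arrhenius(T, F)
        assert fit.e_a == pytest.approx(1.0, abs=1e-8)
        assert fit.epsilon == pytest.approx(30.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_flux_zero_energy(self):
        T = np.linspace(275, 300, 20)
        fit = fit_arrhenius(T, np.full(20, 12.0))
        assert fit.e_a == pytest.approx(0.0, abs=1e-10)

    def test_noisy_matches_independent_ols_oracle(self):
        rng = np.random.default_rng(19)
        T = rng.uniform(275, 303, size=100)
        F = np.exp(25.0 - 0.8 / (BOLTZMANN_EV * T)) * rng.lognormal(0, 0.3, 100)
        fit = fit_arrhenius(T, F)
        # independent normal-equations solve
        x = -1.0 / (BOLTZMANN_EV * T)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(F))
        assert fit.e_a == pytest.approx(beta[0], rel=1e-9)
        assert fit.epsilon == pytest.approx(beta[1], rel=1e-9)

    def test_nonpositive_flux_excluded_and_counted(self):
        T = np.linspace(275, 300, 10)
        F = np.full(10, 5.0)
        F[[2, 7]] = -1.0
        fit = fit_arrhenius(T, F)
        assert fit.n_points == 8
        assert fit.n_excluded == 2

    def test_too_few_positive_days(self):
        with pytest.raises(InsufficientDataError):
            fit_arrhenius([280.0, 285.0, 290.0], [1.0, -1.0, 2.0])

    def test_zero_temperature_variance(self):
        with pytest.raises(DegenerateFitError):
            fit_arrhenius(np.full(5, 280.0), np.full(5, 3.0))


class TestCompareFunctionalForms:
    def test_true_model_wins_and_nesting(self):
        rng = np.random.default_rng(5)
        T = rng.uniform(1, 19, 50)
        truth = BranchFit(0.3, 20.0, 120.0, "full", 50, 0.0)
        F = eval_curve(truth, T)
        table = compare_functional_forms(T, F, 20.0, 120.0)
        assert table["poly2"] <= table["poly1"] + 1e-9
        assert table["poly2"] <= 1e-9
        # nested constrained polynomials can only improve
        assert table["poly5"] <= table["poly3"] + 1e-9
        assert table["poly3"] <= table["poly2"] + 1e-9

    def test_noisy_table_matches_brute_force_refits(self):
        rng = np.random.default_rng(9)
        T = rng.uniform(1, 19, 50)
        F = 3.0 * T + rng.normal(0, 4, 50)
        table = compare_functional_forms(T, F, 20.0, 60.0)
        for d in (1, 2, 3, 5):
            coef = constrained_polyfit(T, F, d, [(0.0, 0.0), (20.0, 60.0)])
            rmse = np.sqrt(np.mean((polyval(T, coef) - F) ** 2))
            assert table[f"poly{d}"] == pytest.approx(rmse, rel=1e-9)

    def test_per_form_errors_recorded_not_raised(self):
        # all-negative flux: Arrhenius has no positive days; polynomials still fit
        T = np.linspace(1, 19, 20)
        F = -np.ones(20)
        table = compare_functional_forms(T, F, 20.0, -1.0)
        assert isinstance(table["arrhenius"], str) and "error" in table["arrhenius"]
        assert isinstance(table["poly2"], float)
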