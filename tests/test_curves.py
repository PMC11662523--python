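"""Exposure-response curves, MMT search, reduction and extrapolation."""

import numpy as np
import pytest

import heatmort as hm
from heatmort.curves import Z975
from heatmort.fit import FitResult


def toy_fit(toy_spec, beta=None, vcov_scale=0.01):
    p = toy_spec.df_var * toy_spec.df_lag
    if beta is None:
        beta = 0.1 * (np.arange(p) + 1.0)
    return FitResult(beta=np.asarray(beta, float),
                     vcov=vcov_scale * np.eye(p),
                     n_strata_total=1, n_strata_informative=1,
                     loglik=0.0, converged=True)


class TestPredictCumulative:
    def test_rr_one_at_reference(self, toy_spec):
        curve = hm.predict_cumulative(toy_fit(toy_spec), toy_spec,
                                      [2.0, 5.0, 8.0], reference=5.0)
        i = 1
        assert curve.rr[i] == 1.0
        assert curve.se[i] == 0.0
        assert curve.rr_lo[i] == curve.rr_hi[i] == 1.0

    def test_matches_hand_computed_basis_difference(self, toy_spec):
        fit = toy_fit(toy_spec)
        grid, ref = np.array([1.0, 4.0, 9.0]), 5.0
        curve = hm.predict_cumulative(fit, toy_spec, grid, ref)
        vb = toy_spec.var_basis()
        s = toy_spec.lag_basis_matrix().sum(axis=0)
        for i, t in enumerate(grid):
            dv = vb([t])[0] - vb([ref])[0]
            row = np.concatenate([s[k] * dv for k in range(toy_spec.df_lag)])
            assert curve.log_rr[i] == pytest.approx(row @ fit.beta, abs=1e-12)
            se = np.sqrt(row @ fit.vcov @ row)
            assert curve.se[i] == pytest.approx(se, abs=1e-12)

    def test_ci_halfwidth_scales_sqrt2_with_doubled_vcov(self, toy_spec):
        grid, ref = [1.0, 9.0], 5.0
        c1 = hm.predict_cumulative(toy_fit(toy_spec, vcov_scale=0.01),
                                   toy_spec, grid, ref)
        c2 = hm.predict_cumulative(toy_fit(toy_spec, vcov_scale=0.02),
                                   toy_spec, grid, ref)
        np.testing.assert_allclose(c2.se, np.sqrt(2) * c1.se, rtol=1e-12)

    def test_empty_grid_rejected(self, toy_spec):
        with pytest.raises(ValueError):
            hm.predict_cumulative(toy_fit(toy_spec), toy_spec, [], 5.0)


class TestReduceToOverall:
    def test_lag_free_reduction_is_identity(self):
        spec = hm.KnotSpec(var_knots=(5.0,), var_boundary=(0, 10), lag_max=0)
        fit = toy_fit(spec)
        red = hm.reduce_to_overall(fit, spec)
        np.testing.assert_allclose(red.eta, fit.beta)
        np.testing.assert_allclose(red.vcov_eta, fit.vcov)

    def test_reduced_curve_equals_full_prediction(self, small_model):
        grid = np.linspace(*small_model.spec.var_boundary, 50)
        ref = small_model.mmt.mmt
        full = hm.predict_cumulative(small_model.fit, small_model.spec,
                                     grid, ref)
        red = hm.curve_from_reduced(small_model.reduced, grid, ref)
        np.testing.assert_allclose(red.log_rr, full.log_rr, atol=1e-8)
        np.testing.assert_allclose(red.se, full.se, atol=1e-8)

    def test_vcov_eta_matches_monte_carlo(self, toy_spec):
        """Delta covariance of the reduction equals the empirical covariance
        of reduced predictions under draws of beta."""
        fit = toy_fit(toy_spec, vcov_scale=0.05)
        red = hm.reduce_to_overall(fit, toy_spec)
        rng = np.random.default_rng(42)
        draws = rng.multivariate_normal(fit.beta, fit.vcov, size=10_000)
        s = toy_spec.lag_basis_matrix().sum(axis=0)
        M = np.kron(s[None, :], np.eye(toy_spec.df_var)).reshape(
            toy_spec.df_var, -1)
        emp = np.cov((draws @ M.T).T)
        np.testing.assert_allclose(red.vcov_eta, emp, rtol=0.05, atol=1e-4)


class TestFindMMT:
    def test_fine_grid_scan_oracle(self, small_model):
        window = tuple(np.percentile(small_model.season_temps, [1, 99]))
        coarse = hm.find_mmt(small_model.fit, small_model.spec, window,
                             step=0.1)
        fine = hm.find_mmt(small_model.fit, small_model.spec, window,
                           step=0.01)
        assert abs(coarse.mmt - fine.mmt) <= 0.1 + 1e-9

    def test_monotone_curve_flags_boundary(self):
        spec = hm.KnotSpec(var_knots=(), var_boundary=(0, 10), lag_max=0)
        fit = toy_fit(spec, beta=[1.0])  # strictly increasing curve
        res = hm.find_mmt(fit, spec, (2.0, 8.0))
        assert res.at_boundary
        assert res.mmt == pytest.approx(2.0)

    def test_bad_window_rejected(self, toy_spec):
        with pytest.raises(ValueError):
            hm.find_mmt(toy_fit(toy_spec), toy_spec, (5.0, 5.0))


class TestPercentIncrease:
    @pytest.mark.parametrize("rr,expected", [(5.13, 413.0), (1.62, 62.0),
                                             (1.0, 0.0)])
    def test_closed_form(self, rr, expected):
        assert hm.percent_increase(rr) == pytest.approx(expected)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            hm.percent_increase(0.0)
        with pytest.raises(ValueError):
            hm.percent_increase(-2.0)


class TestExtrapolation:
    def test_unchanged_within_range(self, small_model):
        red = small_model.reduced
        temps = np.linspace(*red.spec.var_boundary, 20)
        np.testing.assert_allclose(
            hm.extrapolate_curve(red, temps, 20.0),
            hm.cumulative_log_rr(red, temps, 20.0))

    def test_equally_spaced_beyond_boundary_is_linear(self, small_model):
        red = small_model.reduced
        hi = red.spec.var_boundary[1]
        temps = hi + np.arange(1, 6)
        vals = hm.extrapolate_curve(red, temps, 20.0)
        np.testing.assert_allclose(np.diff(vals, 2), 0.0, atol=1e-9)

    def test_tail_slope_matches_boundary_derivative(self, small_model):
        red = small_model.reduced
        hi = red.spec.var_boundary[1]
        delta = 1e-4
        inner_slope = (hm.cumulative_log_rr(red, [hi], 20.0)[0]
                       - hm.cumulative_log_rr(red, [hi - delta], 20.0)[0]) / delta
        outer_slope = (hm.extrapolate_curve(red, [hi + 1.0], 20.0)[0]
                       - hm.extrapolate_curve(red, [hi], 20.0)[0])
        assert outer_slope == pytest.approx(inner_slope, rel=1e-3)


class TestLagResponse:
    def test_rr_one_at_reference_every_lag(self, toy_spec):
        rr, lo, hi = hm.lag_response(toy_fit(toy_spec), toy_spec, 5.0, 5.0)
        np.testing.assert_allclose(rr, 1.0)
        np.testing.assert_allclose(lo, 1.0)
        np.testing.assert_allclose(hi, 1.0)

    def test_lag_sum_equals_cumulative(self, toy_spec):
        fit = toy_fit(toy_spec)
        rr, _, _ = hm.lag_response(fit, toy_spec, 8.0, 5.0)
        cum = hm.predict_cumulative(fit, toy_spec, [8.0], 5.0)
        assert np.log(rr).sum() == pytest.approx(cum.log_rr[0], abs=1e-10)

    def test_lag0_direct_dot_product(self, toy_spec):
        fit = toy_fit(toy_spec)
        vb = toy_spec.var_basis()
        dv = vb([8.0])[0] - vb([5.0])[0]
        c0 = toy_spec.lag_basis_matrix()[0]
        row = np.concatenate([c0[k] * dv for k in range(toy_spec.df_lag)])
        rr, _, _ = hm.lag_response(fit, toy_spec, 8.0, 5.0)
        assert np.log(rr[0]) == pytest.approx(row @ fit.beta, abs=1e-12)


class TestAffineInvariance:
    def test_fahrenheit_fit_gives_same_rr(self, small_panel):
        """Refitting with the exposure affinely rescaled (degC -> degF) must
        reproduce the same RR curve at corresponding temperatures."""
        model_c = hm.fit_heat_model(small_panel, knot_percentiles=(50, 90),
                                    lag_max=3)
        panel_f = small_panel.copy()
        panel_f["tmean"] = panel_f["tmean"] * 1.8 + 32.0
        model_f = hm.fit_heat_model(panel_f, knot_percentiles=(50, 90),
                                    lag_max=3)
        grid_c = np.linspace(18, 28, 21)
        ref_c = 20.0
        rr_c = hm.curve_from_reduced(model_c.reduced, grid_c, ref_c).rr
        rr_f = hm.curve_from_reduced(model_f.reduced, grid_c * 1.8 + 32,
                                     ref_c * 1.8 + 32).rr
        np.testing.assert_allclose(rr_f, rr_c, rtol=1e-6)
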