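"""Forward attributable fractions/numbers and Monte Carlo empirical CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import heatmort as hm
from heatmort.curves import ReducedFit

from conftest import make_panel


def linear_reduced(slope=0.1, var=0.0, boundary=(0.0, 40.0)):
    """Reduced fit whose cumulative log RR is exactly slope*(T - ref)."""
    spec = hm.KnotSpec(var_knots=(), var_boundary=boundary, lag_max=0)
    vb = spec.var_basis()
    col_slope = (vb([boundary[1]])[0, 0] - vb([boundary[0]])[0, 0]) \
        / (boundary[1] - boundary[0])
    eta = np.array([slope / col_slope])
    return ReducedFit(eta=eta, vcov_eta=np.array([[var]]), spec=spec)


class TestDailyAF:
    def test_zero_effect_gives_zero_af(self):
        red = linear_reduced(slope=0.0)
        af = hm.daily_af(np.array([10.0, 25.0, 39.0]), red, reference=19.0)
        np.testing.assert_array_equal(af, 0.0)

    def test_af_zero_at_or_below_reference(self):
        red = linear_reduced(slope=0.2)
        af = hm.daily_af(np.array([18.0, 19.0, 20.0]), red, reference=19.0)
        assert af[0] == af[1] == 0.0
        assert af[2] > 0.0

    def test_log2_cumulative_gives_half(self):
        red = linear_reduced(slope=np.log(2.0))
        af = hm.daily_af(np.array([20.0]), red, reference=19.0)
        assert af[0] == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_heat(self):
        """Raising every above-reference temperature by 1 degC strictly
        increases every positive AF (monotone fitted curve)."""
        red = linear_reduced(slope=0.1)
        t = np.array([15.0, 20.0, 24.0, 30.0])
        af0 = hm.daily_af(t, red, 19.0)
        t1 = np.where(t > 19.0, t + 1.0, t)
        af1 = hm.daily_af(t1, red, 19.0)
        assert (af1[af0 > 0] > af0[af0 > 0]).all()
        assert af1[0] == 0.0


class TestDailyAN:
    def test_zero_deaths_zero_an(self):
        an, complete = hm.daily_an(np.full(5, 0.5), np.zeros(5), lag_max=2)
        np.testing.assert_array_equal(an, 0.0)

    def test_forward_mean_closed_form(self):
        af = np.array([0.5] + [0.0] * 10)
        deaths = np.full(11, 2.0)
        an, complete = hm.daily_an(af, deaths, lag_max=10)
        assert an[0] == pytest.approx(0.5 * 2.0)
        assert complete[0] and not complete[1:].any()

    def test_brute_force_20_day_series(self):
        rng = np.random.default_rng(5)
        af = rng.uniform(0, 0.3, 20)
        deaths = rng.poisson(2.0, 20).astype(float)
        units = np.repeat(["a", "b"], 10)
        an, complete = hm.daily_an(af, deaths, lag_max=3, units=units)
        for i in range(20):
            seg = slice(10 * (i // 10), 10 * (i // 10) + 10)
            window = deaths[i:min(i + 4, seg.stop)]
            assert an[i] == pytest.approx(af[i] * window.mean())
            assert complete[i] == (len(window) == 4)


class TestAggregate:
    def make_daily(self, an, deaths, dates, units="A"):
        df = make_panel(units, dates, 20.0, deaths)
        df["an"] = an
        return df

    def test_af_percent_identity(self):
        # an_total / total deaths as the relative excess (%)
        daily = self.make_daily([5296.4, 0.0], [200000, 27835],
                                ["2001-06-01", "2001-06-02"])
        out = hm.aggregate(daily)
        assert out["an_total"] == pytest.approx(5296.4)
        assert out["af_total_pct"] == pytest.approx(100 * 5296.4 / 227835)
        assert round(out["af_total_pct"], 2) == 2.32

    def test_subregion_af_identity(self):
        daily = self.make_daily([2114.44], [59289], ["2001-06-01"])
        assert round(hm.aggregate(daily)["af_total_pct"], 2) == 3.57

    def test_zero_an_gives_zero_percent(self):
        daily = self.make_daily([0.0], [100], ["2001-06-01"])
        assert hm.aggregate(daily)["af_total_pct"] == 0.0

    def test_partition_additivity_exact(self):
        rng = np.random.default_rng(9)
        dates = pd.date_range("2001-05-01", periods=60)
        daily = self.make_daily(rng.uniform(0, 2, 60), rng.poisson(2, 60),
                                dates)
        whole = hm.aggregate(daily, window=("2001-05-01", "2001-06-29"))
        a = hm.aggregate(daily, window=("2001-05-01", "2001-05-31"))
        b = hm.aggregate(daily, window=("2001-06-01", "2001-06-29"))
        # mathematically exact; allow only float summation-order slack
        assert whole["an_total"] == pytest.approx(
            a["an_total"] + b["an_total"], rel=1e-12)

    def test_empty_window_rejected(self):
        daily = self.make_daily([1.0], [5], ["2001-06-01"])
        with pytest.raises(ValueError):
            hm.aggregate(daily, window=("2050-01-01", "2050-12-31"))


class TestAnnualImpacts:
    def test_noiseless_linear_trend_recovered(self):
        rows = []
        for i, year in enumerate(range(2000, 2005)):
            an = 1.0 + 0.1 * i  # af% = an/deaths*100 = 10 + i (slope 1/yr)
            rows.append({"unit": "A", "date": pd.Timestamp(f"{year}-06-01"),
                         "deaths": 10, "an": an, "tmean": 25.0})
        per_year, slope, intercept = hm.annual_impacts(pd.DataFrame(rows))
        assert slope == pytest.approx(1.0)
        # closed-form OLS via normal equations on the 5 points
        x = per_year.index.to_numpy(float)
        y = per_year.af_total_pct.to_numpy()
        sxx = ((x - x.mean()) ** 2).sum()
        assert slope == pytest.approx(((x - x.mean()) * y).sum() / sxx)

    def test_identical_years_zero_slope(self):
        rows = [{"unit": "A", "date": pd.Timestamp(f"{y}-06-01"),
                 "deaths": 10, "an": 0.5, "tmean": 25.0}
                for y in range(2000, 2004)]
        _, slope, _ = hm.annual_impacts(pd.DataFrame(rows))
        assert slope == pytest.approx(0.0, abs=1e-12)


class TestMonteCarloECI:
    def test_zero_vcov_collapses_to_point(self):
        red = linear_reduced(slope=0.1, var=0.0)
        lo, hi, _ = hm.monte_carlo_eci(red, lambda eta: float(eta[0]),
                                       n_sim=200, seed=1)
        assert lo == hi == pytest.approx(red.eta[0])

    def test_seed_reproducibility(self):
        red = linear_reduced(slope=0.1, var=0.3)
        a = hm.monte_carlo_eci(red, lambda eta: float(eta[0]), n_sim=200, seed=7)
        b = hm.monte_carlo_eci(red, lambda eta: float(eta[0]), n_sim=200, seed=7)
        assert a[0] == b[0] and a[1] == b[1]

    def test_linear_gaussian_toy_matches_analytic_quantiles(self):
        """Totals linear in eta => draws are exactly normal; the empirical
        2.5/97.5 percentiles must match the analytic ones within Monte Carlo
        error (3 binomial-SE at n=1000)."""
        sigma2 = 0.25
        red = linear_reduced(slope=0.1, var=0.0)
        red = ReducedFit(eta=np.array([2.0]),
                         vcov_eta=np.array([[sigma2]]), spec=red.spec)
        w = 3.0
        lo, hi, draws = hm.monte_carlo_eci(
            red, lambda eta: w * float(eta[0]), n_sim=1000, seed=3)
        mean, sd = w * 2.0, w * np.sqrt(sigma2)
        # SE of an empirical p-quantile: sqrt(p(1-p)/n)/density at quantile
        p = 0.025
        se_q = np.sqrt(p * (1 - p) / 1000) / stats.norm.pdf(
            stats.norm.ppf(p)) * sd
        assert abs(lo - (mean - 1.959964 * sd)) < 3 * se_q
        assert abs(hi - (mean + 1.959964 * sd)) < 3 * se_q

    def test_nonpsd_vcov_clipped_finite_draws(self):
        from heatmort.attribution import draw_coefficients
        red = ReducedFit(eta=np.zeros(2),
                         vcov_eta=np.array([[1.0, 2.0], [2.0, 1.0]]),
                         spec=hm.KnotSpec(var_knots=(0.5,),
                                          var_boundary=(0, 1), lag_max=0))
        draws = draw_coefficients(red, 500, seed=0)
        assert np.isfinite(draws).all()
        # the negative eigendirection is clipped to zero variance
        w, q = np.linalg.eigh(red.vcov_eta)
        proj = draws @ q[:, 0]
        assert np.std(proj) == pytest.approx(0.0, abs=1e-12)

    def test_attribution_eci_consistent_with_point_estimates(self, small_model,
                                                             small_panel):
        res = hm.attribute_with_eci(small_panel, small_model.reduced,
                                    small_model.mmt.mmt, n_sim=400, seed=5)
        daily, row = res.daily, res.totals.iloc[0]
        assert row.an_lo <= row.an_total <= row.an_hi
        assert row.af_lo_pct <= row.af_total_pct <= row.af_hi_pct
        point = hm.aggregate(daily)
        assert row.an_total == pytest.approx(point["an_total"])
        assert row.af_total_pct == pytest.approx(point["af_total_pct"])
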