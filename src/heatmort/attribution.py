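"""Forward attributable fractions/numbers for heat and Monte Carlo eCIs.

The forward scheme attributes to day *t*'s exposure the risk it will exert
over the following ``lag_max`` days: with ``c_t`` the overall cumulative log
RR at exposure ``x_t`` versus the reference (the MMT), the attributable
fraction is ``af_t = 1 - exp(-c_t)``, set to zero for exposures at or below
the reference (heat only).  The attributable number spreads that fraction
over the deaths actually observed in the forward window:
``an_t = af_t * mean(deaths_{t..t+L})``.  Sums of ``an_t`` over a date range
give the absolute excess; divided by the total deaths in the range, the
relative excess (%).

Uncertainty is propagated by Monte Carlo: coefficient draws from the
multivariate normal ``N(eta, vcov_eta)`` of the reduced fit, re-running the
attribution per draw, and reporting empirical 2.5/97.5 percentiles (eCIs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import _segment_ids
from .curves import ReducedFit, cumulative_log_rr

__all__ = [
    "daily_af",
    "daily_an",
    "attribute_panel",
    "aggregate",
    "annual_impacts",
    "attribute_with_eci",
    "attribution_eci",
    "monte_carlo_eci",
    "draw_coefficients",
    "AttributionResult",
]

logger = logging.getLogger("heatmort")

HEATWAVE_2003 = ("2003-07-27", "2003-08-15")


def daily_af(temps, reduced: ReducedFit, reference: float,
             eta=None) -> np.ndarray:
    """Forward attributable fraction per day, zero at or below the reference."""
    temps = np.asarray(temps, dtype=float)
    red = reduced if eta is None else ReducedFit(
        eta=np.asarray(eta, float), vcov_eta=reduced.vcov_eta, spec=reduced.spec)
    c = cumulative_log_rr(red, temps, reference)
    af = 1.0 - np.exp(-c)
    af[temps <= reference] = 0.0
    return af


def _forward_mean(deaths: np.ndarray, seg: np.ndarray, lag_max: int):
    """Mean of deaths over t..t+lag_max within each contiguous segment.

    Trailing days whose window is cut short by the end of the segment use the
    available days and are flagged incomplete.
    """
    n = len(deaths)
    means = np.empty(n, dtype=float)
    complete = np.empty(n, dtype=bool)
    csum = np.concatenate([[0.0], np.cumsum(deaths)])
    seg_end = np.empty(n, dtype=int)  # exclusive end index of each row's segment
    if n:
        boundaries = np.flatnonzero(np.diff(seg)) + 1
        ends = np.concatenate([boundaries, [n]])
        starts = np.concatenate([[0], boundaries])
        for s, e in zip(starts, ends):
            seg_end[s:e] = e
    stop = np.minimum(np.arange(n) + lag_max + 1, seg_end)
    width = stop - np.arange(n)
    means = (csum[stop] - csum[np.arange(n)]) / width
    complete = width == lag_max + 1
    return means, complete


def daily_an(af, deaths, lag_max: int, units=None, dates=None):
    """Forward attributable number: ``af_t`` times the forward mean deaths.

    Returns ``(an, complete_window)``; trailing rows averaged over fewer
    than ``lag_max + 1`` days are flagged ``complete_window=False``.
    """
    af = np.asarray(af, dtype=float)
    deaths = np.asarray(deaths, dtype=float)
    if units is None:
        units = np.zeros(len(deaths), dtype=int)
    seg = _segment_ids(np.asarray(units), dates)
    means, complete = _forward_mean(deaths, seg, lag_max)
    return af * means, complete


@dataclass
class AttributionResult:
    """Daily and aggregated heat-attributable mortality with empirical CIs."""

    daily: pd.DataFrame                      # unit, date, tmean, deaths, af, an
    totals: pd.DataFrame                     # window x (an_total, af_total_pct, eci)
    reference: float
    n_sim: int


def attribute_panel(panel: pd.DataFrame, reduced: ReducedFit, reference: float,
                    lag_max: int = None, season_only: bool = True) -> pd.DataFrame:
    """Daily AF/AN columns for a panel, using the reduced (overall) fit.

    Returns a copy of the panel with ``af``, ``an`` and ``complete_window``
    columns.  With ``season_only`` (default) only in-season records are
    scored; the panel must then carry an ``in_season`` column or be entirely
    in-season.
    """
    if lag_max is None:
        lag_max = reduced.spec.lag_max
    df = panel.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["unit", "date"], ignore_index=True)
    if season_only and "in_season" in df.columns:
        df = df[df["in_season"]].reset_index(drop=True)
    af = daily_af(df["tmean"].to_numpy(), reduced, reference)
    an, complete = daily_an(af, df["deaths"].to_numpy(), lag_max,
                            units=df["unit"].to_numpy(), dates=df["date"])
    df["af"] = af
    df["an"] = an
    df["complete_window"] = complete
    return df


def aggregate(daily: pd.DataFrame, window=None, units=None) -> dict:
    """Total attributable number and relative excess (%) over a date window.

    ``an_total`` is the sum of daily AN over the window (and unit subset);
    ``af_total_pct`` is 100 * an_total / total deaths in the same window.
    """
    df = daily
    if units is not None:
        df = df[df["unit"].isin(units)]
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        df = df[(df["date"] >= start) & (df["date"] <= end)]
    if len(df) == 0:
        raise ValueError("aggregation window selects no records")
    an_total = float(df["an"].sum())
    deaths_total = float(df["deaths"].sum())
    return {
        "an_total": an_total,
        "deaths_total": deaths_total,
        "af_total_pct": 100.0 * an_total / deaths_total if deaths_total else 0.0,
    }


def annual_impacts(daily: pd.DataFrame) -> tuple:
    """Per-year totals plus the OLS linear trend of the annual relative excess.

    Returns ``(per_year, slope, intercept)`` where ``per_year`` is a
    DataFrame indexed by year with ``an_total``, ``deaths_total`` and
    ``af_total_pct``, and the trend is ordinary least squares of
    ``af_total_pct`` on calendar year.
    """
    df = daily.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    per_year = df.groupby("year").agg(
        an_total=("an", "sum"), deaths_total=("deaths", "sum"))
    per_year["af_total_pct"] = (100.0 * per_year["an_total"]
                                / per_year["deaths_total"])
    years = per_year.index.to_numpy(dtype=float)
    if len(years) < 2:
        raise ValueError("annual trend needs at least two years")
    slope, intercept = np.polyfit(years, per_year["af_total_pct"].to_numpy(), 1)
    return per_year, float(slope), float(intercept)


def draw_coefficients(reduced: ReducedFit, n_sim: int, seed) -> np.ndarray:
    """``n_sim`` draws from N(eta, vcov_eta), PSD-repairing the covariance.

    The covariance is symmetrised and any negative eigenvalues are clipped at
    zero (with a warning) before taking the matrix square root.
    """
    rng = np.random.default_rng(seed)
    v = (reduced.vcov_eta + reduced.vcov_eta.T) / 2.0
    w, q = np.linalg.eigh(v)
    if w.min() < -1e-10 * max(1.0, w.max()):
        logger.warning("vcov_eta not PSD (min eigenvalue %.3g); clipping", w.min())
    root = q * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_sim, len(reduced.eta)))
    return reduced.eta + z @ root.T


def attribute_with_eci(panel: pd.DataFrame, reduced: ReducedFit,
                       reference: float, windows: dict = None,
                       n_sim: int = 1000, seed: int = 0) -> AttributionResult:
    """Daily AF/AN plus window totals with empirical CIs, in one call."""
    daily = attribute_panel(panel, reduced, reference)
    totals = attribution_eci(daily, reduced, reference, windows=windows,
                             n_sim=n_sim, seed=seed)
    return AttributionResult(daily=daily, totals=totals,
                             reference=float(reference), n_sim=n_sim)


def attribution_eci(daily: pd.DataFrame, reduced: ReducedFit, reference: float,
                    windows: dict = None, n_sim: int = 1000, seed: int = 0):
    """Empirical 95% CIs for AN/AF% totals over one or more date windows.

    A vectorised specialisation of :func:`monte_carlo_eci` for the standard
    attribution totals: coefficient draws are shared across windows (so the
    annual series stays coherent) and the forward death means are reused
    from the point estimate.  ``windows`` maps a name to ``(start, end)``
    date pairs (``None`` selects the full span).  Returns a DataFrame with
    the point estimates and eCI bounds per window.
    """
    windows = windows if windows is not None else {"overall": None}
    deaths = daily["deaths"].to_numpy(dtype=float)
    temps = daily["tmean"].to_numpy()
    an = daily["an"].to_numpy()
    af = daily["af"].to_numpy()
    fwd = np.divide(an, af, out=np.zeros_like(an), where=af != 0)
    idx = np.flatnonzero(af == 0)
    if len(idx):
        allfwd, _ = daily_an(np.ones_like(af), deaths, reduced.spec.lag_max,
                             units=daily["unit"].to_numpy(),
                             dates=daily["date"])
        fwd[idx] = allfwd[idx]
    draws = draw_coefficients(reduced, n_sim, seed)
    vb = reduced.spec.var_basis()
    D = vb(temps) - vb([reference])
    hot = temps > reference
    dates = pd.to_datetime(daily["date"])
    selections, names = [], []
    for name, window in windows.items():
        if window is None:
            sel = np.ones(len(daily), dtype=bool)
        else:
            start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
            sel = ((dates >= start) & (dates <= end)).to_numpy()
        if not sel.any():
            raise ValueError(f"window {name!r} selects no records")
        selections.append(sel)
        names.append(name)
    # chunk the draws so the (draws x days) AF matrix stays small
    an_sims = np.zeros((n_sim, len(names)))
    for lo_i in range(0, n_sim, 100):
        chunk = draws[lo_i:lo_i + 100]
        log_rr = chunk @ D.T
        log_rr[:, ~hot] = 0.0
        af_chunk = 1.0 - np.exp(-log_rr)
        for j, sel in enumerate(selections):
            an_sims[lo_i:lo_i + 100, j] = af_chunk[:, sel] @ fwd[sel]
    rows = []
    for j, (name, sel) in enumerate(zip(names, selections)):
        deaths_total = float(deaths[sel].sum())
        an_total = float(an[sel].sum())
        sims = an_sims[:, j]
        rows.append({
            "window": name,
            "an_total": an_total,
            "an_lo": float(np.percentile(sims, 2.5)),
            "an_hi": float(np.percentile(sims, 97.5)),
            "deaths_total": deaths_total,
            "af_total_pct": 100.0 * an_total / deaths_total,
            "af_lo_pct": float(np.percentile(100 * sims / deaths_total, 2.5)),
            "af_hi_pct": float(np.percentile(100 * sims / deaths_total, 97.5)),
        })
    return pd.DataFrame(rows)


def monte_carlo_eci(reduced: ReducedFit, totals_fn, n_sim: int = 1000,
                    seed: int = 0, level: float = 0.95):
    """Empirical CI of any attribution total under coefficient uncertainty.

    ``totals_fn(eta)`` must recompute the total(s) -- scalar or 1-D array --
    for a coefficient vector; the same draws are reused across all totals so
    that, e.g., annual series stay coherent.  Returns ``(lo, hi, draws)``
    with the empirical ``(1-level)/2`` and ``1-(1-level)/2`` percentiles.
    """
    draws = draw_coefficients(reduced, n_sim, seed)
    sims = np.asarray([np.asarray(totals_fn(eta), dtype=float) for eta in draws])
    alpha = 100 * (1 - level) / 2
    lo = np.percentile(sims, alpha, axis=0)
    hi = np.percentile(sims, 100 - alpha, axis=0)
    return lo, hi, sims
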