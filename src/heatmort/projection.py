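"""End-of-century projection of heat-attributable mortality.

Future impacts combine three ingredients: (i) a counterfactual daily death
series built by replicating the observed mean count per seasonal day into
every projection year (demographics held fixed); (ii) bias-corrected
climate-scenario temperatures, with the fitted exposure-response curve
log-linearly extrapolated beyond the observed range; (iii) the forward
attribution machinery.  Results are aggregated over 20-year periods and
averaged across ensemble members per emission pathway, with empirical CIs
that pool Monte Carlo coefficient draws across members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import daily_af, daily_an, draw_coefficients
from .curves import ReducedFit
from .synth import ClimateSeries

__all__ = [
    "DEFAULT_PERIODS",
    "baseline_death_series",
    "project_impacts",
    "ProjectionResult",
]

logger = logging.getLogger("heatmort")

DEFAULT_PERIODS = (
    (1981, 2000), (2001, 2020), (2021, 2040),
    (2041, 2060), (2061, 2080), (2081, 2100),
)


def baseline_death_series(panel: pd.DataFrame, projection_years,
                          season=((5, 1), (9, 30))) -> pd.DataFrame:
    """Counterfactual daily deaths: observed day-of-season means, replicated.

    For every unit and every seasonal day-of-year, the projected count is the
    mean observed count for that day-of-year across the observed years,
    repeated identically into each projection year (aligned by days since
    the season start, so the profile is invariant to leap years -- the
    May-September season contains no Feb 29).
    """
    years = sorted(int(y) for y in projection_years)
    if not years:
        raise ValueError("projection_years is empty")
    df = panel.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "in_season" in df.columns:
        df = df[df["in_season"]]
    if len(df) == 0:
        raise ValueError("panel has no in-season records")
    (m0, d0), (m1, d1) = season
    start_md = (m0, d0)
    # day-of-season = days since the season start of the same year
    season_start = pd.to_datetime({
        "year": df["date"].dt.year, "month": m0, "day": d0})
    df["dos"] = (df["date"] - season_start).dt.days
    profile = df.groupby(["unit", "dos"])["deaths"].mean()

    frames = []
    for year in years:
        start = pd.Timestamp(year=year, month=m0, day=d0)
        end = pd.Timestamp(year=year, month=m1, day=d1)
        dates = pd.date_range(start, end, freq="D")
        dos = np.arange(len(dates))
        for unit in profile.index.get_level_values(0).unique():
            prof = profile.loc[unit]
            vals = prof.reindex(dos).to_numpy()
            frames.append(pd.DataFrame({
                "unit": unit, "date": dates, "deaths": vals}))
    out = pd.concat(frames, ignore_index=True)
    if out["deaths"].isna().any():
        raise ValueError("observed panel does not cover the full season")
    return out


@dataclass
class ProjectionResult:
    """Ensemble projection summary.

    ``summary`` has one row per (period, pathway) with the ensemble-mean
    attributable number / relative excess and empirical CI bounds;
    ``members`` keeps the per-member point estimates behind each mean.
    """

    summary: pd.DataFrame
    members: pd.DataFrame
    reference: float
    n_sim: int


def _member_period_frame(member: ClimateSeries, baseline: pd.DataFrame,
                         season_months) -> pd.DataFrame:
    temps = member.data.copy()
    temps["date"] = pd.to_datetime(temps["date"])
    temps = temps[temps["date"].dt.month.isin(season_months)]
    merged = baseline.merge(temps, on=["unit", "date"], how="inner")
    return merged.sort_values(["unit", "date"], ignore_index=True)


def project_impacts(members, reduced: ReducedFit, reference: float,
                    baseline: pd.DataFrame, periods=DEFAULT_PERIODS,
                    n_sim: int = 1000, seed: int = 0,
                    season_months=(5, 6, 7, 8, 9)) -> ProjectionResult:
    """Project attributable mortality per 20-year period and pathway.

    Parameters
    ----------
    members : list of ClimateSeries (bias-corrected ensemble members)
    reduced : the overall exposure-response fit (extrapolates log-linearly
        beyond the observed range by construction)
    reference : MMT (degC)
    baseline : counterfactual death series from :func:`baseline_death_series`
    periods : iterable of (start_year, end_year) inclusive
    n_sim : Monte Carlo coefficient draws; the same draws are shared across
        members so the pooled draw x member distribution yields the eCI.

    Point estimates per (period, pathway) are arithmetic means over that
    pathway's members; a member not covering a period is excluded from it
    with a warning.
    """
    lag_max = reduced.spec.lag_max
    draws = draw_coefficients(reduced, n_sim, seed)
    member_rows = []
    sim_rows = {}  # (pathway, period) -> list of per-draw arrays
    for member in members:
        merged = _member_period_frame(member, baseline, season_months)
        if len(merged) == 0:
            logger.warning("member %s/%s shares no dates with the baseline",
                           member.model_id, member.pathway_id)
            continue
        temps = merged["tmean"].to_numpy()
        deaths = merged["deaths"].to_numpy()
        units = merged["unit"].to_numpy()
        dates = merged["date"]
        years = dates.dt.year.to_numpy()
        af = daily_af(temps, reduced, reference)
        an, _ = daily_an(af, deaths, lag_max, units=units, dates=dates)
        # per-draw AFs reuse the same forward death means
        fwd = np.divide(an, af, out=np.zeros_like(an), where=af > 0)
        need_fwd = np.flatnonzero(af == 0)
        if len(need_fwd):
            all_fwd, _ = daily_an(np.ones_like(af), deaths, lag_max,
                                  units=units, dates=dates)
            fwd[need_fwd] = all_fwd[need_fwd]
        for period in periods:
            sel = (years >= period[0]) & (years <= period[1])
            if not sel.any():
                logger.warning("member %s/%s does not cover period %s-%s",
                               member.model_id, member.pathway_id, *period)
                continue
            deaths_total = float(deaths[sel].sum())
            an_total = float(an[sel].sum())
            member_rows.append({
                "model": member.model_id, "pathway": member.pathway_id,
                "period_start": period[0], "period_end": period[1],
                "an_total": an_total, "deaths_total": deaths_total,
                "af_total_pct": 100.0 * an_total / deaths_total,
            })
            an_draws = _an_draws_chunked(draws, reduced, temps[sel],
                                         reference, fwd[sel])
            sim_rows.setdefault((member.pathway_id, period), []).append(
                100.0 * an_draws / deaths_total)

    members_df = pd.DataFrame(member_rows)
    if len(members_df) == 0:
        raise ValueError("no member covers any requested period")
    summary_rows = []
    for (pathway, period), sims in sorted(sim_rows.items()):
        pooled = np.concatenate(sims)
        sub = members_df[(members_df["pathway"] == pathway)
                         & (members_df["period_start"] == period[0])]
        summary_rows.append({
            "pathway": pathway,
            "period_start": period[0], "period_end": period[1],
            "n_members": len(sub),
            "an_total": float(sub["an_total"].mean()),
            "af_total_pct": float(sub["af_total_pct"].mean()),
            "eci_lo_pct": float(np.percentile(pooled, 2.5)),
            "eci_hi_pct": float(np.percentile(pooled, 97.5)),
        })
    summary = pd.DataFrame(summary_rows).sort_values(
        ["pathway", "period_start"], ignore_index=True)
    return ProjectionResult(summary=summary, members=members_df,
                            reference=float(reference), n_sim=n_sim)


def _an_draws_chunked(draws: np.ndarray, reduced: ReducedFit,
                      temps: np.ndarray, reference: float,
                      fwd: np.ndarray) -> np.ndarray:
    """Per-draw AN totals, chunking draws to bound the AF matrix size."""
    vb = reduced.spec.var_basis()
    D = vb(temps) - vb([reference])
    cold = temps <= reference
    out = np.empty(len(draws))
    for i in range(0, len(draws), 100):
        log_rr = draws[i:i + 100] @ D.T
        log_rr[:, cold] = 0.0
        out[i:i + 100] = (1.0 - np.exp(-log_rr)) @ fwd
    return out
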