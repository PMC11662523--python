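"""Trend-preserving bias correction of climate-scenario temperatures.

Scenario temperatures from regional climate models carry systematic biases
in mean and variability relative to observations.  The correction here is
the month-wise additive-offset plus residual-scaling form of the
trend-preserving (ISIMIP-style) approach for temperature: per unit and
calendar month, an additive offset ``C_m`` (observed minus model historical
mean) and a residual scale ``s_m`` (ratio of observed to model within-month
standard deviation), both estimated on the overlapping historical period
only.  Applied as

    corrected = m_ym + C_m + s_m * (x - m_ym)

where ``m_ym`` is the model's monthly mean of that specific year, so
interannual variability and the long-term warming signal pass through the
additive channel untouched (the correction is trend-preserving), while
day-to-day variability is rescaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import ClimateSeries

__all__ = ["CorrectionParams", "fit_correction", "apply_correction"]

logger = logging.getLogger("heatmort")


@dataclass
class CorrectionParams:
    """Per unit x calendar-month additive offsets and residual scales."""

    table: pd.DataFrame  # columns unit, month, offset, scale

    def lookup(self) -> pd.DataFrame:
        return self.table.set_index(["unit", "month"])


def _monthly_stats(df: pd.DataFrame) -> pd.DataFrame:
    d = df.copy()
    d["date"] = pd.to_datetime(d["date"])
    d["month"] = d["date"].dt.month
    d["year"] = d["date"].dt.year
    # residual sd about each year's own monthly mean, pooled within month
    d["ym_mean"] = d.groupby(["unit", "year", "month"])["tmean"].transform("mean")
    d["resid"] = d["tmean"] - d["ym_mean"]
    g = d.groupby(["unit", "month"])
    return pd.DataFrame({
        "mean": g["tmean"].mean(),
        "resid_sd": g["resid"].apply(lambda r: float(np.sqrt(np.mean(r ** 2)))),
    })


def fit_correction(obs: pd.DataFrame, model_hist, overlap_years) -> CorrectionParams:
    """Estimate month-wise offsets and scales on the overlapping years.

    Parameters
    ----------
    obs : observed panel (needs ``unit, date, tmean``)
    model_hist : ClimateSeries or DataFrame of the model's historical segment
    overlap_years : iterable of calendar years present in both records
        (at least 10)
    """
    years = sorted(int(y) for y in overlap_years)
    if len(years) < 10:
        raise ValueError("bias correction needs at least 10 overlap years")
    model_df = model_hist.data if isinstance(model_hist, ClimateSeries) else model_hist

    def clip(df):
        d = df.copy()
        d["date"] = pd.to_datetime(d["date"])
        d = d[d["date"].dt.year.isin(years)]
        if len(d) == 0:
            raise ValueError("no records in the overlap period")
        return d

    so = _monthly_stats(clip(obs))
    sm = _monthly_stats(clip(model_df))
    joined = so.join(sm, lsuffix="_obs", rsuffix="_mod", how="inner")
    if len(joined) == 0:
        raise ValueError("observed and model records share no unit-months")
    offset = joined["mean_obs"] - joined["mean_mod"]
    zero_var = joined["resid_sd_mod"] <= 0
    scale = np.where(zero_var, 1.0,
                     joined["resid_sd_obs"] / joined["resid_sd_mod"].replace(0, 1))
    if zero_var.any():
        logger.warning("%d unit-months with zero model variance; scale set to 1",
                       int(zero_var.sum()))
    table = joined.reset_index()[["unit", "month"]]
    table["offset"] = offset.to_numpy()
    table["scale"] = scale
    return CorrectionParams(table=table)


def apply_correction(series, params: CorrectionParams):
    """Apply the correction to a full scenario series (historical + future).

    Each daily value is shifted and rescaled about its own year-month model
    mean; missing unit-month parameters raise.
    """
    is_cs = isinstance(series, ClimateSeries)
    df = (series.data if is_cs else series).copy()
    df["date"] = pd.to_datetime(df["date"])
    df["month"] = df["date"].dt.month
    df["year"] = df["date"].dt.year
    lut = params.lookup()
    keys = pd.MultiIndex.from_frame(df[["unit", "month"]])
    missing = ~keys.isin(lut.index)
    if missing.any():
        miss = sorted(set(keys[missing]))[:5]
        raise ValueError(f"no correction parameters for unit-months {miss}")
    par = lut.loc[keys]
    ym_mean = df.groupby(["unit", "year", "month"])["tmean"].transform("mean")
    corrected = (ym_mean.to_numpy() + par["offset"].to_numpy()
                 + par["scale"].to_numpy() * (df["tmean"].to_numpy()
                                              - ym_mean.to_numpy()))
    out = df[["unit", "date"]].copy()
    out["tmean"] = corrected
    if is_cs:
        return ClimateSeries(model_id=series.model_id,
                             pathway_id=series.pathway_id, data=out)
    return out
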