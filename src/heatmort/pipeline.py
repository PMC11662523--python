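"""One-call orchestration of the full analysis chain.

``fit_heat_model`` runs: knot placement on the pooled in-season temperature
distribution -> cross-basis construction -> stratum assignment ->
conditional Poisson fit -> MMT search -> lag-dimension reduction.  The
returned :class:`HeatModel` carries everything attribution, projection and
comparison need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import CrossBasis, KnotSpec, build_crossbasis
from .curves import (ExposureResponseCurve, MMTResult, ReducedFit,
                     curve_from_reduced, find_mmt, reduce_to_overall)
from .fit import FULL_SCHEME, FitResult, assign_strata, fit_conditional_poisson

__all__ = ["HeatModel", "fit_heat_model"]

logger = logging.getLogger("heatmort")


@dataclass
class HeatModel:
    """Fitted exposure-lag-response model for one panel."""

    spec: KnotSpec
    fit: FitResult
    mmt: MMTResult
    reduced: ReducedFit
    season_temps: np.ndarray

    def curve(self, temp_grid=None, reference=None) -> ExposureResponseCurve:
        """Overall cumulative RR curve, centred at the MMT by default."""
        if temp_grid is None:
            lo = float(np.min(self.season_temps))
            hi = float(np.max(self.season_temps))
            temp_grid = np.round(np.arange(lo, hi + 0.05, 0.1), 6)
        ref = self.mmt.mmt if reference is None else reference
        return curve_from_reduced(self.reduced, temp_grid, ref)


def fit_heat_model(panel: pd.DataFrame, knot_percentiles=(10, 25, 50, 75, 90),
                   lag_max: int = 10, scheme: str = FULL_SCHEME,
                   mmt_window_percentiles=(1, 99),
                   spec: KnotSpec = None) -> HeatModel:
    """Fit the case time series DLNM and locate the MMT.

    Parameters
    ----------
    panel : DataFrame with ``unit, date, tmean, deaths`` (and optionally
        ``in_season``; out-of-season rows then only feed lag histories).
    knot_percentiles : exposure-knot percentiles of the pooled in-season
        temperature distribution.  The default places two of the five knots
        below the median so the spline can resolve the risk minimum, which
        typically sits in the cooler quarter of the seasonal distribution;
        sensitivity variants such as (50, 90), (50, 75, 90), (50, 75) or
        (75, 90) are accepted unchanged.
    lag_max : lag window in days (default 10).
    scheme : stratum scheme, ``unit-year-month`` by default.
    mmt_window_percentiles : MMT search window as percentiles of the
        in-season distribution (default 1st-99th, avoiding noisy tails).
    spec : optional pre-built KnotSpec (overrides knot parameters), e.g. to
        share knots across subset fits.
    """
    df = panel.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["unit", "date"], ignore_index=True)
    in_season = (df["in_season"].to_numpy(dtype=bool)
                 if "in_season" in df.columns
                 else np.ones(len(df), dtype=bool))
    season_temps = df["tmean"].to_numpy()[in_season]
    if spec is None:
        spec = KnotSpec.from_temperatures(season_temps,
                                          percentiles=knot_percentiles,
                                          lag_max=lag_max)
    cb = build_crossbasis(df["tmean"].to_numpy(), spec,
                          units=df["unit"].to_numpy(), dates=df["date"])
    # only in-season days with full lag windows enter the likelihood
    valid = cb.valid & in_season
    strata = assign_strata(df, scheme=scheme, valid=valid)
    fit = fit_conditional_poisson(cb, df["deaths"].to_numpy(), strata)
    window = tuple(np.percentile(season_temps, mmt_window_percentiles))
    mmt = find_mmt(fit, spec, window,
                   provisional_reference=float(np.median(season_temps)))
    reduced = reduce_to_overall(fit, spec)
    logger.info("fitted heat model: MMT=%.2f degC%s, %d informative strata",
                mmt.mmt, " (boundary)" if mmt.at_boundary else "",
                fit.n_strata_informative)
    return HeatModel(spec=spec, fit=fit, mmt=mmt, reduced=reduced,
                     season_temps=season_temps)
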