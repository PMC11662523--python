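"""Panel and scenario file handling, derived variables and summary tables.

The universal input is a *panel*: one record per municipality-date with the
daily mean temperature and the all-cause death count, stored as delimited
text with header ``unit,date,tmean,deaths[,age65plus_deaths]`` and ISO-8601
dates.  Scenario files carry ``model,pathway,unit,date,tmean``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synth import ClimateSeries

__all__ = [
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "read_scenario",
    "write_scenario",
    "derive_tmean",
    "area_weighted_average",
    "summarize_panel",
]

logger = logging.getLogger("heatmort")

PANEL_COLUMNS = ["unit", "date", "tmean", "deaths"]
SEASON_DEFAULT = ((5, 1), (9, 30))
SEASON_MONTHS = (5, 6, 7, 8, 9)  # MJJAS


class PanelFormatError(ValueError):
    """A panel file violates the schema or its invariants."""


def _season_flags(dates: pd.Series, season) -> np.ndarray:
    (m0, d0), (m1, d1) = season
    md = list(zip(dates.dt.month, dates.dt.day))
    return np.array([(m0, d0) <= x <= (m1, d1) for x in md])


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel invariants; returns the panel sorted by (unit, date)."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelFormatError(f"panel is missing columns {missing}")
    if len(panel) == 0:
        raise PanelFormatError("panel is empty")
    panel = panel.copy()
    panel["date"] = pd.to_datetime(panel["date"])
    if panel.duplicated(["unit", "date"]).any():
        dup = panel[panel.duplicated(["unit", "date"], keep=False)].iloc[0]
        raise PanelFormatError(
            f"duplicate record for unit {dup['unit']} on {dup['date'].date()}"
        )
    deaths = panel["deaths"].to_numpy()
    if np.any(pd.isna(deaths)) or np.any(deaths < 0):
        raise PanelFormatError("deaths must be non-negative")
    if np.any(np.asarray(deaths, float) != np.round(np.asarray(deaths, float))):
        raise PanelFormatError("deaths must be integer counts")
    if not np.all(np.isfinite(panel["tmean"].to_numpy(dtype=float))):
        raise PanelFormatError("tmean must be finite")
    panel["deaths"] = panel["deaths"].astype(int)
    return panel.sort_values(["unit", "date"], ignore_index=True)


def read_panel(path, season=None) -> pd.DataFrame:
    """Read and validate a panel file.

    When ``season`` -- a ``((month, day), (month, day))`` window -- is given,
    an ``in_season`` column marks records inside it; out-of-season records
    (e.g. the pre-season days needed for lag exposures) are retained.
    """
    try:
        panel = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise PanelFormatError(f"{path}: empty file") from exc
    panel = validate_panel(panel)
    if season is not None:
        panel["in_season"] = _season_flags(panel["date"], season)
    logger.info("read panel %s: %d records, %d units", path, len(panel),
                panel["unit"].nunique())
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_scenario(path) -> list:
    """Read a scenario file into one ClimateSeries per (model, pathway)."""
    df = pd.read_csv(path)
    for col in ("model", "pathway", "unit", "date", "tmean"):
        if col not in df.columns:
            raise PanelFormatError(f"scenario file is missing column {col!r}")
    df["date"] = pd.to_datetime(df["date"])
    out = []
    for (model, pathway), grp in df.groupby(["model", "pathway"], sort=True):
        out.append(ClimateSeries(
            model_id=str(model), pathway_id=str(pathway),
            data=grp[["unit", "date", "tmean"]].reset_index(drop=True),
        ))
    return out


def write_scenario(series, path) -> None:
    """Write one or more ClimateSeries to a single delimited file."""
    if isinstance(series, ClimateSeries):
        series = [series]
    frames = []
    for s in series:
        d = s.data.copy()
        d.insert(0, "model", s.model_id)
        d.insert(1, "pathway", s.pathway_id)
        d["date"] = pd.to_datetime(d["date"]).dt.strftime("%Y-%m-%d")
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def derive_tmean(tmin, tmax):
    """Daily mean temperature as the average of the daily extremes."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin must not exceed tmax")
    out = (tmin + tmax) / 2.0
    return float(out) if out.ndim == 0 else out


def area_weighted_average(values, weights):
    """Weighted average of grid-cell values by cell area fractions."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    return float(values @ weights / total)


def _iqr(x: np.ndarray) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def summarize_panel(panel: pd.DataFrame, areas: dict,
                    region_label: str = "Region") -> pd.DataFrame:
    """Descriptive summary per area plus an aggregate region row.

    ``areas`` maps every unit label to an area (subregion) label.  For each
    area the table reports the 12-month and seasonal (MJJAS) death sums, the
    seasonal share of annual deaths (%), the seasonal 65+ share (%) when an
    ``age65plus_deaths`` column is present, and temperature mean / range /
    IQR for the full year and the season.  Count columns of the region row
    are exact sums of the area rows.
    """
    panel = panel.copy()
    panel["date"] = pd.to_datetime(panel["date"])
    unknown = set(panel["unit"].unique()) - set(areas)
    if unknown:
        raise ValueError(f"units not covered by the area grouping: {sorted(unknown)}")
    panel["area"] = panel["unit"].map(areas)
    seasonal = panel["date"].dt.month.isin(SEASON_MONTHS).to_numpy()
    has_age = "age65plus_deaths" in panel.columns

    def one(sub: pd.DataFrame, label: str) -> dict:
        s = sub["date"].dt.month.isin(SEASON_MONTHS).to_numpy()
        deaths = sub["deaths"].to_numpy()
        temps = sub["tmean"].to_numpy(dtype=float)
        deaths_12mo = int(deaths.sum())
        deaths_mjjas = int(deaths[s].sum())
        row = {
            "area": label,
            "deaths_12mo": deaths_12mo,
            "deaths_mjjas": deaths_mjjas,
            "seasonal_share_pct": 100.0 * deaths_mjjas / deaths_12mo
            if deaths_12mo else np.nan,
            "tmean_mean_12mo": float(temps.mean()),
            "tmean_mean_mjjas": float(temps[s].mean()) if s.any() else np.nan,
            "tmean_range_mjjas": float(temps[s].max() - temps[s].min())
            if s.any() else np.nan,
            "tmean_iqr_mjjas": _iqr(temps[s]) if s.any() else np.nan,
            "deaths_mean_daily_mjjas": float(deaths[s].mean()) if s.any() else np.nan,
        }
        if has_age:
            a65 = int(sub["age65plus_deaths"].to_numpy()[s].sum())
            row["deaths65_mjjas"] = a65
            row["share_65plus_pct"] = (100.0 * a65 / deaths_mjjas
                                       if deaths_mjjas else np.nan)
        return row

    rows = [one(grp, area) for area, grp in panel.groupby("area", sort=True)]
    rows.append(one(panel, region_label))
    table = pd.DataFrame(rows).set_index("area")
    # region counts must be exact sums of area counts
    count_cols = ["deaths_12mo", "deaths_mjjas"] + (
        ["deaths65_mjjas"] if has_age else [])
    sums = table.drop(region_label)[count_cols].sum()
    assert (table.loc[region_label, count_cols] == sums).all()
    return table
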