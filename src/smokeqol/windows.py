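"""Time-windowed exposure metrics per subject visit.

For each visit and each window length X ∈ {7, 15, 30, 60} days the module
computes, over the X consecutive days ending the day *before* the visit
(the questionnaire describes the preceding weeks, so the visit day itself is
excluded):

* mean smoke PM2.5 and mean smoke BC (arithmetic mean over all X days, with
  non-smoke days contributing 0),
* mean total PM2.5,
* the number of smoke days, and
* the cumulative plume-overlap area (day-by-day sum, no de-duplication, so it
  can exceed the study-area size).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

DEFAULT_WINDOWS = (7, 15, 30, 60)

__all__ = [
    "DEFAULT_WINDOWS",
    "window_days",
    "locate_cell",
    "daily_exposure_table",
    "window_metrics",
    "attach_exposures",
]


def window_days(visit_date, x: int) -> pd.DatetimeIndex:
    """The X consecutive days ending the day before `visit_date`."""
    if x <= 0:
        raise ValueError("window length must be positive")
    visit = pd.Timestamp(visit_date)
    return pd.date_range(visit - pd.Timedelta(days=x), visit - pd.Timedelta(days=1), freq="D")


def locate_cell(lon: float, lat: float, cells: pd.DataFrame) -> int:
    """Cell whose center is nearest the point (ties broken by lowest cell_id).

    Distances are measured in a local tangent plane (longitude scaled by
    cos(latitude)), which is exact for the 1 km scales of the grid.  Points
    outside the grid bounding box (plus half a cell) are rejected.
    """
    lons = cells["lon"].to_numpy()
    lats = cells["lat"].to_numpy()
    coslat = np.cos(np.radians(np.mean(lats)))
    half_deg = 0.5 / 111.32  # ~half a 1 km cell, in degrees latitude
    if not (lons.min() - half_deg / coslat <= lon <= lons.max() + half_deg / coslat
            and lats.min() - half_deg <= lat <= lats.max() + half_deg):
        raise ValueError(f"point ({lon:.4f}, {lat:.4f}) outside the grid extent")
    d2 = ((lons - lon) * coslat) ** 2 + (lats - lat) ** 2
    best = d2.min()
    candidates = cells["cell_id"].to_numpy()[np.isclose(d2, best, rtol=0, atol=1e-12)]
    return int(candidates.min())


def daily_exposure_table(
    attribution: pd.DataFrame,
    smokedays: pd.DataFrame,
    total_pm25: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the daily series the window metrics are computed from.

    `attribution` is a date-indexed frame with smoke_pm25 / smoke_bc (regional
    output, or one cell's series); `smokedays` supplies is_smoke and
    overlap_km2.  total_pm25 defaults to the attribution frame's own
    total_pm25 column when present.
    """
    daily = pd.DataFrame(index=attribution.index.copy())
    daily["smoke_pm25"] = attribution["smoke_pm25"]
    daily["smoke_bc"] = attribution["smoke_bc"]
    if total_pm25 is not None:
        daily["total_pm25"] = total_pm25.reindex(daily.index)
    elif "total_pm25" in attribution.columns:
        daily["total_pm25"] = attribution["total_pm25"]
    else:
        raise ValueError("total_pm25 series required")
    daily["is_smoke"] = smokedays["is_smoke"].reindex(daily.index)
    daily["overlap_km2"] = smokedays["overlap_km2"].reindex(daily.index)
    if daily["is_smoke"].isna().any():
        raise ValueError("smoke-day table does not cover the attribution dates")
    return daily


def window_metrics(visit_date, daily: pd.DataFrame, x: int) -> dict[str, float]:
    """The five exposure metrics for one visit and one window length."""
    days = window_days(visit_date, x)
    sub = daily.reindex(days)
    missing = sub[["smoke_pm25", "smoke_bc", "total_pm25"]].isna().any(axis=1)
    if missing.any():
        bad = ", ".join(str(d.date()) for d in sub.index[missing][:5])
        raise ValueError(f"window ({x} d before {pd.Timestamp(visit_date).date()}) "
                         f"has missing coverage on: {bad}")
    return {
        f"smoke_pm25_{x}d": float(sub["smoke_pm25"].mean()),
        f"smoke_bc_{x}d": float(sub["smoke_bc"].mean()),
        f"total_pm25_{x}d": float(sub["total_pm25"].mean()),
        f"n_smoke_days_{x}d": float(sub["is_smoke"].sum()),
        f"cum_area_{x}d": float(sub["overlap_km2"].sum()),
    }


def _rolling_lookup(daily: pd.DataFrame, windows) -> dict[int, pd.DataFrame]:
    """Rolling window aggregates indexed by the day *after* the window ends
    (i.e. directly addressable by visit date)."""
    out = {}
    cols_mean = ["smoke_pm25", "smoke_bc", "total_pm25"]
    for x in windows:
        roll = pd.DataFrame({
            **{c: daily[c].rolling(x).mean() for c in cols_mean},
            "n_smoke_days": daily["is_smoke"].astype(float).rolling(x).sum(),
            "cum_area": daily["overlap_km2"].rolling(x).sum(),
        })
        roll.index = roll.index + pd.Timedelta(days=1)
        out[x] = roll
    return out


def attach_exposures(
    visits: pd.DataFrame,
    daily: pd.DataFrame | None = None,
    windows=DEFAULT_WINDOWS,
    level: str = "region",
    per_cell_daily: dict[int, pd.DataFrame] | None = None,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One analysis-ready row per visit with all metrics for every window.

    level='region' evaluates every visit against the shared regional `daily`
    table; level='residence' locates each visit's 1×1 km cell from its
    (lon, lat) and uses that cell's daily table from `per_cell_daily`.
    """
    rows = visits.reset_index(drop=True).copy()
    if level == "region":
        if daily is None:
            raise ValueError("regional daily table required for level='region'")
        lookups = _rolling_lookup(daily, windows)
        cell_of = np.zeros(len(rows), dtype=int)
    elif level == "residence":
        if per_cell_daily is None or cells is None:
            raise ValueError("per_cell_daily and cells required for level='residence'")
        cell_of = np.array([locate_cell(lon, lat, cells)
                            for lon, lat in zip(rows["lon"], rows["lat"])])
        lookups_by_cell = {cid: _rolling_lookup(tbl, windows)
                           for cid, tbl in per_cell_daily.items()}
    else:
        raise ValueError(f"unknown level {level!r}")

    metric_cols = {f"{m}_{x}d": np.empty(len(rows))
                   for x in windows
                   for m in ("smoke_pm25", "smoke_bc", "total_pm25", "n_smoke_days", "cum_area")}
    for i, visit in enumerate(pd.to_datetime(rows["visit_date"])):
        lk = lookups if level == "region" else lookups_by_cell[cell_of[i]]
        for x in windows:
            try:
                rec = lk[x].loc[visit]
            except KeyError:
                raise ValueError(f"visit {visit.date()} outside daily coverage") from None
            if rec.isna().any():
                raise ValueError(f"window {x} d before {visit.date()} has missing coverage")
            for m_src, m_dst in (("smoke_pm25", "smoke_pm25"), ("smoke_bc", "smoke_bc"),
                                 ("total_pm25", "total_pm25"), ("n_smoke_days", "n_smoke_days"),
                                 ("cum_area", "cum_area")):
                metric_cols[f"{m_dst}_{x}d"][i] = rec[m_src]
    for col, vals in metric_cols.items():
        rows[col] = vals
    if level == "residence":
        rows["cell_id"] = cell_of
    return rows
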