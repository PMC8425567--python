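"""Covariate construction for survey clusters from open geospatial sources.

Implements the feature-engineering rules applied to each enumeration area
(EA) before modelling:

* nearest-in-space assignment of static geographic covariates,
* seasonal z-score anomalies of gridded monthly series (vegetation SIF,
  land-surface temperature, precipitation) within a 100 km neighbourhood,
* one-year food-price windows (per-market, per-commodity mean and variance,
  markets ordered by distance),
* one-year conflict event/death counts (country-level, spatially agnostic),
* the missingness filters (drop features missing for >20% of a test/train
  regime, then drop rows with any remaining missing value).

Months are indexed as consecutive integers ``year * 12 + (month - 1)``.
Distances are great-circle (haversine, R = 6371 km).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "month_index",
    "assign_nearest_static",
    "seasonal_zscore",
    "price_window_features",
    "clean_conflicts",
    "conflict_window_counts",
    "filter_missing",
    "FilterReport",
]

EARTH_RADIUS_KM = 6371.0


def month_index(d: date) -> int:
    """Consecutive calendar-month index: year*12 + month-1."""
    return d.year * 12 + d.month - 1


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def assign_nearest_static(points: pd.DataFrame, ea_lat: float, ea_lon: float,
                          value_col: str = "value") -> float:
    """Value of the candidate point physically closest to the EA centroid.

    ``points`` needs columns lat, lon and ``value_col``.  Ties in distance
    break to the lowest positional index (stable argmin).
    """
    if len(points) == 0:
        raise ValueError("no candidate points to assign from")
    d = haversine_km(points["lat"].to_numpy(), points["lon"].to_numpy(), ea_lat, ea_lon)
    return float(points[value_col].to_numpy()[int(np.argmin(d))])


# ---------------------------------------------------------------------------
# Seasonal z-score anomalies


def _season_month_sets(start_month: int) -> list[list[int]]:
    """Four consecutive non-overlapping 3-month seasons counted backwards
    from the survey start month: offsets -3..-1, -6..-4, -9..-7, -12..-10."""
    return [
        [start_month - o for o in range(lo, hi - 1, -1)]
        for lo, hi in ((3, 1), (6, 4), (9, 7), (12, 10))
    ]


def seasonal_zscore(
    series: pd.DataFrame,
    ea_lat: float,
    ea_lon: float,
    survey_start: int | date,
    radius_km: float = 100.0,
    climatology: str = "full_record",
    calendar_fixed: bool = False,
) -> float:
    """Mean of the four seasonal z-scores over the year before survey start.

    The 12 months before ``survey_start`` are partitioned into four
    consecutive 3-month seasons.  For each season the anomaly is

        z = (seasonal value at the nearest sensed cell - mu) / sd,

    where mu and sd are the sample mean and sample standard deviation
    (n-1 denominator) of all raw values observed during that season within
    ``radius_km`` of the target.  A season with zero spread maps to z = 0.
    The returned feature is the mean of the four z-scores.

    Parameters
    ----------
    series : DataFrame with columns lat, lon, month, value
        Gridded monthly series; ``month`` is a consecutive month index.
    survey_start : int month index or datetime.date
    climatology : {"full_record", "window_only"}
        Whether mu/sd pool every year of the record for the season's
        calendar months, or only the season's own 12-month-window values.
    calendar_fixed : bool
        If True, seasons are the calendar quarters containing the prior
        12 months rather than survey-anchored 3-month blocks.
    """
    if isinstance(survey_start, date):
        survey_start = month_index(survey_start)
    if climatology not in ("full_record", "window_only"):
        raise ValueError("climatology must be 'full_record' or 'window_only'")

    lat = series["lat"].to_numpy(dtype=float)
    lon = series["lon"].to_numpy(dtype=float)
    mon = series["month"].to_numpy(dtype=int)
    val = series["value"].to_numpy(dtype=float)

    prior = (mon >= survey_start - 12) & (mon < survey_start)
    if not prior.any() or (np.unique(mon[prior]).size < 12):
        raise ValueError("series must cover the 12 months before survey start")

    within = haversine_km(lat, lon, ea_lat, ea_lon) <= radius_km
    if not within.any():
        raise ValueError(f"no grid cell within {radius_km} km of the target")

    if calendar_fixed:
        # calendar quarters (JFM, AMJ, JAS, OND) intersecting the prior year
        months_prior = list(range(survey_start - 12, survey_start))
        seasons: dict[int, list[int]] = {}
        for m in months_prior:
            seasons.setdefault((m % 12) // 3, []).append(m)
        season_list = [sorted(v) for _, v in sorted(seasons.items())][:4]
    else:
        season_list = _season_month_sets(survey_start)

    # nearest sensed cell among in-radius cells
    cells = np.unique(np.column_stack([lat[within], lon[within]]), axis=0)
    dcell = haversine_km(cells[:, 0], cells[:, 1], ea_lat, ea_lon)
    cell_order = np.argsort(dcell, kind="stable")

    zs = []
    for months in season_list:
        mset = set(months)
        if climatology == "full_record":
            cal = {m % 12 for m in months}
            pool_mask = within & np.isin(mon % 12, list(cal))
        else:
            pool_mask = within & np.isin(mon, months)
        pool = val[pool_mask]
        if pool.size == 0:
            raise ValueError("no observations within radius for a prior season")
        mu = float(pool.mean())
        sd = float(pool.std(ddof=1)) if pool.size > 1 else 0.0

        # seasonal value at the nearest cell holding data for those months
        v = None
        season_mask = within & np.isin(mon, list(mset))
        for ci in cell_order:
            cmask = season_mask & (lat == cells[ci, 0]) & (lon == cells[ci, 1])
            if cmask.any():
                v = float(val[cmask].mean())
                break
        if v is None:
            raise ValueError("no in-radius cell has data for a prior season")
        zs.append(0.0 if sd == 0.0 else (v - mu) / sd)
    return float(np.mean(zs))


# ---------------------------------------------------------------------------
# Food-price windows


def price_window_features(
    prices: pd.DataFrame,
    ea_lat: float,
    ea_lon: float,
    survey_start: int | date,
    n_markets: int | None = None,
) -> pd.DataFrame:
    """Per-market, per-commodity price mean and sample variance over the
    12 months strictly before survey start, markets ordered by distance.

    Commodity series missing any month of the window are excluded
    (incomplete records are dropped, not imputed).  Returns a DataFrame
    with columns market_rank, market, distance_km, commodity, mean,
    variance — ordered by (market_rank, commodity).
    """
    if isinstance(survey_start, date):
        survey_start = month_index(survey_start)
    window = set(range(survey_start - 12, survey_start))

    mk = prices.drop_duplicates("market")[["market", "lat", "lon"]]
    d = haversine_km(mk["lat"].to_numpy(), mk["lon"].to_numpy(), ea_lat, ea_lon)
    mk = mk.assign(distance_km=d).sort_values(
        ["distance_km", "market"], kind="stable"
    )

    rows = []
    for rank, (_, mrow) in enumerate(mk.iterrows(), start=1):
        sub = prices[(prices["market"] == mrow["market"]) & prices["month"].isin(window)]
        for commodity, grp in sorted(sub.groupby("commodity"), key=lambda t: str(t[0])):
            present = grp.dropna(subset=["price"])
            if set(present["month"]) != window:
                continue  # incomplete record: excluded from analysis
            p = present["price"].to_numpy(dtype=float)
            rows.append(
                {
                    "market_rank": rank,
                    "market": mrow["market"],
                    "distance_km": float(mrow["distance_km"]),
                    "commodity": commodity,
                    "mean": float(p.mean()),
                    "variance": float(p.var(ddof=1)),
                }
            )
        if n_markets is not None and rank >= n_markets:
            break
    out = pd.DataFrame(
        rows,
        columns=["market_rank", "market", "distance_km", "commodity", "mean", "variance"],
    )
    if out.empty:
        warnings.warn(
            "no complete commodity price series in the pre-survey window",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# Conflict windows


def clean_conflicts(events: pd.DataFrame) -> pd.DataFrame:
    """Drop events lacking a georeference or a timestamp."""
    req = ["lat", "lon", "start", "end"]
    mask = events[req].notna().all(axis=1)
    return events[mask].reset_index(drop=True)


def conflict_window_counts(
    events: pd.DataFrame, country: str, survey_start: date
) -> tuple[int, int]:
    """(event count, death count) for the year before the survey start.

    Counts events of ``country`` whose start date lies in
    [survey_start - 1y, survey_start), plus multi-day events whose end date
    lies in that window; each qualifying event is counted once and its
    deaths summed.  Country-specific but otherwise spatially agnostic.
    """
    if len(events) == 0:
        return 0, 0
    ev = events[events["country"] == country]
    if len(ev) == 0:
        return 0, 0
    lo = (pd.Timestamp(survey_start) - pd.DateOffset(years=1)).date()
    start = pd.to_datetime(ev["start"]).dt.date
    end = pd.to_datetime(ev["end"]).dt.date
    in_window_start = (start >= lo) & (start < survey_start)
    multi_day = end > start
    in_window_end = multi_day & (end >= lo) & (end < survey_start)
    qual = in_window_start | in_window_end
    return int(qual.sum()), int(ev.loc[qual, "deaths"].sum())


# ---------------------------------------------------------------------------
# Missingness filters


@dataclass
class FilterReport:
    """What the missingness filter removed from one test/train regime."""

    dropped_columns: list[str] = field(default_factory=list)
    dropped_rows: int = 0
    n_rows_in: int = 0
    n_rows_out: int = 0


def filter_missing(
    table: pd.DataFrame,
    feature_cols: list[str],
    outcome_cols: list[str],
) -> tuple[pd.DataFrame, FilterReport]:
    """Two-stage missingness filter applied to a stacked train+test regime.

    Step 1 drops every feature column whose missing fraction across the
    regime is strictly greater than 20%; step 2 drops every row that still
    has any missing feature or outcome.  Raises if step 1 removes all
    feature columns.
    """
    report = FilterReport(n_rows_in=len(table))
    keep_feats = []
    for c in feature_cols:
        frac = table[c].isna().mean()
        if frac > 0.20:
            report.dropped_columns.append(c)
        else:
            keep_feats.append(c)
    if not keep_feats:
        raise ValueError("missingness filter removed every feature column")
    cols = keep_feats + list(outcome_cols)
    complete = table[cols].notna().all(axis=1)
    out = table.loc[complete, [c for c in table.columns if c not in report.dropped_columns]]
    report.dropped_rows = int((~complete).sum())
    report.n_rows_out = len(out)
    return out.reset_index(drop=True), report
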