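"""Readers/writers for the flat cluster table and auxiliary CSV sources.

The flat table has one row per surveyed enumeration area with required
columns ``country, year, lat, lon, urban`` and the five prevalence
outcomes; every remaining column is treated as a feature.  Column names in
external files can be mapped onto this schema through a user-editable alias
file (YAML mapping external name -> schema name), since data releases vary
in their header conventions.

All CSV is UTF-8 with a header row, '.' decimals, and empty cells for
missing values.  Auxiliary sources: long-format rasters
(lat, lon, month, value), market prices (market, lat, lon, commodity,
month, price), conflict events (country, lat, lon, start, end, deaths with
ISO-8601 dates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .synthetic import OUTCOME_NAMES

__all__ = [
    "REQUIRED_COLUMNS",
    "OUTCOME_NAMES",
    "SchemaReport",
    "read_flat_table",
    "split_surveys",
    "default_feature_groups",
    "load_aliases",
    "read_raster",
    "read_market_prices",
    "read_conflict_events",
]

REQUIRED_COLUMNS = ["country", "year", "lat", "lon", "urban"] + OUTCOME_NAMES


@dataclass
class SchemaReport:
    """Validation summary for a flat-table read."""

    n_rows: int = 0
    feature_columns: list[str] = field(default_factory=list)
    out_of_range_outcomes: int = 0
    bad_coordinates: int = 0
    coerced_non_numeric: int = 0


def load_aliases(path) -> dict[str, str]:
    """Load a YAML alias file mapping external column names to schema names."""
    with open(path, encoding="utf-8") as fh:
        aliases = yaml.safe_load(fh) or {}
    if not isinstance(aliases, dict):
        raise ValueError("alias file must be a mapping of column names")
    return {str(k): str(v) for k, v in aliases.items()}


def read_flat_table(
    path, aliases: dict[str, str] | None = None
) -> tuple[pd.DataFrame, SchemaReport]:
    """Read and validate a flat EA table.

    Missing required columns raise; unparsable numerics are coerced to
    missing (dropped later by the missingness filter); outcomes outside
    [0, 1] and coordinates outside valid ranges are flagged missing and
    counted in the report.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty flat table")
    if aliases:
        df = df.rename(columns=aliases)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    report = SchemaReport(n_rows=len(df))
    numeric_cols = [c for c in df.columns if c != "country"]
    for c in numeric_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        report.coerced_non_numeric += int(coerced.isna().sum() - df[c].isna().sum())
        df[c] = coerced

    for c in OUTCOME_NAMES:
        bad = df[c].notna() & ((df[c] < 0.0) | (df[c] > 1.0))
        report.out_of_range_outcomes += int(bad.sum())
        df.loc[bad, c] = np.nan

    bad_coord = (
        df["lat"].isna()
        | df["lon"].isna()
        | (df["lat"].abs() > 90.0)
        | (df["lon"].abs() > 180.0)
    )
    report.bad_coordinates = int(bad_coord.sum())

    report.feature_columns = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    return df, report


def split_surveys(df: pd.DataFrame) -> dict[tuple[str, int], pd.DataFrame]:
    """Group rows into per-(country, year) survey datasets."""
    return {
        (str(c), int(y)): g.reset_index(drop=True)
        for (c, y), g in df.groupby(["country", "year"], sort=True)
    }


_GROUP_RULES = [
    # (group, exact names, prefixes)
    ("location", {"lat", "lon", "altitude", "slope"}, ()),
    ("remoteness", {"urban", "travel_time_city"}, ("travel_time",)),
    ("vegetation", {"tree_cover", "pasture"}, ("sif",)),
    ("weather", set(), ("lst", "precip", "chirps")),
    ("market", set(), ("price", "mkt", "market")),
    ("conflict", set(), ("conflict",)),
    ("time", {"survey_month", "survey_date", "year"}, ()),
]


def default_feature_groups(feature_names) -> dict[str, str]:
    """Map features to data-type groups (location, remoteness, vegetation,
    weather, market, conflict, time); unknown columns fall into "other"."""
    out = {}
    for f in feature_names:
        group = "other"
        for g, exact, prefixes in _GROUP_RULES:
            if f in exact or any(f.startswith(p) for p in prefixes):
                group = g
                break
        out[f] = group
    return out


def read_raster(path) -> pd.DataFrame:
    """Long-format gridded monthly series: lat, lon, month, value."""
    df = pd.read_csv(path)
    need = {"lat", "lon", "month", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: raster CSV needs columns {sorted(need)}")
    if df.duplicated(["lat", "lon", "month"]).any():
        raise ValueError(f"{path}: duplicate (cell, month) keys")
    return df


def read_market_prices(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"market", "lat", "lon", "commodity", "month", "price"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: market CSV needs columns {sorted(need)}")
    if (df["price"].dropna() <= 0).any():
        raise ValueError(f"{path}: prices must be positive")
    if df.duplicated(["market", "commodity", "month"]).any():
        raise ValueError(f"{path}: duplicate (market, commodity, month) keys")
    return df


def read_conflict_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"country", "start", "end", "deaths"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: conflict CSV needs columns {sorted(need)}")
    ok = df["deaths"].dropna() >= 1
    if not ok.all():
        raise ValueError(f"{path}: events must have at least one death")
    s, e = pd.to_datetime(df["start"]), pd.to_datetime(df["end"])
    if ((e - s).dt.days < 0).any():
        raise ValueError(f"{path}: event end precedes start")
    return df
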