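"""Synthetic survey worlds for exercising the full pipeline without downloads.

The generator emulates the structure of georeferenced household-survey
cluster data: several countries, repeated survey rounds, a few hundred
enumeration areas (EAs) per survey with anonymity-jittered coordinates,
five correlated prevalence outcomes in [0, 1] driven by a smooth function
of the engineered covariates plus multivariate noise with a configurable
covariance, and the auxiliary open-data sources (gridded monthly
vegetation/temperature/precipitation rasters with seasonal structure,
market food-price tables, conflict events).

Ground truth: for outcome j,

    y = clip01( expit(alpha_j + s_j * u_j(x)) + eps ),   eps ~ N(0, Sigma)

where u_j mixes a signal component common to all outcomes (weight
``signal_share_common`` — poverty and malnutrition co-vary with the same
geography) with an outcome-specific component; each component is a
standardized linear + one-interaction function of 5 of the static/anomaly
covariates (learnable by shallow trees), s_j is the configured signal
strength, and Sigma is the configured outcome-noise covariance on the
prevalence scale.  Clipped entries are counted and the fraction reported in
``world.truth["clip_fraction"]``.

Each data source draws from its own sub-seed (master seed plus a fixed
offset), so adding a source never perturbs another source's draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import features as ft

__all__ = ["WorldConfig", "SyntheticWorld", "generate_world", "export_flat_table"]

OUTCOME_NAMES = [
    "asset_poverty",
    "child_stunting",
    "child_wasting",
    "healthy_weight",
    "underweight_women",
]

#: covariates that can carry ground-truth signal, with their relative weight
#: in the generating function: static geography dominates and the seasonal
#: anomalies contribute secondarily, mirroring the relative importance of
#: these data types for observed prevalence rates (and keeping inter-survey
#: outcome drift modest, as in repeated household surveys)
SIGNAL_POOL = [
    "altitude",
    "slope",
    "tree_cover",
    "pasture",
    "travel_time_city",
    "urban",
    "sif_anom",
    "lst_anom",
    "precip_anom",
]
SIGNAL_WEIGHTS = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.4, 0.4, 0.4])

KM_PER_DEG = 111.19  # one degree of latitude

RASTER_SOURCES = {
    # name: (base level, seasonal amplitude, anomaly scale, noise sd)
    "sif": (1.0, 0.4, 0.3, 0.05),
    "lst": (30.0, 8.0, 3.0, 0.5),
    "precip": (80.0, 50.0, 25.0, 4.0),
}


def _default_noise_cov(sd: float = 0.05, rho: float = 0.5) -> np.ndarray:
    k = len(OUTCOME_NAMES)
    c = sd * sd * (rho * np.ones((k, k)) + (1 - rho) * np.eye(k))
    return c


@dataclass
class WorldConfig:
    """Study conditions of a synthetic world.

    ``outcome_noise_cov`` is the prevalence-scale covariance of the additive
    outcome noise (default: sd 0.05 per outcome, pairwise correlation 0.5 —
    the order of cluster-level sampling noise in household surveys).
    ``signal_strength_per_outcome`` scales the standardized signal on the
    logit scale (default 0.7 keeps pre-noise prevalences inside roughly
    (0.1, 0.8) so clipping stays below 1%).  ``offset_km`` is the maximum
    coordinate jitter mimicking survey anonymization (default 10 km).
    """

    n_countries: int = 3
    years_per_country: Sequence[int] | Sequence[Sequence[int]] = (2010, 2015)
    eas_per_survey: int = 200
    outcome_noise_cov: np.ndarray = field(default_factory=_default_noise_cov)
    signal_strength_per_outcome: Sequence[float] = (0.7,) * 5
    grid_resolution_deg: float = 0.5
    months_span: Optional[tuple[int, int]] = None
    n_markets: int = 4
    n_commodities: int = 3
    conflict_rate: float = 30.0
    offset_km: float = 10.0
    survey_start_month: int = 6
    signal_share_common: float = 0.5
    seed: int = 0

    def country_years(self) -> list[list[int]]:
        ys = self.years_per_country
        if len(ys) and isinstance(ys[0], (list, tuple)):
            if len(ys) != self.n_countries:
                raise ValueError("years_per_country list must match n_countries")
            return [sorted(int(y) for y in c) for c in ys]
        return [sorted(int(y) for y in ys) for _ in range(self.n_countries)]

    def resolved_months_span(self) -> tuple[int, int]:
        years = [y for c in self.country_years() for y in c]
        first = min(years) * 12 + self.survey_start_month - 1
        last = max(years) * 12 + self.survey_start_month - 1
        if self.months_span is None:
            return first - 36, last + 6
        return tuple(self.months_span)

    def validate(self) -> None:
        cov = np.asarray(self.outcome_noise_cov, dtype=float)
        k = len(OUTCOME_NAMES)
        if cov.shape != (k, k) or not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("outcome_noise_cov must be a symmetric 5x5 matrix")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("outcome_noise_cov must be positive definite") from exc
        if self.eas_per_survey < 5:
            raise ValueError("eas_per_survey must be >= 5")
        if self.offset_km < 0:
            raise ValueError("offset_km must be >= 0")
        if any(s < 0 for s in self.signal_strength_per_outcome):
            raise ValueError("signal strengths must be non-negative")
        if not 0.0 <= self.signal_share_common <= 1.0:
            raise ValueError("signal_share_common must lie in [0, 1]")
        if not 1 <= self.survey_start_month <= 12:
            raise ValueError("survey_start_month must be 1..12")
        lo, hi = self.resolved_months_span()
        years = [y for c in self.country_years() for y in c]
        first_start = min(years) * 12 + self.survey_start_month - 1
        if lo > first_start - 12 or hi < first_start:
            raise ValueError(
                "months_span must cover at least the 12 months before the "
                "earliest survey start"
            )


@dataclass
class SyntheticWorld:
    """A generated world: EA table, raster/market/conflict sources, truth."""

    config: WorldConfig
    ea_table: pd.DataFrame
    rasters: dict[str, pd.DataFrame]
    markets: pd.DataFrame
    conflicts: pd.DataFrame
    truth: dict


def _country_code(i: int) -> str:
    return f"C{i:02d}"


def _country_box(i: int) -> tuple[float, float, float, float]:
    """(lat_min, lat_max, lon_min, lon_max); boxes separated by >300 km."""
    lon0 = 8.0 * i + 1.0
    return 1.0, 6.0, lon0, lon0 + 5.0


def _bump_field(rng: np.random.Generator, box, n_bumps: int = 3):
    """A smooth random field as a sum of Gaussian bumps over the box."""
    la0, la1, lo0, lo1 = box
    centers = np.column_stack(
        [rng.uniform(la0, la1, n_bumps), rng.uniform(lo0, lo1, n_bumps)]
    )
    widths = rng.uniform(1.0, 2.5, n_bumps)
    amps = rng.uniform(-1.0, 1.0, n_bumps)

    def f(lat, lon):
        lat = np.asarray(lat, dtype=float)[..., None]
        lon = np.asarray(lon, dtype=float)[..., None]
        d2 = (lat - centers[:, 0]) ** 2 + (lon - centers[:, 1]) ** 2
        return (amps * np.exp(-d2 / (2.0 * widths**2))).sum(axis=-1)

    return f


def _jitter_disc(rng: np.random.Generator, lat, lon, radius_km: float):
    """Uniform jitter in a disc of the given radius, local-tangent approx."""
    n = len(lat)
    r = radius_km * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    dlat = r * np.sin(theta) / KM_PER_DEG
    dlon = r * np.cos(theta) / (KM_PER_DEG * np.cos(np.radians(lat)))
    return lat + dlat, lon + dlon


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world. Deterministic given config.seed."""
    config.validate()
    seed = int(config.seed)
    rng_static = np.random.default_rng(seed + 11)
    rng_ea = np.random.default_rng(seed + 23)
    rng_raster = np.random.default_rng(seed + 37)
    rng_market = np.random.default_rng(seed + 41)
    rng_conflict = np.random.default_rng(seed + 53)
    rng_noise = np.random.default_rng(seed + 67)
    rng_coef = np.random.default_rng(seed + 79)

    country_years = config.country_years()
    mlo, mhi = config.resolved_months_span()
    months = np.arange(mlo, mhi + 1)

    # -- static covariate fields and cities per country ---------------------
    static_fields: dict[str, dict] = {}
    for ci in range(config.n_countries):
        box = _country_box(ci)
        la0, la1, lo0, lo1 = box
        cities = np.column_stack(
            [rng_static.uniform(la0, la1, 2), rng_static.uniform(lo0, lo1, 2)]
        )
        static_fields[_country_code(ci)] = {
            "box": box,
            "cities": cities,
            "altitude": _bump_field(rng_static, box),
            "slope": _bump_field(rng_static, box),
            "tree": _bump_field(rng_static, box),
            "pasture": _bump_field(rng_static, box),
        }

    # -- rasters -------------------------------------------------------------
    raster_frames: dict[str, list[pd.DataFrame]] = {s: [] for s in RASTER_SOURCES}
    all_years = np.arange(mlo // 12, mhi // 12 + 1)
    anomalies = {
        (src, _country_code(ci), int(yr)): rng_raster.normal(0.0, 1.0)
        for src in RASTER_SOURCES
        for ci in range(config.n_countries)
        for yr in all_years
    }
    for ci in range(config.n_countries):
        code = _country_code(ci)
        la0, la1, lo0, lo1 = static_fields[code]["box"]
        res = config.grid_resolution_deg
        glat = np.arange(la0, la1 + res / 2, res)
        glon = np.arange(lo0, lo1 + res / 2, res)
        cell_lat, cell_lon = (a.ravel() for a in np.meshgrid(glat, glon, indexing="ij"))
        phase = rng_raster.uniform(0.0, 2.0 * np.pi)
        for src, (base, amp, ascale, nsd) in RASTER_SOURCES.items():
            base_f = _bump_field(rng_raster, static_fields[code]["box"])
            w_f = _bump_field(rng_raster, static_fields[code]["box"])
            bcell = base + base_f(cell_lat, cell_lon) * base * 0.2
            wcell = 1.0 + 0.5 * w_f(cell_lat, cell_lon)
            seas = amp * np.sin(2.0 * np.pi * (months % 12) / 12.0 + phase)
            anom = np.array(
                [anomalies[(src, code, int(m // 12))] for m in months]
            )
            vals = (
                bcell[:, None]
                + seas[None, :]
                + ascale * anom[None, :] * wcell[:, None]
                + nsd * rng_raster.normal(size=(cell_lat.size, months.size))
            )
            raster_frames[src].append(
                pd.DataFrame(
                    {
                        "country": code,
                        "lat": np.repeat(cell_lat, months.size),
                        "lon": np.repeat(cell_lon, months.size),
                        "month": np.tile(months, cell_lat.size),
                        "value": vals.ravel(),
                    }
                )
            )
    rasters = {
        src: pd.concat(frames, ignore_index=True)
        for src, frames in raster_frames.items()
    }

    # -- markets -------------------------------------------------------------
    market_rows = []
    for ci in range(config.n_countries):
        code = _country_code(ci)
        la0, la1, lo0, lo1 = static_fields[code]["box"]
        for mi in range(config.n_markets):
            mlat = rng_market.uniform(la0, la1)
            mlon = rng_market.uniform(lo0, lo1)
            for ki in range(config.n_commodities):
                base = float(np.exp(rng_market.uniform(np.log(0.2), np.log(2.0))))
                phase = rng_market.uniform(0.0, 2.0 * np.pi)
                shocks = rng_market.normal(0.0, 0.03, months.size).cumsum()
                price = base * np.exp(
                    0.10 * np.sin(2.0 * np.pi * (months % 12) / 12.0 + phase)
                    + 0.2 * np.tanh(shocks)
                )
                market_rows.append(
                    pd.DataFrame(
                        {
                            "country": code,
                            "market": f"{code}_M{mi}",
                            "lat": mlat,
                            "lon": mlon,
                            "commodity": f"com{ki}",
                            "month": months,
                            "price": price,
                        }
                    )
                )
    markets = pd.concat(market_rows, ignore_index=True)

    # -- conflicts -----------------------------------------------------------
    conflict_rows = []
    for ci in range(config.n_countries):
        code = _country_code(ci)
        la0, la1, lo0, lo1 = static_fields[code]["box"]
        for yr in all_years:
            n_ev = rng_conflict.poisson(config.conflict_rate)
            for _ in range(n_ev):
                day = int(rng_conflict.integers(0, 365))
                start = pd.Timestamp(f"{yr}-01-01") + pd.Timedelta(days=day)
                dur = int(rng_conflict.geometric(0.5)) - 1
                conflict_rows.append(
                    {
                        "country": code,
                        "lat": rng_conflict.uniform(la0, la1),
                        "lon": rng_conflict.uniform(lo0, lo1),
                        "start": start.date().isoformat(),
                        "end": (start + pd.Timedelta(days=dur)).date().isoformat(),
                        "deaths": 1 + int(rng_conflict.poisson(2.0)),
                    }
                )
    conflicts = pd.DataFrame(
        conflict_rows, columns=["country", "lat", "lon", "start", "end", "deaths"]
    )

    # -- enumeration areas with engineered features --------------------------
    ea_rows = []
    for ci in range(config.n_countries):
        code = _country_code(ci)
        sf = static_fields[code]
        la0, la1, lo0, lo1 = sf["box"]
        cmarkets = markets[markets["country"] == code]
        for yr in country_years[ci]:
            survey_start = date(yr, config.survey_start_month, 1)
            start_idx = ft.month_index(survey_start)
            n = config.eas_per_survey
            tlat = rng_ea.uniform(la0 + 0.2, la1 - 0.2, n)
            tlon = rng_ea.uniform(lo0 + 0.2, lo1 - 0.2, n)
            lat, lon = _jitter_disc(rng_ea, tlat, tlon, config.offset_km)

            alt = 1200.0 * (sf["altitude"](lat, lon) + 1.2)
            slope = 12.0 * np.abs(sf["slope"](lat, lon))
            tree = 100.0 * expit(2.0 * sf["tree"](lat, lon))
            pasture = expit(2.0 * sf["pasture"](lat, lon))
            dcity = np.min(
                np.stack(
                    [
                        ft.haversine_km(lat, lon, c[0], c[1])
                        for c in sf["cities"]
                    ]
                ),
                axis=0,
            )
            travel = 1.1 * dcity
            urban = (travel < 60.0).astype(int)

            # seasonal anomaly features from the rasters (single code path
            # with the real feature layer)
            anoms = {}
            for src in RASTER_SOURCES:
                sub = rasters[src]
                sub = sub[sub["country"] == code]
                anoms[src] = np.array(
                    [
                        ft.seasonal_zscore(sub, lat[i], lon[i], start_idx)
                        for i in range(n)
                    ]
                )

            # price features: per-survey (market, commodity) stats shared by
            # all EAs; only the distance ranking is EA-specific
            center = ((la0 + la1) / 2.0, (lo0 + lo1) / 2.0)
            stats = ft.price_window_features(cmarkets, center[0], center[1], start_idx)
            stats_by_market = {
                m: g.set_index("commodity")[["mean", "variance"]]
                for m, g in stats.groupby("market")
            }
            mk = cmarkets.drop_duplicates("market")[["market", "lat", "lon"]]

            ev_count, death_count = ft.conflict_window_counts(
                conflicts, code, survey_start
            )

            for i in range(n):
                row = {
                    "country": code,
                    "year": int(yr),
                    "lat": float(lat[i]),
                    "lon": float(lon[i]),
                    "urban": int(urban[i]),
                    "altitude": float(alt[i]),
                    "slope": float(slope[i]),
                    "tree_cover": float(tree[i]),
                    "pasture": float(pasture[i]),
                    "travel_time_city": float(travel[i]),
                    "sif_anom": float(anoms["sif"][i]),
                    "lst_anom": float(anoms["lst"][i]),
                    "precip_anom": float(anoms["precip"][i]),
                    "conflict_events_1y": ev_count,
                    "conflict_deaths_1y": death_count,
                    "survey_month": start_idx,
                }
                d = ft.haversine_km(
                    mk["lat"].to_numpy(), mk["lon"].to_numpy(), lat[i], lon[i]
                )
                order = mk["market"].to_numpy()[np.argsort(d, kind="stable")]
                for rank, mname in enumerate(order, start=1):
                    sm = stats_by_market.get(mname)
                    for ki in range(config.n_commodities):
                        com = f"com{ki}"
                        if sm is not None and com in sm.index:
                            row[f"price_m{rank}_{com}_mean"] = float(sm.loc[com, "mean"])
                            row[f"price_m{rank}_{com}_var"] = float(sm.loc[com, "variance"])
                        else:
                            row[f"price_m{rank}_{com}_mean"] = np.nan
                            row[f"price_m{rank}_{com}_var"] = np.nan
                ea_rows.append(row)
    ea = pd.DataFrame(ea_rows)

    # -- ground-truth outcomes ------------------------------------------------
    k = len(OUTCOME_NAMES)
    strengths = np.asarray(config.signal_strength_per_outcome, dtype=float)
    pool = ea[SIGNAL_POOL].to_numpy(dtype=float)
    mu = pool.mean(axis=0)
    sd = pool.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    pool_std = (pool - mu) / sd * SIGNAL_WEIGHTS

    alphas = rng_coef.uniform(-1.0, 0.2, k)

    def _standardized_component(rng):
        sel = np.sort(rng.choice(len(SIGNAL_POOL), size=5, replace=False))
        betas = rng.normal(0.0, 1.0, 5)
        gamma = rng.normal(0.0, 0.7)
        raw = pool_std[:, sel] @ betas + gamma * pool_std[:, sel[0]] * pool_std[:, sel[1]]
        rsd = raw.std(ddof=0)
        u = (raw - raw.mean()) / rsd if rsd > 0 else np.zeros_like(raw)
        info = {
            "features": [SIGNAL_POOL[s] for s in sel],
            "betas": betas.tolist(),
            "interaction": float(gamma),
        }
        return u, info

    # outcomes share a common signal component (poverty and malnutrition
    # co-vary with the same geography) plus outcome-specific structure
    w = float(config.signal_share_common)
    u_common, common_info = _standardized_component(rng_coef)
    coef_info = []
    eta = np.zeros((len(ea), k))
    for j in range(k):
        u_spec, spec_info = _standardized_component(rng_coef)
        u = np.sqrt(w) * u_common + np.sqrt(1.0 - w) * u_spec
        eta[:, j] = alphas[j] + strengths[j] * u
        coef_info.append(
            {"alpha": float(alphas[j]), "specific": spec_info}
        )
    signal = expit(eta)
    eps = rng_noise.multivariate_normal(
        np.zeros(k), np.asarray(config.outcome_noise_cov, dtype=float), size=len(ea),
        method="cholesky",
    )
    y_pre = signal + eps
    y = np.clip(y_pre, 0.0, 1.0)
    clip_fraction = float((y != y_pre).mean())
    for j, name in enumerate(OUTCOME_NAMES):
        ea[name] = y[:, j]
    front = ["country", "year", "lat", "lon", "urban"] + OUTCOME_NAMES
    feature_cols = [c for c in ea.columns if c not in front]
    ea = ea[front + feature_cols]

    truth = {
        "common_signal": common_info,
        "coefficients": coef_info,
        "noise_cov": np.asarray(config.outcome_noise_cov, dtype=float),
        "clip_fraction": clip_fraction,
        "signal": signal,
        "pre_clip": y_pre,
        "feature_columns": feature_cols,
    }
    return SyntheticWorld(
        config=config,
        ea_table=ea,
        rasters=rasters,
        markets=markets,
        conflicts=conflicts,
        truth=truth,
    )


def export_flat_table(world: SyntheticWorld, path=None) -> pd.DataFrame:
    """The flat EA table in the released-data schema (one row per EA).

    Columns: country, year, lat, lon, urban, the five prevalence outcomes,
    then all engineered features.  If ``path`` is given the table is written
    as UTF-8 CSV with a header row, '.' decimals and empty cells for missing
    values; it round-trips losslessly through :func:`mahaforest.io.read_flat_table`.
    """
    df = world.ea_table.copy()
    if path is not None:
        df.to_csv(path, index=False)
    return df
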