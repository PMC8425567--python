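"""Test/train regimes, metrics, aggregation and nowcast-map emission.

Two regimes are implemented:

* **sequential nowcasting** — for every country surveyed in year t with at
  least one earlier survey, train on all same-country surveys with year
  t' < t and predict the year-t clusters (early-warning use case);
* **contemporaneous prediction** — five-fold cross validation over the
  year-t survey: train on all prior surveys plus four folds of year t,
  predict the held-out fold (poverty-mapping use case).

Both the joint Mahalanobis forest (MRF) and the independent per-outcome
forest baseline (IRF) are run on the same filtered train/test data, and
performance is reported as out-of-sample r² and range-normalized RMSE at
three pooling levels (aggregate, country, survey).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import filter_missing
from .forest import IndependentForestRegressor, MahalanobisForestRegressor

__all__ = [
    "RegimeSplit",
    "make_sequential_splits",
    "make_contemporaneous_splits",
    "r_squared",
    "nrmse",
    "aggregate_metrics",
    "MetricsReport",
    "grouped_importance",
    "emit_nowcast_map",
    "run_regime",
]

_MAX_SEED = 2**31 - 1


@dataclass
class RegimeSplit:
    """One train/test assignment of EA-table rows."""

    kind: str  # "sequential" | "contemporaneous"
    country: str
    test_year: int
    train_index: np.ndarray
    test_index: np.ndarray
    fold: Optional[int] = None

    def __post_init__(self):
        self.train_index = np.asarray(self.train_index, dtype=int)
        self.test_index = np.asarray(self.test_index, dtype=int)


def make_sequential_splits(table: pd.DataFrame) -> list[RegimeSplit]:
    """One split per (country, year t) with at least one prior same-country
    survey: train = all years t' < t, test = year t.  Countries with a
    single survey round yield no splits."""
    splits = []
    for country, g in table.groupby("country", sort=True):
        years = sorted(g["year"].unique())
        for t in years[1:]:
            train = g.index[g["year"] < t].to_numpy()
            test = g.index[g["year"] == t].to_numpy()
            splits.append(
                RegimeSplit("sequential", str(country), int(t), train, test)
            )
    return splits


def make_contemporaneous_splits(
    table: pd.DataFrame, n_folds: int = 5, seed: int = 0
) -> list[RegimeSplit]:
    """Five-fold cross validation within each survey year.

    Year-t rows of each country are partitioned into ``n_folds`` near-equal
    folds by a seeded shuffle; each split trains on all same-country prior
    surveys plus the other folds and tests on the held-out fold.
    """
    rng = np.random.default_rng(seed)
    splits = []
    for country, g in table.groupby("country", sort=True):
        years = sorted(g["year"].unique())
        for t in years:
            year_idx = g.index[g["year"] == t].to_numpy()
            prior_idx = g.index[g["year"] < t].to_numpy()
            if len(year_idx) < n_folds:
                raise ValueError(
                    f"survey ({country}, {t}) has {len(year_idx)} rows; "
                    f"need at least n_folds={n_folds}"
                )
            perm = rng.permutation(year_idx)
            folds = np.array_split(perm, n_folds)
            for f, test in enumerate(folds):
                train = np.concatenate(
                    [prior_idx] + [folds[o] for o in range(n_folds) if o != f]
                )
                splits.append(
                    RegimeSplit(
                        "contemporaneous",
                        str(country),
                        int(t),
                        np.sort(train),
                        np.sort(test),
                        fold=f,
                    )
                )
    return splits


# ---------------------------------------------------------------------------
# Metrics


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Out-of-sample r²: 1 - SSE / SST with the baseline mean taken over the
    pooled observed test outcomes of the reporting unit.  May be negative;
    NaN (with a warning) when the observed outcomes are constant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn("constant observed outcomes: r^2 undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst


def nrmse(
    y: np.ndarray, yhat: np.ndarray, range_values: Optional[np.ndarray] = None
) -> float:
    """RMSE divided by the observed outcome range of the reporting unit.

    ``range_values`` defaults to the test outcomes themselves; pass the
    training outcomes to normalize by the in-sample (train) range instead.
    NaN (with a warning) on zero range.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    rv = y if range_values is None else np.asarray(range_values, dtype=float)
    rng = float(rv.max() - rv.min())
    if rng <= 0.0:
        warnings.warn("zero observed range: NRMSE undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return rmse / rng


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class MetricsReport:
    """Per-unit metric records plus country-mean summaries.

    ``records`` has one row per (variant, outcome, level, unit, fold) with
    columns r2 and nrmse; ``country_means`` carries size-weighted and
    unweighted means of the country-level rows (weights proportional to the
    pooled country test-row counts).
    """

    records: pd.DataFrame
    country_means: pd.DataFrame
    fold_summary: Optional[pd.DataFrame] = None


def _metric_rows(pred: pd.DataFrame, outcomes, level: str, keys: list[str]):
    rows = []
    for gval, g in pred.groupby(keys) if keys else [((), pred)]:
        if not isinstance(gval, tuple):
            gval = (gval,)
        unit = dict(zip(keys, gval))
        for variant in sorted(g["variant"].unique()):
            gv = g[g["variant"] == variant]
            for out in outcomes:
                go = gv[gv["outcome"] == out]
                y = go["y_true"].to_numpy()
                yhat = go["y_pred"].to_numpy()
                if y.size < 2:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    r2 = r_squared(y, yhat)
                    nr = nrmse(y, yhat)
                rows.append(
                    {
                        "level": level,
                        "variant": variant,
                        "outcome": out,
                        "n": int(y.size),
                        "r2": r2,
                        "nrmse": nr,
                        **unit,
                    }
                )
    return rows


def aggregate_metrics(
    predictions: pd.DataFrame, outcomes: Optional[Sequence[str]] = None
) -> MetricsReport:
    """Metrics at the aggregate, country and survey pooling levels.

    ``predictions`` is long-format with columns country, year, fold,
    variant, outcome, y_true, y_pred (fold may be NaN for the sequential
    regime).  For fold-based (contemporaneous) predictions metrics are
    computed within each fold and the report carries across-fold mean/std.
    """
    pred = predictions.copy()
    if outcomes is None:
        outcomes = sorted(pred["outcome"].unique())
    has_folds = "fold" in pred.columns and pred["fold"].notna().any()
    fold_key = ["fold"] if has_folds else []

    rows = []
    rows += _metric_rows(pred, outcomes, "aggregate", fold_key)
    rows += _metric_rows(pred, outcomes, "country", ["country"] + fold_key)
    rows += _metric_rows(pred, outcomes, "survey", ["country", "year"] + fold_key)
    records = pd.DataFrame(rows)

    # size-weighted and unweighted means of country-level rows
    country = records[records["level"] == "country"]
    cm_rows = []
    for (variant, out), g in country.groupby(["variant", "outcome"]):
        w = g["n"].to_numpy(dtype=float)
        for metric in ("r2", "nrmse"):
            v = g[metric].to_numpy(dtype=float)
            ok = np.isfinite(v)
            if not ok.any():
                continue
            cm_rows.append(
                {
                    "variant": variant,
                    "outcome": out,
                    "metric": metric,
                    "weighted_mean": float(np.average(v[ok], weights=w[ok])),
                    "unweighted_mean": float(v[ok].mean()),
                }
            )
    country_means = pd.DataFrame(cm_rows)

    fold_summary = None
    if has_folds:
        fs = (
            records.groupby(
                ["level", "variant", "outcome"]
                + [c for c in ("country", "year") if c in records.columns],
                dropna=False,
            )
            .agg(
                r2_mean=("r2", "mean"),
                r2_std=("r2", "std"),
                nrmse_mean=("nrmse", "mean"),
                nrmse_std=("nrmse", "std"),
                n_folds=("r2", "size"),
            )
            .reset_index()
        )
        fold_summary = fs
    return MetricsReport(records=records, country_means=country_means,
                         fold_summary=fold_summary)


def grouped_importance(
    importances: dict[str, float], groups: dict[str, str]
) -> dict[str, float]:
    """Sum per-feature importances within named data-type groups.

    Raises on any feature lacking a group assignment.
    """
    unmapped = [f for f in importances if f not in groups]
    if unmapped:
        raise ValueError(f"features without a group mapping: {unmapped}")
    out: dict[str, float] = {}
    for f, v in importances.items():
        out[groups[f]] = out.get(groups[f], 0.0) + float(v)
    return out


def emit_nowcast_map(
    forest,
    test_table: pd.DataFrame,
    feature_cols: Sequence[str],
    outcome_names: Sequence[str],
    path=None,
) -> pd.DataFrame:
    """Per-EA predicted prevalence and across-tree std, as a long table.

    Columns: lat, lon, outcome, mean, sd — one record per (test EA,
    outcome); written as CSV when ``path`` is given.
    """
    X = test_table[list(feature_cols)].to_numpy(dtype=float)
    mean, sd = forest.predict(X, return_std=True)
    rows = []
    lats = test_table["lat"].to_numpy()
    lons = test_table["lon"].to_numpy()
    for j, out in enumerate(outcome_names):
        for i in range(len(test_table)):
            rows.append(
                {
                    "lat": float(lats[i]),
                    "lon": float(lons[i]),
                    "outcome": out,
                    "mean": float(mean[i, j]),
                    "sd": float(sd[i, j]),
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Regime runner


def run_regime(
    table: pd.DataFrame,
    outcome_cols: Sequence[str],
    feature_cols: Sequence[str],
    regime: str = "sequential",
    variants: Sequence[str] = ("mrf", "irf"),
    n_folds: int = 5,
    seed: int = 0,
    forest_params: Optional[dict] = None,
) -> tuple[pd.DataFrame, list]:
    """Fit and test both model variants over every split of a regime.

    For each split the stacked train+test rows pass through the missingness
    filter, then an MRF (FGLS precision) and/or the IRF baseline are fitted
    on the shared training rows and evaluated on the shared test rows.
    Returns (long-format predictions, per-split filter reports).
    """
    forest_params = dict(forest_params or {})
    table = table.reset_index(drop=True)
    if regime == "sequential":
        splits = make_sequential_splits(table)
    elif regime == "contemporaneous":
        splits = make_contemporaneous_splits(table, n_folds=n_folds, seed=seed)
    else:
        raise ValueError("regime must be 'sequential' or 'contemporaneous'")

    pred_rows = []
    reports = []
    for si, split in enumerate(splits):
        regime_rows = np.concatenate([split.train_index, split.test_index])
        sub = table.loc[regime_rows]
        filtered, report = filter_missing(sub, list(feature_cols), list(outcome_cols))
        reports.append((split, report))
        feats = [c for c in feature_cols if c in filtered.columns]
        # filter_missing resets the index; recover train/test membership by
        # re-deriving its row rule on the stacked regime table
        kept = sub[feats + list(outcome_cols)].notna().all(axis=1).to_numpy()
        n_tr = len(split.train_index)
        train = sub.iloc[:n_tr][kept[:n_tr]]
        test = sub.iloc[n_tr:][kept[n_tr:]]
        if len(train) < 2 or len(test) < 1:
            continue
        X_train = train[feats].to_numpy(dtype=float)
        Y_train = train[list(outcome_cols)].to_numpy(dtype=float)
        X_test = test[feats].to_numpy(dtype=float)
        Y_test = test[list(outcome_cols)].to_numpy(dtype=float)
        split_seed = (seed * 1000003 + si * 7919 + 17) % _MAX_SEED

        models = {}
        if "mrf" in variants:
            models["mrf"] = MahalanobisForestRegressor(
                precision="fgls", random_state=split_seed, **forest_params
            )
        if "irf" in variants:
            models["irf"] = IndependentForestRegressor(
                random_state=split_seed, **forest_params
            )
        for vname, model in models.items():
            model.fit(X_train, Y_train)
            mean, sd = model.predict(X_test, return_std=True)
            for j, out in enumerate(outcome_cols):
                for i in range(len(test)):
                    pred_rows.append(
                        {
                            "country": split.country,
                            "year": split.test_year,
                            "fold": split.fold,
                            "variant": vname,
                            "outcome": out,
                            "lat": float(test["lat"].iloc[i]) if "lat" in test else np.nan,
                            "lon": float(test["lon"].iloc[i]) if "lon" in test else np.nan,
                            "y_true": float(Y_test[i, j]),
                            "y_pred": float(mean[i, j]),
                            "y_sd": float(sd[i, j]),
                        }
                    )
    predictions = pd.DataFrame(pred_rows)
    return predictions, reports
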