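"""Lagged panel designs and random-forest forecasting under temporal CV.

The forecasting model regresses the district phase on three lag blocks,
each measured at the district, its province and its country:

* six reporting-period lags of the phase itself;
* five time-invariant district attributes plus nine time-varying
  traditional factors at months t-3 .. t-8 (six monthly lags);
* the retained news factors over the same monthly lags.

The *traditional* variant uses the first two blocks (167 columns beyond
the phase lags: 9 factors x 3 levels x 6 lags + 5 static), the *news*
variant swaps the traditional block for the news block, and *combined*
uses everything.  All time-varying regressors end at least ``horizon``
months before the target period, so every prediction only uses
information observed at least one quarter in the past.

Cross-validation is temporal: contiguous, ordered, disjoint test windows,
a validation window immediately before each test window, and training on
everything earlier.  Hyperparameters minimize validation RMSE per fold;
the reported RMSE is the unweighted mean of per-fold test RMSEs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from crisiscast.world import Calendar, ConfigurationError, GeoHierarchy

#: the full hyperparameter search grid of the reference procedure
PAPER_GRID: dict[str, list] = {
    "n_estimators": list(range(10, 101, 10)),
    "min_samples_split": [0.1, 0.5, 1, 2, 3, 4, 5],
    "max_features": ["auto", "sqrt", "log2"],
    "min_impurity_decrease": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
}

#: desk-scale default grid (4 combinations per fold)
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [40],
    "min_samples_split": [2, 5],
    "max_features": ["sqrt"],
    "min_impurity_decrease": [1e-4, 1e-3],
}


def map_hyperparams(combo: dict) -> dict:
    """Translate grid values to scikit-learn arguments.

    ``min_samples_split`` values at or below 1 are fractions of the
    training sample (1 -> 1.0, the whole sample); 2 and above are counts.
    ``max_features`` "auto" means all features, its historical meaning
    for regression forests.
    """
    out = dict(combo)
    mss = out["min_samples_split"]
    out["min_samples_split"] = float(mss) if mss <= 1 else int(mss)
    if out.get("max_features") == "auto":
        out["max_features"] = None
    return out


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """A model-ready design: feature frame X, target y, and provenance."""

    X: pd.DataFrame  # indexed by (district_id, period)
    y: pd.Series
    variant: str
    horizon: int
    n_dropped: int
    column_groups: dict[str, list[str]] = field(default_factory=dict)

    @property
    def periods(self) -> pd.PeriodIndex:
        return pd.PeriodIndex(self.X.index.get_level_values("period"), freq="M")


def _panel_blocks(
    panel: pd.DataFrame, value_col: str = "value"
) -> dict[tuple[str, str], tuple[np.ndarray, dict[str, int], dict[int, int]]]:
    """(name, level) -> (unit x month matrix, unit row map, month-ordinal col map)."""
    out: dict[tuple[str, str], tuple[np.ndarray, dict[str, int], dict[int, int]]] = {}
    name_col = "factor" if "factor" in panel.columns else "feature"
    for (name, level), grp in panel.groupby([name_col, "level"], observed=True):
        wide = grp.pivot_table(index="unit_id", columns="month", values=value_col)
        ords = np.array([pd.Period(m, freq="M").ordinal for m in wide.columns])
        order = np.argsort(ords)
        mat = wide.to_numpy(dtype=float)[:, order]
        out[(name, level)] = (
            mat,
            {u: i for i, u in enumerate(wide.index)},
            {int(o): j for j, o in enumerate(ords[order])},
        )
    return out


def _gather_block(
    block: tuple[np.ndarray, dict[str, int], dict[int, int]],
    units_row: list[str],
    month_ords: np.ndarray,
) -> np.ndarray:
    """Vectorized lookup of an (n_rows x n_lags) lag slab; NaN where absent."""
    mat, upos, cpos = block
    u = np.fromiter((upos.get(x, -1) for x in units_row), dtype=int, count=len(units_row))
    cols = np.fromiter(
        (cpos.get(int(o), -1) for o in month_ords.ravel()), dtype=int, count=month_ords.size
    ).reshape(month_ords.shape)
    ok = (u >= 0)[:, None] & (cols >= 0)
    vals = np.full(month_ords.shape, np.nan)
    uu = np.broadcast_to(u[:, None], month_ords.shape)
    vals[ok] = mat[uu[ok], cols[ok]]
    return vals


def build_design(
    ipc: pd.DataFrame,
    factors: pd.DataFrame | None,
    static: pd.DataFrame | None,
    news: pd.DataFrame | None,
    world: GeoHierarchy,
    variant: str = "combined",
    horizon_months: int = 3,
    n_y_lags: int = 6,
    n_month_lags: int = 6,
    expert: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Assemble one row per (district, period) with all lag blocks.

    ``factors`` must carry district, province and country levels (see
    :func:`crisiscast.factors.aggregate_factor_panel`); ``news`` likewise.
    Phase lags are the ``n_y_lags`` most recent reporting periods ending
    at or before t - horizon; monthly lags are months t - n - 2 - max(0,
    horizon - 3) for n = 1..n_month_lags.  Rows lacking any required lag
    are dropped and counted.  ``expert`` (district_id, period, forecast)
    adds a single extra regressor column when supplied.
    """
    if variant not in ("traditional", "news", "combined"):
        raise ConfigurationError(f"unknown variant {variant!r}")
    use_trad = variant in ("traditional", "combined")
    use_news = variant in ("news", "combined")
    if use_news and (news is None or news.empty):
        raise ConfigurationError("news/combined variant requires a non-empty news panel")
    if use_trad and (factors is None or static is None):
        raise ConfigurationError("traditional/combined variant requires factor panels")

    ipc = ipc.copy()
    ipc["period"] = pd.PeriodIndex([pd.Period(p, freq="M") for p in ipc["period"]], freq="M")
    shift = max(0, horizon_months - 3)
    lag_months = np.array([3 + shift + j for j in range(n_month_lags)])  # months back from t

    trad_blocks = _panel_blocks(factors) if use_trad else {}
    news_blocks = _panel_blocks(news) if use_news else {}
    static_wide = (
        static.pivot_table(index="district_id", columns="attr", values="value")
        if use_trad
        else None
    )
    expert_map: dict[tuple[str, pd.Period], float] = {}
    if expert is not None:
        for _, r in expert.iterrows():
            expert_map[(r["district_id"], pd.Period(r["period"], freq="M"))] = float(r["forecast"])

    # column order: phase lags, static, traditional, news, expert
    columns: list[str] = [f"ylag{j}" for j in range(1, n_y_lags + 1)]
    groups: dict[str, list[str]] = {"y_lags": list(columns)}
    if use_trad:
        static_cols = [f"static_{a}" for a in static_wide.columns]
        trad_cols = [
            f"v_{name}_{lvl[0]}_n{j}"
            for (name, lvl) in sorted(trad_blocks)
            for j in range(1, n_month_lags + 1)
        ]
        groups["static"] = static_cols
        groups["traditional"] = trad_cols
        columns += static_cols + trad_cols
    if use_news:
        news_cols = [
            f"x_{name}_{lvl[0]}_n{j}"
            for (name, lvl) in sorted(news_blocks)
            for j in range(1, n_month_lags + 1)
        ]
        groups["news"] = news_cols
        columns += news_cols
    if expert is not None:
        groups["expert"] = ["expert_forecast"]
        columns.append("expert_forecast")

    # candidate rows: every (district, period) with full phase-lag history
    row_d: list[str] = []
    row_t: list[pd.Period] = []
    ylag_rows: list[np.ndarray] = []
    targets: list[float] = []
    n_dropped = 0
    for d, grp in ipc.groupby("district_id", observed=True, sort=True):
        grp = grp.sort_values("period")
        pers = list(grp["period"])
        phases = grp["phase"].to_numpy(dtype=float)
        for i, t in enumerate(pers):
            usable = [j for j in range(i) if pers[j] <= t - horizon_months]
            if len(usable) < n_y_lags:
                n_dropped += 1
                continue
            row_d.append(d)
            row_t.append(t)
            ylag_rows.append(phases[usable[-n_y_lags:]][::-1])
            targets.append(phases[i])
    if not row_d:
        raise ConfigurationError("design is empty: not enough lag history")

    n_rows = len(row_d)
    t_ord = np.array([t.ordinal for t in row_t])
    month_ords = t_ord[:, None] - lag_months[None, :]
    units_by_level = {
        "d": row_d,
        "p": [world.province_of[d] for d in row_d],
        "c": [world.country_of(d) for d in row_d],
    }

    slabs: list[np.ndarray] = [np.asarray(ylag_rows)]
    if use_trad:
        static_vals = {d: static_wide.loc[d].to_numpy(dtype=float) for d in static_wide.index}
        nan_static = np.full(len(static_wide.columns), np.nan)
        slabs.append(np.vstack([static_vals.get(d, nan_static) for d in row_d]))
        for key in sorted(trad_blocks):
            slabs.append(_gather_block(trad_blocks[key], units_by_level[key[1][0]], month_ords))
    if use_news:
        for key in sorted(news_blocks):
            slabs.append(_gather_block(news_blocks[key], units_by_level[key[1][0]], month_ords))
    if expert is not None:
        slabs.append(
            np.array([[expert_map.get((d, t), np.nan)] for d, t in zip(row_d, row_t)])
        )
    full = np.column_stack(slabs)
    valid = np.all(np.isfinite(full), axis=1)
    n_dropped += int((~valid).sum())
    if not valid.any():
        raise ConfigurationError("design is empty: not enough lag history")
    idx = pd.MultiIndex.from_tuples(
        [(d, t) for d, t, v in zip(row_d, row_t, valid) if v],
        names=["district_id", "period"],
    )
    X = pd.DataFrame(full[valid], index=idx, columns=columns)
    y = pd.Series(np.asarray(targets)[valid], index=idx, name="phase")
    return DesignMatrix(
        X=X, y=y, variant=variant, horizon=horizon_months, n_dropped=n_dropped,
        column_groups=groups,
    )


def align_designs(a: DesignMatrix, b: DesignMatrix) -> tuple[DesignMatrix, DesignMatrix]:
    """Restrict two designs to their common (district, period) rows.

    Model comparisons must see the exact same observations; intersection
    never increases either design's row count.
    """
    common = a.X.index.intersection(b.X.index)
    out = []
    for dm in (a, b):
        out.append(
            DesignMatrix(
                X=dm.X.loc[common], y=dm.y.loc[common], variant=dm.variant,
                horizon=dm.horizon, n_dropped=dm.n_dropped, column_groups=dm.column_groups,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# temporal folds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fold:
    train: pd.PeriodIndex
    validation: pd.PeriodIndex
    test: pd.PeriodIndex


@dataclass(frozen=True)
class CVFoldPlan:
    folds: tuple[Fold, ...]

    def __iter__(self):
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)

    def validate(self) -> None:
        """Assert the temporal ordering invariants across the whole plan."""
        prev_test_end = None
        for f in self.folds:
            if not (len(f.train) and len(f.validation) and len(f.test)):
                raise ConfigurationError("fold with an empty window")
            if not (max(f.train) < min(f.validation) < min(f.test)):
                raise ConfigurationError("fold windows out of order")
            if max(f.validation) >= min(f.test):
                raise ConfigurationError("validation overlaps test")
            if prev_test_end is not None and min(f.test) <= prev_test_end:
                raise ConfigurationError("test windows not disjoint/ordered")
            prev_test_end = max(f.test)


def make_folds(
    calendar: Calendar,
    n_folds: int = 10,
    val_periods: int = 2,
    test_periods: int | None = None,
    burn_in_periods: int = 8,
) -> CVFoldPlan:
    """Partition post-burn-in reporting periods into ordered test windows.

    Each fold tests on one window, validates on the ``val_periods``
    periods immediately before it, and trains on every earlier period.
    The plan depends only on the calendar.
    """
    periods = calendar.reporting_periods
    avail = periods[burn_in_periods:]
    if test_periods is None:
        test_periods = len(avail) // n_folds
    need = n_folds * test_periods
    if test_periods < 1 or need > len(avail):
        raise ConfigurationError(
            f"need {max(need, n_folds)} post-burn-in periods for {n_folds} folds, "
            f"have {len(avail)}"
        )
    span = avail[len(avail) - need :]
    folds = []
    for f in range(n_folds):
        test = span[f * test_periods : (f + 1) * test_periods]
        val_end_pos = periods.get_loc(test[0])
        val = periods[val_end_pos - val_periods : val_end_pos]
        train = periods[: val_end_pos - val_periods]
        if not len(train):
            raise ConfigurationError("fold has no training periods; increase burn-in")
        folds.append(
            Fold(
                train=pd.PeriodIndex(train, freq="M"),
                validation=pd.PeriodIndex(val, freq="M"),
                test=pd.PeriodIndex(test, freq="M"),
            )
        )
    plan = CVFoldPlan(folds=tuple(folds))
    plan.validate()
    return plan


def assert_no_leakage(design: DesignMatrix, plan: CVFoldPlan) -> None:
    """Every regressor month in a fold's training rows precedes its test window.

    Time-varying regressors for a row targeted at period t end at month
    t - horizon; training rows satisfy t <= last training/validation
    period, which precedes the fold's test start.
    """
    plan.validate()
    horizon = design.horizon
    for f in plan:
        fit_periods = set(f.train) | set(f.validation)
        fit_rows = [t for t in design.periods if t in fit_periods]
        if not fit_rows:
            continue
        latest_regressor_month = max(fit_rows) - horizon
        if not latest_regressor_month < min(f.test):
            raise ConfigurationError("leakage: training regressors reach into test window")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class ForecastResult:
    """Predictions and per-fold reports of one model variant."""

    variant: str
    predictions: pd.DataFrame  # district_id, period, y, yhat, fold
    fold_reports: list[dict]
    rmse: float  # unweighted mean of per-fold test RMSEs

    @property
    def errors(self) -> np.ndarray:
        """Pooled test errors, ordered by period then district."""
        df = self.predictions.sort_values(["period", "district_id"])
        return (df["y"] - df["yhat"]).to_numpy()


def rmse(errors) -> float:
    """Root mean squared error of a non-empty error sequence."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("rmse of an empty error list is undefined")
    return float(np.sqrt(np.mean(e**2)))


def _grid_combos(grid: dict[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


def fit_predict(
    design: DesignMatrix,
    plan: CVFoldPlan,
    grid: dict[str, list] | None = None,
    seed: int = 0,
) -> ForecastResult:
    """Temporal-CV random-forest fit of one design.

    Per fold: grid search minimizing validation RMSE (ties broken by grid
    order), refit at the optimum on training + validation, predict the
    test window.  Fixed seed gives bit-identical predictions.  Folds whose
    test window intersects no design rows are skipped and reported.
    """
    if grid is None:
        grid = DEFAULT_GRID
    assert_no_leakage(design, plan)
    combos = _grid_combos(grid)
    periods = design.periods
    Xv = design.X.to_numpy(dtype=float)
    yv = design.y.to_numpy(dtype=float)

    preds_frames: list[pd.DataFrame] = []
    reports: list[dict] = []
    fold_rmses: list[float] = []
    for fi, fold in enumerate(plan):
        rs = (seed * 1009 + fi) % (2**31)
        in_train = periods.isin(fold.train)
        in_val = periods.isin(fold.validation)
        in_test = periods.isin(fold.test)
        if not in_test.any():
            reports.append({"fold": fi, "skipped": True, "reason": "empty test intersection"})
            continue
        if not in_train.any() or not in_val.any():
            reports.append({"fold": fi, "skipped": True, "reason": "empty train/validation"})
            continue
        best: tuple[float, dict] | None = None
        for combo in combos:
            model = RandomForestRegressor(
                **map_hyperparams(combo), random_state=rs, n_jobs=1
            )
            model.fit(Xv[in_train], yv[in_train])
            val_rmse = rmse(yv[in_val] - model.predict(Xv[in_val]))
            if best is None or val_rmse < best[0]:
                best = (val_rmse, combo)
        val_rmse, best_combo = best
        model = RandomForestRegressor(
            **map_hyperparams(best_combo), random_state=rs, n_jobs=1
        )
        fit_mask = in_train | in_val
        model.fit(Xv[fit_mask], yv[fit_mask])
        yhat = model.predict(Xv[in_test])
        test_rmse = rmse(yv[in_test] - yhat)
        fold_rmses.append(test_rmse)
        sub = design.X.index[in_test]
        preds_frames.append(
            pd.DataFrame(
                {
                    "district_id": sub.get_level_values("district_id"),
                    "period": sub.get_level_values("period"),
                    "y": yv[in_test],
                    "yhat": yhat,
                    "fold": fi,
                }
            )
        )
        reports.append(
            {
                "fold": fi,
                "skipped": False,
                "best_params": best_combo,
                "val_rmse": val_rmse,
                "test_rmse": test_rmse,
                "n_train": int(fit_mask.sum()),
                "n_test": int(in_test.sum()),
            }
        )
    if not preds_frames:
        raise ConfigurationError("no fold produced test predictions")
    predictions = pd.concat(preds_frames, ignore_index=True)
    return ForecastResult(
        variant=design.variant,
        predictions=predictions,
        fold_reports=reports,
        rmse=float(np.mean(fold_rmses)),
    )
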