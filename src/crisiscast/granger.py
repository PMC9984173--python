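"""Panel Granger-causality screening of news factors.

A candidate news factor survives screening when its lagged monthly values
add explanatory power for the district-level crisis phase beyond the
phase's own lags.  The workhorse is a pooled panel autoregressive
distributed lag (ADL) regression at the district-period level,

    y[d,t] = a0 + a1 y[d,t-1p] + ... + ap y[d,t-pp]
                + b1 x[d,t-3m] + ... + bq x[d,t-(q+2)m] + eps,

where phase lags are indexed in reporting periods and factor lags in
calendar months starting three months back (the forecasting horizon).
Orders (p, q) are chosen by AIC on a common estimation sample; the
screen rejects the no-causality null with a nested F-test of all b's
jointly zero at the 1% level.  Because the test assumes stationarity,
each factor series is differenced until it passes an augmented
Dickey-Fuller (ADF) test; the differenced series is what enters both
screening and forecasting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from crisiscast.world import Calendar


class SeriesTooShortError(ValueError):
    """Series has too few observations for a meaningful stationarity test."""


@dataclass(frozen=True)
class ADFResult:
    """Outcome of ADF-guided differencing of one series."""

    series: np.ndarray
    d: int
    stationary: bool
    degenerate: bool = False


@dataclass(frozen=True)
class ADLFit:
    """A fitted pooled panel ADL model."""

    intercept: float
    a: np.ndarray  # phase-lag coefficients a1..ap
    b: np.ndarray  # factor-lag coefficients b1..bq
    p: int
    q: int
    aic: float
    rss: float
    n_obs: int


def adf_difference(
    series: np.ndarray,
    level: float = 0.05,
    max_diff: int = 2,
    min_len: int = 20,
    maxlag: int = 12,
) -> ADFResult:
    """Difference a series until the ADF test rejects a unit root.

    Returns the d-th difference with the smallest ``d <= max_diff`` whose
    ADF p-value (constant, no trend, lag order by AIC up to ``maxlag``)
    is below ``level``; if none qualifies, the ``max_diff``-th difference
    with ``stationary=False``.  A constant series is degenerate (zero
    variance) and returned as-is with a flag.
    """
    x = np.asarray(series, dtype=float)
    for d in range(max_diff + 1):
        s = np.diff(x, n=d) if d else x
        if len(s) < min_len:
            raise SeriesTooShortError(f"{len(s)} observations after differencing {d} times")
        if np.ptp(s) == 0:
            return ADFResult(series=s, d=d, stationary=False, degenerate=True)
        lag = min(maxlag, max(0, len(s) // 2 - 3))  # adfuller needs maxlag < n/2 - 2
        pval = adfuller(s, maxlag=lag, regression="c", autolag="AIC")[1]
        if pval < level:
            return ADFResult(series=s, d=d, stationary=True)
    s = np.diff(x, n=max_diff) if max_diff else x
    return ADFResult(series=s, d=max_diff, stationary=False)


# ---------------------------------------------------------------------------
# panel ADL
# ---------------------------------------------------------------------------


def _stack_panel(
    y: pd.DataFrame,
    x: pd.DataFrame,
    p_max: int,
    q_max: int,
    periods: pd.PeriodIndex | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack district-period rows with full (p_max, q_max) lag history.

    ``y``: columns (district_id, period, phase); ``x``: columns
    (district_id, month, value), monthly.  Returns target, phase-lag
    matrix (p_max cols), factor-lag matrix (q_max cols, months t-3 ..
    t-q_max-2), plus row district and period arrays.
    """
    x_wide = x.pivot_table(index="unit_id" if "unit_id" in x else "district_id",
                           columns="month", values="value")
    x_wide.columns = pd.PeriodIndex([pd.Period(m, freq="M") for m in x_wide.columns], freq="M")
    targets, ylags, xlags, row_d, row_t = [], [], [], [], []
    for d, grp in y.groupby("district_id", observed=True, sort=True):
        grp = grp.sort_values("period")
        phases = grp["phase"].to_numpy(dtype=float)
        pers = list(grp["period"])
        if periods is not None:
            keep = {p for p in periods}
        xs = x_wide.loc[d] if d in x_wide.index else None
        for i in range(p_max, len(pers)):
            t = pers[i]
            if periods is not None and t not in keep:
                continue
            months = [t - 3 - j for j in range(q_max)]
            if xs is None or any(m not in xs.index or not np.isfinite(xs[m]) for m in months):
                continue
            targets.append(phases[i])
            ylags.append(phases[i - p_max : i][::-1])
            xlags.append([xs[m] for m in months])
            row_d.append(d)
            row_t.append(t)
    if not targets:
        raise ValueError("no stackable district-period observations")
    return (
        np.asarray(targets),
        np.asarray(ylags),
        np.asarray(xlags),
        np.asarray(row_d, dtype=object),
        np.asarray(row_t, dtype=object),
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood AIC up to an additive constant
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)


def fit_panel_adl(
    y: pd.DataFrame,
    x: pd.DataFrame,
    p_range: tuple[int, ...] = (1, 2, 3, 4),
    q_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    periods: pd.PeriodIndex | None = None,
) -> ADLFit:
    """Pooled least-squares ADL fit with AIC order selection.

    All (p, q) candidates are fit on the common sample defined by the
    largest orders in the grid so their AICs are comparable.  Raises
    ``np.linalg.LinAlgError`` on a rank-deficient design.
    """
    p_max, q_max = max(p_range), max(q_range)
    target, ylags, xlags, _, _ = _stack_panel(y, x, p_max, q_max, periods)
    n = len(target)
    best: ADLFit | None = None
    for p, q in itertools.product(sorted(p_range), sorted(q_range)):
        X = np.column_stack([np.ones(n), ylags[:, :p], xlags[:, :q]])
        coef, rss = _ols(X, target)
        aic = _aic(rss, n, p + q)
        if best is None or aic < best.aic:
            best = ADLFit(
                intercept=float(coef[0]),
                a=coef[1 : 1 + p].copy(),
                b=coef[1 + p :].copy(),
                p=p,
                q=q,
                aic=aic,
                rss=rss,
                n_obs=n,
            )
    assert best is not None
    return best


def nested_f_test(
    target: np.ndarray, ylags: np.ndarray, xlags: np.ndarray, p: int, q: int
) -> tuple[float, float, float, float]:
    """Nested F-test of the q factor-lag coefficients being jointly zero.

    Returns (F, p-value, RSS_restricted, RSS_full) with
    F = [(RSS_r - RSS_f)/q] / [RSS_f/(n - p - q - 1)].
    """
    n = len(target)
    X_full = np.column_stack([np.ones(n), ylags[:, :p], xlags[:, :q]])
    X_restr = np.column_stack([np.ones(n), ylags[:, :p]])
    _, rss_f = _ols(X_full, target)
    _, rss_r = _ols(X_restr, target)
    dof = n - p - q - 1
    f_stat = ((rss_r - rss_f) / q) / (rss_f / dof)
    pval = float(stats.f.sf(f_stat, q, dof))
    return float(f_stat), pval, rss_r, rss_f


def pruned_f_test(
    target: np.ndarray, ylags: np.ndarray, xlags: np.ndarray, p: int, q: int,
    t_crit: float = 1.96,
) -> tuple[float, float, int]:
    """Variant screen: drop individually insignificant factor lags first.

    Factor lags whose |t| < ``t_crit`` in the full fit are removed, then
    the surviving lags are tested jointly against the phase-lags-only
    model.  Returns (F, p-value, number of surviving lags); zero
    survivors yields (0, 1, 0), i.e. no explanatory power.
    """
    n = len(target)
    X_full = np.column_stack([np.ones(n), ylags[:, :p], xlags[:, :q]])
    coef, rss_f = _ols(X_full, target)
    dof_full = n - X_full.shape[1]
    sigma2 = rss_f / dof_full
    cov = sigma2 * np.linalg.inv(X_full.T @ X_full)
    tstats = coef[1 + p :] / np.sqrt(np.diag(cov)[1 + p :])
    keep = np.abs(tstats) >= t_crit
    if not keep.any():
        return 0.0, 1.0, 0
    q_sel = int(keep.sum())
    X_sel = np.column_stack([np.ones(n), ylags[:, :p], xlags[:, :q][:, keep]])
    _, rss_sel = _ols(X_sel, target)
    X_restr = np.column_stack([np.ones(n), ylags[:, :p]])
    _, rss_r = _ols(X_restr, target)
    dof = n - p - q_sel - 1
    f_stat = ((rss_r - rss_sel) / q_sel) / (rss_sel / dof)
    return float(f_stat), float(stats.f.sf(f_stat, q_sel, dof)), q_sel


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def _feature_difference_order(
    x_wide: pd.DataFrame,
    train_months: pd.PeriodIndex,
    adf_level: float,
    max_diff: int,
    maxlag: int,
    district_sample: int | None,
) -> tuple[int, bool]:
    """Per-feature differencing order: the median of per-district minimal
    orders (rounded up), computed on the training window only."""
    cols = [m for m in train_months if m in x_wide.columns]
    mat = x_wide[cols]
    rows = mat.index[:district_sample] if district_sample else mat.index
    orders, stationary_flags = [], []
    for d in rows:
        s = mat.loc[d].to_numpy(dtype=float)
        s = s[np.isfinite(s)]
        if np.ptp(s) == 0:
            continue
        try:
            res = adf_difference(s, level=adf_level, max_diff=max_diff, maxlag=maxlag)
        except SeriesTooShortError:
            continue
        orders.append(res.d)
        stationary_flags.append(res.stationary)
    if not orders:
        return 0, False
    d = int(np.ceil(np.median(orders)))
    return d, bool(np.mean(stationary_flags) >= 0.5)


def difference_panel(x: pd.DataFrame, d: int) -> pd.DataFrame:
    """d-th difference of each district's monthly series, month-aligned.

    The differenced value at month m uses months m-d..m; the first d
    months of each district are dropped.  Long in, long out.
    """
    if d == 0:
        return x
    key = "unit_id" if "unit_id" in x else "district_id"
    out = []
    for _, grp in x.groupby(key, observed=True, sort=True):
        grp = grp.sort_values("month").copy()
        grp["value"] = grp["value"].diff(1)
        for _ in range(d - 1):
            grp["value"] = grp["value"].diff(1)
        out.append(grp.iloc[d:])
    return pd.concat(out, ignore_index=True)


def granger_screen(
    features: list[str],
    ipc: pd.DataFrame,
    news: pd.DataFrame,
    train_end: pd.Period | str,
    level: float = 0.01,
    p_range: tuple[int, ...] = (1, 2, 3, 4),
    q_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    adf_level: float = 0.05,
    max_diff: int = 2,
    adf_maxlag: int = 12,
    adf_district_sample: int | None = None,
    eval_end: pd.Period | str | None = None,
    drop_insignificant_lags: bool = False,
) -> pd.DataFrame:
    """Screen news factors by panel Granger causality on training data.

    Per feature: ADF-guided differencing (order decided on the training
    window), AIC order selection, nested F-test of the factor lags at
    ``level``; retained iff p-value < level.  With
    ``drop_insignificant_lags`` the variant screen prunes individually
    insignificant factor lags before the joint test.  Observations after
    ``train_end`` are never used for selection; when ``eval_end`` is given
    the fitted full model is additionally checked out-of-split and its
    evaluation RMSE reported.

    Returns a frame with columns feature, d, stationary, p, q, F, pvalue,
    decision, reason, n_train, eval_rmse.
    """
    train_end = pd.Period(train_end, freq="M")
    if eval_end is not None:
        eval_end = pd.Period(eval_end, freq="M")
    news_d = news[news["level"] == "district"] if "level" in news else news
    ipc = ipc.copy()
    ipc["period"] = pd.PeriodIndex([pd.Period(p, freq="M") for p in ipc["period"]], freq="M")
    train_periods = pd.PeriodIndex(
        sorted({p for p in ipc["period"] if p <= train_end}), freq="M"
    )
    eval_periods = (
        pd.PeriodIndex(
            sorted({p for p in ipc["period"] if train_end < p <= eval_end}), freq="M"
        )
        if eval_end is not None
        else None
    )
    all_months = pd.PeriodIndex(
        sorted({pd.Period(m, freq="M") for m in news_d["month"].unique()}), freq="M"
    )
    train_months = pd.PeriodIndex([m for m in all_months if m <= train_end], freq="M")

    by_feature = {feat: sub for feat, sub in news_d.groupby("feature", observed=True)}
    rows = []
    for feat in features:
        sub = by_feature.get(feat, news_d.iloc[0:0])
        result = dict(
            feature=feat, d=0, stationary=False, p=np.nan, q=np.nan,
            F=np.nan, pvalue=np.nan, decision="discarded", reason="", n_train=0,
            eval_rmse=np.nan,
        )
        if sub.empty:
            result["reason"] = "no_data"
            rows.append(result)
            continue
        key = "unit_id" if "unit_id" in sub else "district_id"
        x_wide = sub.pivot_table(index=key, columns="month", values="value")
        x_wide.columns = pd.PeriodIndex(
            [pd.Period(m, freq="M") for m in x_wide.columns], freq="M"
        )
        train_vals = x_wide[[m for m in train_months if m in x_wide.columns]].to_numpy()
        if np.ptp(train_vals[np.isfinite(train_vals)]) == 0:
            result["reason"] = "degenerate"
            rows.append(result)
            continue
        try:
            d, stationary = _feature_difference_order(
                x_wide, train_months, adf_level, max_diff, adf_maxlag, adf_district_sample
            )
        except SeriesTooShortError:
            result["reason"] = "too_short"
            rows.append(result)
            continue
        result["d"], result["stationary"] = d, stationary
        x_long = sub.rename(columns={key: "district_id"})[["district_id", "month", "value"]].copy()
        x_long["month"] = pd.PeriodIndex(
            [pd.Period(m, freq="M") for m in x_long["month"]], freq="M"
        )
        x_used = difference_panel(x_long, d)
        try:
            p_max, q_max = max(p_range), max(q_range)
            target, ylags, xlags, _, _ = _stack_panel(ipc, x_used, p_max, q_max, train_periods)
            if np.ptp(xlags) == 0:
                result["reason"] = "degenerate"
                rows.append(result)
                continue
            # AIC order selection on the common training sample
            best_pq, best_aic = None, np.inf
            n = len(target)
            for p, q in itertools.product(sorted(p_range), sorted(q_range)):
                X = np.column_stack([np.ones(n), ylags[:, :p], xlags[:, :q]])
                _, rss = _ols(X, target)
                aic = _aic(rss, n, p + q)
                if aic < best_aic:
                    best_pq, best_aic = (p, q), aic
            p, q = best_pq
            if drop_insignificant_lags:
                f_stat, pval, _ = pruned_f_test(target, ylags, xlags, p, q)
            else:
                f_stat, pval, _, _ = nested_f_test(target, ylags, xlags, p, q)
        except (np.linalg.LinAlgError, ValueError) as exc:
            result["reason"] = f"fit_failure: {exc}"
            rows.append(result)
            continue
        result.update(p=p, q=q, F=f_stat, pvalue=pval, n_train=n)
        result["decision"] = "retained" if pval < level else "discarded"
        result["reason"] = "" if pval < level else "f_test"
        if eval_periods is not None and len(eval_periods):
            try:
                t_e, yl_e, xl_e, _, _ = _stack_panel(ipc, x_used, p, q, eval_periods)
                X = np.column_stack([np.ones(n), ylags[:, :p], xlags[:, :q]])
                coef, _ = _ols(X, target)
                X_e = np.column_stack([np.ones(len(t_e)), yl_e[:, :p], xl_e[:, :q]])
                result["eval_rmse"] = float(np.sqrt(np.mean((t_e - X_e @ coef) ** 2)))
            except (np.linalg.LinAlgError, ValueError):
                pass
        rows.append(result)
    return pd.DataFrame(rows)


def screening_boundary(calendar: Calendar, n_train_periods: int = 6) -> pd.Period:
    """Default screening cutoff: the end of the n-th reporting period."""
    return calendar.reporting_periods[min(n_train_periods, len(calendar.reporting_periods)) - 1]
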