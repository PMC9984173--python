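"""Outbreak labelling, dual-threshold classification and forecast comparison.

A *food-crisis outbreak* starts at the reporting period where the phase
reaches 3 or more for at least two consecutive periods while the previous
period's phase was at most 2.  Phase forecasts become outbreak
classifiers through a lower threshold ``l`` and an upper threshold ``u``:
an outbreak is predicted at period t iff the predicted phase is at least
``u`` at t and at the next period, and at most ``l`` at the previous
period ("previous/next period" is the adjacent reporting period, which
keeps the rule valid across the reporting-schedule change).

Sweeping (l, u) traces precision-recall operating points whose
non-dominated subset is the Pareto front; we report its AUC and the best
recall at a fixed precision.  Forecast accuracy comparisons use the
Diebold-Mariano test on squared-error loss differentials with a
truncated-autocovariance (serial-correlation-robust) variance, and the
same correction yields a confidence interval for a single model's RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class NoOutbreaksError(ValueError):
    """Recall is undefined: the evaluation window contains no labeled outbreaks."""


class EmptyCurveError(ValueError):
    """No threshold pair predicts a single positive."""


# ---------------------------------------------------------------------------
# labelling and classification
# ---------------------------------------------------------------------------


def label_outbreaks(ipc: pd.DataFrame) -> pd.DataFrame:
    """Label outbreak onsets in an observed phase panel.

    Onset at period t iff phase >= 3 at t and at t+1 and phase <= 2 at
    t-1; the first and last periods of a district's series can never be
    onsets.  Each onset opens an episode lasting while the phase stays
    >= 3; the onset row records the episode duration and a severity flag
    (episode phase reaches 4 or 5).

    Returns the input panel with added columns onset, severe, duration
    and ``evaluable`` (both neighbors exist).
    """
    out = []
    for d, grp in ipc.groupby("district_id", observed=True, sort=True):
        grp = grp.sort_values("period").reset_index(drop=True)
        ph = grp["phase"].to_numpy()
        n = len(ph)
        onset = np.zeros(n, dtype=bool)
        severe = np.zeros(n, dtype=bool)
        duration = np.zeros(n, dtype=int)
        evaluable = np.zeros(n, dtype=bool)
        evaluable[1 : n - 1] = True
        for i in range(1, n - 1):
            if ph[i] >= 3 and ph[i + 1] >= 3 and ph[i - 1] <= 2:
                onset[i] = True
                j = i
                while j < n and ph[j] >= 3:
                    j += 1
                duration[i] = j - i
                severe[i] = bool(np.any(ph[i:j] >= 4))
        grp["onset"], grp["severe"] = onset, severe
        grp["duration"], grp["evaluable"] = duration, evaluable
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def _neighbor_arrays(pred: pd.DataFrame) -> pd.DataFrame:
    """Per row: previous/next-period prediction within the district series."""
    out = []
    for d, grp in pred.groupby("district_id", observed=True, sort=True):
        grp = grp.sort_values("period").reset_index(drop=True)
        grp["yhat_prev"] = grp["yhat"].shift(1)
        grp["yhat_next"] = grp["yhat"].shift(-1)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def classify_outbreaks(
    pred: pd.DataFrame,
    lower: float,
    upper: float,
    observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Predict outbreak onsets from a phase-forecast panel.

    ``pred`` needs columns district_id, period, yhat.  Periods missing a
    neighboring prediction are marked unevaluable (never predicted).
    The prior-period condition uses the predicted phase, exactly as the
    classifier formula reads; pass an ``observed`` phase panel
    (district_id, period, phase) to use the observed prior instead.
    """
    if lower > upper:
        raise ValueError("need lower <= upper")
    df = _neighbor_arrays(pred)
    if observed is not None:
        obs = observed.rename(columns={"phase": "yhat"})[["district_id", "period", "yhat"]]
        prev = _neighbor_arrays(obs)[["district_id", "period", "yhat_prev"]]
        df = df.drop(columns="yhat_prev").merge(prev, on=["district_id", "period"], how="left")
    ok = df["yhat_prev"].notna() & df["yhat_next"].notna()
    df["pred_evaluable"] = ok
    df["pred_onset"] = (
        ok
        & (df["yhat"] >= upper)
        & (df["yhat_next"] >= upper)
        & (df["yhat_prev"] <= lower)
    )
    return df


# ---------------------------------------------------------------------------
# precision-recall sweep
# ---------------------------------------------------------------------------


@dataclass
class PRCurve:
    """Threshold-sweep result: all operating points, the front, and its AUC."""

    points: pd.DataFrame  # l, u, precision, recall
    front: pd.DataFrame  # the non-dominated subset, sorted by recall
    auc: float
    n_outbreaks: int
    step: float = field(default=np.nan)


def _pareto_front(points: pd.DataFrame) -> pd.DataFrame:
    """Non-dominated subset over (precision, recall), both maximized."""
    uniq = points.drop_duplicates(subset=["precision", "recall"])
    uniq = uniq.sort_values(["recall", "precision"], ascending=[False, False])
    keep, best_prec = [], -np.inf
    for row in uniq.itertuples():
        if row.precision > best_prec:
            keep.append(row.Index)
            best_prec = row.precision
    front = points.loc[keep].sort_values("recall").reset_index(drop=True)
    return front


def front_auc(front: pd.DataFrame) -> float:
    """Trapezoidal area under the front's monotone interpolation over recall.

    The front is anchored at (recall 0, precision of its lowest-recall
    point); recall beyond the front's maximum is unattainable and
    contributes no area.
    """
    if front.empty:
        return float("nan")
    rec = np.concatenate([[0.0], front["recall"].to_numpy()])
    prec = np.concatenate([[front["precision"].iloc[0]], front["precision"].to_numpy()])
    return float(np.trapezoid(prec, rec))


def pr_sweep(
    pred: pd.DataFrame,
    labels: pd.DataFrame,
    step: float = 0.01,
    lo: float = 1.0,
    hi: float = 5.0,
) -> PRCurve:
    """Sweep (l, u) thresholds and trace the precision-recall front.

    Thresholds vary over [lo, hi] in increments of ``step`` with l <= u;
    the upper threshold starts one step above the scale floor (a
    predicted phase at the floor is no outbreak signal).  Grid points
    predicting zero positives are skipped; if all are, the curve is
    empty (:class:`EmptyCurveError`).  Evaluation pools every (district,
    period) where both the label and the prediction rule are defined.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    df = _neighbor_arrays(pred)
    lab = labels[["district_id", "period", "onset", "evaluable"]]
    df = df.merge(lab, on=["district_id", "period"], how="inner")
    df = df[df["evaluable"] & df["yhat_prev"].notna() & df["yhat_next"].notna()]
    onset = df["onset"].to_numpy(dtype=bool)
    n_outbreaks = int(onset.sum())
    if n_outbreaks == 0:
        raise NoOutbreaksError("no labeled outbreaks in the evaluation window")
    cur = df["yhat"].to_numpy(dtype=float)
    nxt = df["yhat_next"].to_numpy(dtype=float)
    prv = df["yhat_prev"].to_numpy(dtype=float)

    n_steps = int(round((hi - lo) / step))
    ls = lo + step * np.arange(n_steps + 1)
    us = ls[1:]  # u > scale floor
    rows = []
    for u in us:
        pos = (cur >= u) & (nxt >= u)
        if not pos.any():
            continue
        prv_pos = prv[pos]
        onset_pos = onset[pos]
        order = np.argsort(prv_pos, kind="stable")
        prv_sorted = prv_pos[order]
        tp_cum = np.concatenate([[0], np.cumsum(onset_pos[order])])
        valid_l = ls[ls <= u + 1e-12]
        counts = np.searchsorted(prv_sorted, valid_l, side="right")
        for l_val, c in zip(valid_l, counts):
            if c == 0:
                continue
            tp = tp_cum[c]
            rows.append((l_val, u, tp / c, tp / n_outbreaks))
    if not rows:
        raise EmptyCurveError("no threshold pair predicts any positive")
    points = pd.DataFrame(rows, columns=["l", "u", "precision", "recall"])
    front = _pareto_front(points)
    return PRCurve(
        points=points, front=front, auc=front_auc(front), n_outbreaks=n_outbreaks, step=step
    )


def recall_at_precision(curve: PRCurve, target: float) -> dict:
    """Best recall among front points with precision >= target.

    Returns a dict with keys recall, precision, l, u and ``attainable``;
    when no front point reaches the target precision the result is
    flagged unattainable with NaN recall.
    """
    if curve.front.empty:
        raise ValueError("empty curve")
    ok = curve.front[curve.front["precision"] >= target]
    if ok.empty:
        return {"attainable": False, "recall": float("nan"), "precision": float("nan"),
                "l": float("nan"), "u": float("nan")}
    best = ok.loc[ok["recall"].idxmax()]
    return {
        "attainable": True,
        "recall": float(best["recall"]),
        "precision": float(best["precision"]),
        "l": float(best["l"]),
        "u": float(best["u"]),
    }


# ---------------------------------------------------------------------------
# Diebold-Mariano machinery
# ---------------------------------------------------------------------------


def _autocovariances(x: np.ndarray, n_lags: int) -> np.ndarray:
    """gamma_k = (1/n) sum_{i=k+1..n} (x_i - mean)(x_{i-k} - mean), k = 0..n_lags."""
    n = len(x)
    xc = x - x.mean()
    return np.array(
        [float(xc[k:] @ xc[: n - k]) / n for k in range(min(n_lags, n - 1) + 1)]
    )


def _truncation_lag(n: int) -> int:
    return int(np.floor(n ** (1.0 / 3.0))) + 1


@dataclass
class DMResult:
    """Diebold-Mariano comparison of two paired error sequences."""

    statistic: float
    pvalue: float
    n: int
    mean_diff: float
    small_sample: bool = False


@dataclass
class RMSECIResult:
    """Serial-correlation-corrected confidence interval for one model's RMSE."""

    mse: float
    rmse: float
    gamma: np.ndarray
    sigma: float
    ci_mse: tuple[float, float]
    ci_rmse: tuple[float, float]
    n: int
    clamped: bool = False


def dm_test(errors_a, errors_b) -> DMResult:
    """Diebold-Mariano test on the squared-error loss differential.

    Errors must be paired by observation and pooled across test periods
    in temporal order.  The differential's long-run variance uses the
    truncated autocovariance sum with lag floor(n^(1/3)) + 1; the
    two-sided p-value comes from the normal reference distribution.
    Positive statistic: model a has larger squared errors (b wins).
    """
    ea = np.asarray(errors_a, dtype=float)
    eb = np.asarray(errors_b, dtype=float)
    if ea.shape != eb.shape or ea.ndim != 1:
        raise ValueError("error sequences must be 1-d and of equal length")
    n = len(ea)
    d = ea**2 - eb**2
    mean_d = float(d.mean())
    gamma = _autocovariances(d, _truncation_lag(n))
    var_mean = (gamma[0] + 2.0 * gamma[1:].sum()) / n
    if var_mean <= 0:
        statistic = 0.0 if mean_d == 0 else float(np.sign(mean_d)) * np.inf
    else:
        statistic = mean_d / float(np.sqrt(var_mean))
    pvalue = float(2.0 * stats.norm.sf(abs(statistic))) if np.isfinite(statistic) else 0.0
    if mean_d == 0:
        statistic, pvalue = 0.0, 1.0
    return DMResult(
        statistic=float(statistic), pvalue=pvalue, n=n, mean_diff=mean_d,
        small_sample=n < 10,
    )


def rmse_ci(errors) -> RMSECIResult:
    """95% CI for the RMSE, corrected for serial correlation.

    With m the mean squared error, gamma_k the autocovariances of the
    squared errors and K = floor(n^(1/3)) + 1, the standard error of m is
    sqrt([gamma_0 + 2 sum_{k=1..K} gamma_k] / n); the CI is m +- 1.96 se
    on the squared scale and its (clamped) square root on the RMSE scale.
    A negative truncated variance estimate is clamped at zero and flagged.
    """
    e = np.asarray(errors, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValueError("need at least 2 errors")
    n = len(e)
    sq = e**2
    m = float(sq.mean())
    gamma = _autocovariances(sq, _truncation_lag(n))
    var_mean = (gamma[0] + 2.0 * gamma[1:].sum()) / n
    clamped = var_mean < 0
    sigma = float(np.sqrt(max(var_mean, 0.0)))
    lo, hi = m - 1.96 * sigma, m + 1.96 * sigma
    return RMSECIResult(
        mse=m,
        rmse=float(np.sqrt(m)),
        gamma=gamma,
        sigma=sigma,
        ci_mse=(lo, hi),
        ci_rmse=(float(np.sqrt(max(lo, 0.0))), float(np.sqrt(max(hi, 0.0)))),
        n=n,
        clamped=clamped,
    )


def percent_change(base: float, new: float) -> float:
    """Percent improvement from ``base`` to ``new``: 100 (base - new) / base.

    Positive values are improvements (error reduced); rounding to integers
    happens only at the reporting layer.
    """
    if base <= 0:
        raise ValueError("base must be positive")
    return 100.0 * (base - new) / base
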