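"""Outbreak labels, dual-threshold classification, PR sweeps, DM machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crisiscast.crisis_eval import (
    DMResult,
    EmptyCurveError,
    NoOutbreaksError,
    PRCurve,
    classify_outbreaks,
    dm_test,
    front_auc,
    label_outbreaks,
    percent_change,
    pr_sweep,
    recall_at_precision,
    rmse_ci,
)

PERIODS = pd.period_range("2010-01", periods=12, freq="3M").asfreq("M")


def _ipc(phases_by_district):
    rows = []
    for d, phases in phases_by_district.items():
        for p, ph in zip(PERIODS, phases):
            rows.append({"district_id": d, "period": p, "phase": ph})
    return pd.DataFrame(rows)


def _pred(yhat_by_district):
    rows = []
    for d, vals in yhat_by_district.items():
        for p, v in zip(PERIODS, vals):
            rows.append({"district_id": d, "period": p, "yhat": float(v)})
    return pd.DataFrame(rows)


class TestLabelOutbreaks:
    def test_two_consecutive_high_phases_after_calm_is_onset(self):
        lab = label_outbreaks(_ipc({"d": [2, 2, 3, 3, 2]}))
        assert list(lab["onset"][:5]) == [False, False, True, False, False]

    def test_alternating_phases_never_onset(self):
        lab = label_outbreaks(_ipc({"d": [2, 3, 2, 3, 2]}))
        assert not lab["onset"].any()

    def test_phase_four_episode_is_severe_with_duration(self):
        lab = label_outbreaks(_ipc({"d": [2, 3, 4, 3, 1]}))
        onset_rows = lab[lab["onset"]]
        assert len(onset_rows) == 1
        row = onset_rows.iloc[0]
        assert row["period"] == PERIODS[1]
        assert row["severe"]
        assert row["duration"] == 3

    def test_series_boundaries_are_never_onsets(self):
        lab = label_outbreaks(_ipc({"d": [3, 3, 1, 2, 3]}))
        assert not lab["onset"].any()
        assert not lab["evaluable"].iloc[0]


class TestClassifyOutbreaks:
    def test_perfect_predictions_with_canonical_thresholds_reproduce_labels(self):
        rng = np.random.default_rng(0)
        phases = {f"d{i}": rng.integers(1, 6, size=len(PERIODS)) for i in range(10)}
        ipc = _ipc({d: list(v) for d, v in phases.items()})
        labels = label_outbreaks(ipc)
        pred = classify_outbreaks(
            _pred({d: list(map(float, v)) for d, v in phases.items()}), 2.0, 3.0
        )
        merged = labels.merge(pred, on=["district_id", "period"])
        inner = merged[merged["evaluable"]]
        np.testing.assert_array_equal(inner["onset"].to_numpy(),
                                      inner["pred_onset"].to_numpy())

    def test_upper_threshold_above_scale_gives_empty_prediction(self):
        pred = classify_outbreaks(_pred({"d": [2, 5, 5, 5, 2]}), 2.0, 5.01)
        assert not pred["pred_onset"].any()

    def test_matches_per_period_brute_force(self):
        rng = np.random.default_rng(4)
        yhat = {f"d{i}": rng.uniform(1, 5, size=len(PERIODS)) for i in range(5)}
        for l, u in [(1.5, 2.5), (2.0, 3.0), (2.5, 4.0)]:
            got = classify_outbreaks(_pred(yhat), l, u)
            for d, vals in yhat.items():
                for i in range(len(PERIODS)):
                    expect = (
                        0 < i < len(PERIODS) - 1
                        and vals[i] >= u and vals[i + 1] >= u and vals[i - 1] <= l
                    )
                    row = got[(got["district_id"] == d) & (got["period"] == PERIODS[i])]
                    assert bool(row["pred_onset"].item()) == expect

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_outbreaks(_pred({"d": [1, 2, 3]}), 3.0, 2.0)

    def test_observed_prior_variant_uses_true_phase_history(self):
        """With the flag, the t-1 condition reads the observed phase, so a
        forecast that never dips below l can still signal onsets."""
        yhat = {"d": [4.0, 4.0, 4.0, 4.0, 4.0]}
        observed = _ipc({"d": [2, 2, 3, 3, 3]})
        default = classify_outbreaks(_pred(yhat), 2.0, 3.0)
        assert not default["pred_onset"].any()
        flagged = classify_outbreaks(_pred(yhat), 2.0, 3.0, observed=observed)
        assert flagged.loc[flagged["period"] == PERIODS[2], "pred_onset"].item()


def brute_force_sweep(pred, labels, step, lo=1.0, hi=5.0):
    """Naive per-(l, u) confusion-matrix enumeration (test oracle)."""
    from crisiscast.crisis_eval import _neighbor_arrays

    df = _neighbor_arrays(pred).merge(
        labels[["district_id", "period", "onset", "evaluable"]],
        on=["district_id", "period"],
    )
    df = df[df["evaluable"] & df["yhat_prev"].notna() & df["yhat_next"].notna()]
    n_pos = int(df["onset"].sum())
    grid = [round(lo + i * step, 9) for i in range(int(round((hi - lo) / step)) + 1)]
    points = set()
    for u in grid[1:]:
        for l in grid:
            if l > u:
                continue
            pred_mask = (df["yhat"] >= u) & (df["yhat_next"] >= u) & (df["yhat_prev"] <= l)
            tp = int((pred_mask & df["onset"]).sum())
            npred = int(pred_mask.sum())
            if npred == 0:
                continue
            points.add((round(tp / npred, 12), round(tp / n_pos, 12)))
    return points


class TestPRSweep:
    def test_perfect_predictor_reaches_the_corner(self):
        phases = {"a": [2, 2, 3, 3, 2, 2, 3, 3, 1, 1, 1, 1], "b": [1] * 12}
        ipc = _ipc(phases)
        labels = label_outbreaks(ipc)
        pred = _pred({d: list(map(float, v)) for d, v in phases.items()})
        curve = pr_sweep(pred, labels, step=0.25)
        assert ((curve.front["precision"] == 1) & (curve.front["recall"] == 1)).any()
        assert curve.auc == pytest.approx(1.0)

    def test_floor_constant_predictor_signals_empty_curve(self):
        phases = {"a": [2, 2, 3, 3, 2, 1, 1, 1, 1, 1, 1, 1]}
        labels = label_outbreaks(_ipc(phases))
        with pytest.raises(EmptyCurveError):
            pr_sweep(_pred({"a": [1.0] * 12}), labels, step=0.25)

    def test_no_labeled_outbreaks_signals_undefined_recall(self):
        labels = label_outbreaks(_ipc({"a": [1] * 12}))
        with pytest.raises(NoOutbreaksError):
            pr_sweep(_pred({"a": [3.0] * 12}), labels, step=0.5)

    def test_operating_points_match_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        phases = {f"d{i}": rng.integers(1, 6, size=len(PERIODS)) for i in range(5)}
        ipc = _ipc({d: list(v) for d, v in phases.items()})
        labels = label_outbreaks(ipc)
        yhat = {d: np.clip(v + rng.normal(0, 0.7, len(v)), 1, 5) for d, v in phases.items()}
        pred = _pred(yhat)
        curve = pr_sweep(pred, labels, step=0.25)
        got = {
            (round(p, 12), round(r, 12))
            for p, r in curve.points[["precision", "recall"]].itertuples(index=False)
        }
        assert got == brute_force_sweep(pred, labels, 0.25)

    def test_front_is_non_dominated(self):
        rng = np.random.default_rng(2)
        phases = {f"d{i}": rng.integers(1, 6, size=len(PERIODS)) for i in range(6)}
        ipc = _ipc({d: list(v) for d, v in phases.items()})
        labels = label_outbreaks(ipc)
        yhat = {d: np.clip(v + rng.normal(0, 1, len(v)), 1, 5) for d, v in phases.items()}
        curve = pr_sweep(_pred(yhat), labels, step=0.2)
        f = curve.front
        for i in range(len(f)):
            for j in range(len(f)):
                if i == j:
                    continue
                dominates = (
                    f["precision"].iloc[j] >= f["precision"].iloc[i]
                    and f["recall"].iloc[j] >= f["recall"].iloc[i]
                    and (
                        f["precision"].iloc[j] > f["precision"].iloc[i]
                        or f["recall"].iloc[j] > f["recall"].iloc[i]
                    )
                )
                assert not dominates

    def test_auc_stable_once_step_resolves_all_confusion_matrices(self):
        """Predictions on a coarse lattice: halving the step changes nothing."""
        rng = np.random.default_rng(9)
        phases = {f"d{i}": rng.integers(1, 6, size=len(PERIODS)) for i in range(5)}
        ipc = _ipc({d: list(v) for d, v in phases.items()})
        labels = label_outbreaks(ipc)
        yhat = {d: np.round(np.clip(v + rng.normal(0, 0.6, len(v)), 1, 5) * 2) / 2
                for d, v in phases.items()}
        c1 = pr_sweep(_pred(yhat), labels, step=0.25)
        c2 = pr_sweep(_pred(yhat), labels, step=0.125)
        assert c1.auc == pytest.approx(c2.auc, abs=1e-12)


class TestRecallAtPrecision:
    @staticmethod
    def _curve():
        front = pd.DataFrame(
            {"l": [2.0, 2.2, 2.4], "u": [3.0, 3.2, 3.4],
             "precision": [0.7, 0.8, 0.9], "recall": [0.8, 0.6, 0.4]}
        ).sort_values("recall")
        return PRCurve(points=front, front=front.reset_index(drop=True),
                       auc=front_auc(front), n_outbreaks=10)

    def test_selects_best_recall_meeting_target(self):
        out = recall_at_precision(self._curve(), 0.8)
        assert out["attainable"] and out["recall"] == pytest.approx(0.6)

    def test_zero_target_returns_max_recall(self):
        out = recall_at_precision(self._curve(), 0.0)
        assert out["recall"] == pytest.approx(0.8)

    def test_unreachable_target_flagged(self):
        out = recall_at_precision(self._curve(), 0.95)
        assert not out["attainable"] and np.isnan(out["recall"])


def oracle_dm(ea, eb):
    """Independent transcription of the DM formulas (direct summation)."""
    d = np.asarray(ea) ** 2 - np.asarray(eb) ** 2
    n = len(d)
    m = d.mean()
    K = int(np.floor(n ** (1 / 3))) + 1
    gamma = []
    for k in range(K + 1):
        acc = 0.0
        for i in range(k, n):
            acc += (d[i] - m) * (d[i - k] - m)
        gamma.append(acc / n)
    var = (gamma[0] + 2 * sum(gamma[1:])) / n
    stat = m / np.sqrt(var)
    return stat, 2 * stats.norm.sf(abs(stat))


class TestDieboldMariano:
    def test_identical_errors_give_zero_statistic_unit_pvalue(self):
        e = np.array([0.5, -1.0, 0.2, 0.8])
        res = dm_test(e, e.copy())
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_direct_formula_transcription(self):
        rng = np.random.default_rng(13)
        ea = rng.normal(0, 1.0, 50)
        eb = rng.normal(0, 1.3, 50)
        res = dm_test(ea, eb)
        stat, pval = oracle_dm(ea, eb)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.pvalue == pytest.approx(pval, rel=1e-10)

    def test_swapping_sequences_negates_statistic(self):
        rng = np.random.default_rng(3)
        ea, eb = rng.normal(0, 1, 60), rng.normal(0, 2, 60)
        assert dm_test(ea, eb).statistic == pytest.approx(-dm_test(eb, ea).statistic)

    def test_small_sample_flagged(self):
        res = dm_test([1.0, 2.0, 0.5], [0.5, 1.0, 2.0])
        assert isinstance(res, DMResult) and res.small_sample

    def test_type_one_error_near_nominal_on_equal_accuracy_forecasts(self):
        """Rejection rate at nominal 5% stays within [0.02, 0.09] for
        i.i.d. equal-accuracy errors (n=200, 1000 replicates)."""
        rng = np.random.default_rng(6)
        rejections = 0
        for _ in range(1000):
            ea = rng.normal(0, 1, 200)
            eb = rng.normal(0, 1, 200)
            rejections += dm_test(ea, eb).pvalue < 0.05
        assert 0.02 <= rejections / 1000 <= 0.09


class TestRMSECI:
    def test_equal_errors_give_zero_width_interval(self):
        res = rmse_ci([0.7] * 10)
        assert res.sigma == 0.0
        assert res.ci_mse[0] == pytest.approx(0.49)
        assert res.ci_mse[1] == pytest.approx(0.49)
        np.testing.assert_allclose(res.gamma, 0.0, atol=1e-15)

    def test_alternating_signs_have_constant_squares(self):
        res = rmse_ci([1.0, -1.0, 1.0, -1.0])
        assert res.rmse == 1.0
        assert res.ci_rmse == (1.0, 1.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        e = rng.normal(0, 1, 40)
        res = rmse_ci(e)
        sq = e**2
        m = sq.mean()
        n = len(e)
        g1 = sum((sq[i] - m) * (sq[i - 1] - m) for i in range(1, n)) / n
        assert res.gamma[1] == pytest.approx(g1, rel=1e-12)
        K = int(np.floor(n ** (1 / 3))) + 1
        gam = [sum((sq[i] - m) * (sq[i - k] - m) for i in range(k, n)) / n
               for k in range(K + 1)]
        sigma = np.sqrt((gam[0] + 2 * sum(gam[1:])) / n)
        assert res.ci_mse[0] == pytest.approx(m - 1.96 * sigma, rel=1e-12)
        assert res.ci_mse[1] == pytest.approx(m + 1.96 * sigma, rel=1e-12)
        assert res.ci_rmse[0] <= res.rmse <= res.ci_rmse[1]


class TestPercentChange:
    def test_matches_reported_error_reduction(self):
        assert percent_change(0.1486, 0.0819) == pytest.approx(44.9, abs=0.05)
        assert round(percent_change(0.1486, 0.0819)) == 45

    def test_no_change_is_zero(self):
        assert percent_change(0.3, 0.3) == 0.0

    def test_deterioration_is_negative(self):
        assert percent_change(0.0819, 0.1137) == pytest.approx(-38.8, abs=0.05)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 0.1)
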