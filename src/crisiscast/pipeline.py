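"""End-to-end orchestration: synthetic world -> lexicon -> screening -> forecasts.

Mirrors the full study design on generated data.  Feature selection
(frame filter, keyword expansion, Granger screen) uses only the training
and validation periods of the first cross-validation fold, which precede
every test window — so no observation used to select news indicators
contributes to evaluating forecast performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from crisiscast import crisis_eval, factors, forecast, granger, lexicon
from crisiscast.synthdata import Scenario, ScenarioConfig, generate_scenario


@dataclass
class PipelineResult:
    scenario: Scenario
    features: pd.DataFrame
    screen: pd.DataFrame
    retained: list[str]
    news_panel: pd.DataFrame
    results: dict[str, forecast.ForecastResult]
    evaluation: dict


def select_features(
    scenario: Scenario,
    train_end: pd.Period,
    dist_max: float = 2.0,
    min_count: int = 20,
    level: float = 0.01,
    p_range: tuple[int, ...] = (1, 2, 3, 4),
    q_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    adf_district_sample: int | None = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Lexicon construction plus Granger screening before ``train_end``.

    Returns (features, screen, news_panel) where ``news_panel`` holds the
    complete multi-level panel for every corpus-present candidate and
    ``screen`` records one decision per candidate.
    """
    cfg = scenario.config
    feats = lexicon.build_lexicon(
        scenario.frames,
        scenario.articles,
        scenario.embeddings,
        seeds=cfg.seed_phrases,
        causal_links=cfg.causal_links,
        dist_max=dist_max,
        min_count=min_count,
    )
    counts = lexicon.corpus_ngram_counts(scenario.articles)
    present = [f for f in feats["ngram"] if counts.get(f, 0) > 0]
    absent = [f for f in feats["ngram"] if counts.get(f, 0) == 0]
    news_panel = factors.build_news_factors(
        scenario.articles, present, scenario.world, months=[str(m) for m in scenario.calendar.months]
    )
    screen = granger.granger_screen(
        present,
        scenario.ipc,
        news_panel,
        train_end=train_end,
        level=level,
        p_range=p_range,
        q_range=q_range,
        adf_district_sample=adf_district_sample,
    )
    if absent:
        screen = pd.concat(
            [
                screen,
                pd.DataFrame(
                    {
                        "feature": absent,
                        "d": 0,
                        "stationary": False,
                        "p": np.nan,
                        "q": np.nan,
                        "F": np.nan,
                        "pvalue": np.nan,
                        "decision": "discarded",
                        "reason": "not_in_corpus",
                        "n_train": 0,
                        "eval_rmse": np.nan,
                    }
                ),
            ],
            ignore_index=True,
        )
    status = screen.set_index("feature")["decision"].to_dict()
    feats = feats.copy()
    feats["status"] = feats["ngram"].map(lambda g: status.get(g, "discarded"))
    return feats, screen, news_panel


def differenced_news(news_panel: pd.DataFrame, screen: pd.DataFrame, retained: list[str]) -> pd.DataFrame:
    """Retained news factors, each at its screened difference order."""
    orders = screen.set_index("feature")["d"].to_dict()
    parts = []
    for feat in retained:
        sub = news_panel[news_panel["feature"] == feat].copy()
        d = int(orders.get(feat, 0))
        if d > 0:
            sub = sub.copy()
            sub["month"] = pd.PeriodIndex(sub["month"], freq="M")
            pieces = []
            for (_, _), grp in sub.groupby(["unit_id", "level"], observed=True):
                grp = grp.sort_values("month").copy()
                grp["value"] = grp["value"].diff(d)
                pieces.append(grp.iloc[d:])
            sub = pd.concat(pieces, ignore_index=True)
            sub["month"] = sub["month"].astype(str)
        parts.append(sub)
    return pd.concat(parts, ignore_index=True) if parts else news_panel.iloc[0:0]


def run_pipeline(
    config: ScenarioConfig,
    n_folds: int = 10,
    val_periods: int = 2,
    test_periods: int | None = None,
    burn_in_periods: int = 8,
    grid: dict | None = None,
    variants: tuple[str, ...] = ("traditional", "news", "combined"),
    dist_max: float = 2.0,
    min_count: int = 20,
    level: float = 0.01,
    sweep_step: float = 0.05,
    precision_target: float = 0.8,
    p_range: tuple[int, ...] = (1, 2, 3, 4),
    q_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    adf_district_sample: int | None = 8,
    seed: int | None = None,
) -> PipelineResult:
    """Run the whole study on one synthetic scenario.

    ``seed`` overrides the config seed (one integer drives generation and
    model fitting).  Designs of all variants are intersected so every
    model sees identical observations.
    """
    if seed is not None:
        config = ScenarioConfig(**{**config.__dict__, "seed": seed})
    scenario = generate_scenario(config)
    plan = forecast.make_folds(
        scenario.calendar,
        n_folds=n_folds,
        val_periods=val_periods,
        test_periods=test_periods,
        burn_in_periods=burn_in_periods,
    )
    train_end = plan.folds[0].validation[-1]
    feats, screen, news_panel = select_features(
        scenario,
        train_end,
        dist_max=dist_max,
        min_count=min_count,
        level=level,
        p_range=p_range,
        q_range=q_range,
        adf_district_sample=adf_district_sample,
    )
    retained = sorted(screen.loc[screen["decision"] == "retained", "feature"])
    news_used = differenced_news(news_panel, screen, retained)
    trad_all = factors.aggregate_factor_panel(scenario.factors, scenario.world)

    designs: dict[str, forecast.DesignMatrix] = {}
    for variant in variants:
        designs[variant] = forecast.build_design(
            scenario.ipc,
            trad_all,
            scenario.static,
            news_used if variant != "traditional" else None,
            scenario.world,
            variant=variant,
        )
    common = None
    for dm in designs.values():
        common = dm.X.index if common is None else common.intersection(dm.X.index)
    for variant, dm in designs.items():
        designs[variant] = forecast.DesignMatrix(
            X=dm.X.loc[common], y=dm.y.loc[common], variant=dm.variant,
            horizon=dm.horizon, n_dropped=dm.n_dropped, column_groups=dm.column_groups,
        )

    results = {
        v: forecast.fit_predict(designs[v], plan, grid=grid, seed=config.seed)
        for v in variants
    }
    evaluation = evaluate_models(
        results, scenario.ipc, sweep_step=sweep_step, precision_target=precision_target
    )
    return PipelineResult(
        scenario=scenario,
        features=feats,
        screen=screen,
        retained=retained,
        news_panel=news_panel,
        results=results,
        evaluation=evaluation,
    )


def trial_config(seed: int) -> ScenarioConfig:
    """Desk-scale replicate scenario for model-comparison experiments.

    A reduced world (48 districts, 10 years) keeps one replicate around half
    a minute while preserving the planted structure: a 4-month news lead on
    the weather/pest components and traditional factors reported three months
    late through measurement noise.
    """
    return ScenarioConfig(
        n_countries=12,
        provinces_per_country=2,
        districts_per_province=2,
        n_months=120,
        article_rate=40,
        n_noise_features=10,
        seed=seed,
    )


def superiority_trial(
    seed: int,
    config: ScenarioConfig | None = None,
    n_folds: int = 8,
    sweep_step: float = 0.01,
    precision_target: float = 0.8,
) -> dict:
    """One traditional-vs-combined replicate: RMSE and recall at fixed precision.

    Recall is counted as 0 when the target precision is unattainable on a
    model's Pareto front.
    """
    cfg = config or trial_config(seed)
    res = run_pipeline(
        cfg,
        n_folds=n_folds,
        variants=("traditional", "combined"),
        sweep_step=sweep_step,
        precision_target=precision_target,
        adf_district_sample=6,
        seed=seed,
    )
    planted = set(cfg.planted_features)
    retained = set(res.retained)
    lexicon_ngrams = set(res.features["ngram"])
    out: dict = {
        "seed": seed,
        "n_retained": len(retained),
        "planted_recovery": len(planted & retained) / len(planted),
        "noise_retention": len(set(cfg.noise_features) & retained)
        / max(len(cfg.noise_features), 1),
        "noise_in_lexicon": len(set(cfg.noise_features) & lexicon_ngrams),
    }
    for name in ("traditional", "combined"):
        entry = res.evaluation["models"][name]
        rec = entry.get("recall_at_precision", {})
        out[f"rmse_{name}"] = entry["rmse_pooled"]
        out[f"recall_{name}"] = rec.get("recall", 0.0) if rec.get("attainable") else 0.0
        out[f"auc_{name}"] = entry.get("auc", float("nan"))
    out["combined_wins_rmse"] = out["rmse_combined"] < out["rmse_traditional"]
    out["combined_wins_recall"] = out["recall_combined"] > out["recall_traditional"]
    return out


def evaluate_models(
    results: dict[str, forecast.ForecastResult],
    ipc: pd.DataFrame,
    sweep_step: float = 0.05,
    precision_target: float = 0.8,
) -> dict:
    """RMSE, outbreak-classification and Diebold-Mariano comparison report."""
    labels = crisis_eval.label_outbreaks(ipc)
    out: dict = {"models": {}, "comparisons": {}}
    for name, res in results.items():
        entry: dict = {
            "rmse": res.rmse,
            "rmse_pooled": forecast.rmse(res.errors),
        }
        ci = crisis_eval.rmse_ci(res.errors)
        entry["rmse_ci"] = ci.ci_rmse
        try:
            curve = crisis_eval.pr_sweep(res.predictions, labels, step=sweep_step)
            entry["auc"] = curve.auc
            entry["n_outbreaks"] = curve.n_outbreaks
            rec = crisis_eval.recall_at_precision(curve, precision_target)
            entry["recall_at_precision"] = rec
            entry["n_predicted_outbreaks"] = (
                int(round(rec["recall"] * curve.n_outbreaks)) if rec["attainable"] else 0
            )
        except (crisis_eval.NoOutbreaksError, crisis_eval.EmptyCurveError) as exc:
            entry["auc"] = float("nan")
            entry["classification_error"] = str(exc)
        out["models"][name] = entry
    names = sorted(results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa = results[a].predictions.merge(
                results[b].predictions, on=["district_id", "period"], suffixes=("_a", "_b")
            ).sort_values(["period", "district_id"])
            dm = crisis_eval.dm_test(
                (pa["y_a"] - pa["yhat_a"]).to_numpy(),
                (pa["y_b"] - pa["yhat_b"]).to_numpy(),
            )
            out["comparisons"][f"{a}_vs_{b}"] = {
                "dm_statistic": dm.statistic,
                "dm_pvalue": dm.pvalue,
                "n": dm.n,
            }
    if "traditional" in out["models"]:
        base = out["models"]["traditional"]["rmse_pooled"]
        for name, entry in out["models"].items():
            if name != "traditional":
                entry["rmse_pct_change_vs_traditional"] = crisis_eval.percent_change(
                    base, entry["rmse_pooled"]
                )
    return out
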