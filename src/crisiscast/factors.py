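"""News-factor panels and their validation against traditional factors.

A *news factor* is, for a text feature ``w`` and geographic unit ``i``,
the monthly proportion of articles mentioning ``i`` that also mention
``w``.  A province or country is "mentioned" whenever one of its
districts (or the unit itself) is, so province/country series aggregate
the same counting rule over a larger article pool.  Zero-coverage months
yield a value of 0 with a coverage flag of 0, keeping lag matrices
complete downstream.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from crisiscast.world import GeoHierarchy


def _article_table(articles: Iterable[dict], world: GeoHierarchy) -> pd.DataFrame:
    """One row per (article index, unit) mention, with month and ngram set."""
    rows = []
    for idx, art in enumerate(articles):
        month = art["month"]
        units = set(art["district_ids"])
        for d in art["district_ids"]:
            p, c = world.ancestors(d)
            units.add(p)
            units.add(c)
        for u in units:
            rows.append((idx, u, month))
    return pd.DataFrame(rows, columns=["article", "unit_id", "month"])


def build_news_factors(
    articles: Sequence[dict],
    features: Sequence[str],
    world: GeoHierarchy,
    months: Sequence | None = None,
) -> pd.DataFrame:
    """Build the complete (feature, unit, month) news-factor panel.

    value = (# articles mentioning unit and feature in month) /
            (# articles mentioning unit in month), 0 when the denominator
    is zero (coverage flag 0).  Returns a long frame with columns
    ``feature, unit_id, level, month, value, coverage``; ``month`` is a
    string 'YYYY-MM'.  The panel is complete over every (feature, unit,
    month) combination.
    """
    features = list(dict.fromkeys(features))
    mentions = _article_table(articles, world)
    if months is None:
        months = sorted(mentions["month"].unique())
    months = [str(m) for m in months]
    level_of = dict((u, lv) for u, lv in world.units)
    all_units = [u for u, _ in world.units]

    coverage = (
        mentions.groupby(["unit_id", "month"])["article"].nunique()
        if len(mentions)
        else pd.Series(dtype=int)
    )
    ngram_sets = [set(a["ngrams"]) for a in articles]

    full_index = pd.MultiIndex.from_product([all_units, months], names=["unit_id", "month"])
    cov_full = coverage.reindex(full_index, fill_value=0) if len(mentions) else pd.Series(
        0, index=full_index
    )

    blocks = []
    for feat in features:
        has = np.fromiter((feat in s for s in ngram_sets), dtype=bool, count=len(ngram_sets))
        sub = mentions[has[mentions["article"].to_numpy()]] if len(mentions) else mentions
        joint = (
            sub.groupby(["unit_id", "month"])["article"].nunique().reindex(full_index, fill_value=0)
            if len(sub)
            else pd.Series(0, index=full_index)
        )
        value = np.where(cov_full.to_numpy() > 0, joint.to_numpy() / np.maximum(cov_full.to_numpy(), 1), 0.0)
        block = pd.DataFrame(
            {
                "feature": feat,
                "unit_id": full_index.get_level_values(0),
                "month": full_index.get_level_values(1),
                "value": value,
                "coverage": cov_full.to_numpy(),
            }
        )
        blocks.append(block)
    out = pd.concat(blocks, ignore_index=True)
    out["level"] = out["unit_id"].map(level_of)
    return out[["feature", "unit_id", "level", "month", "value", "coverage"]]


def percentile_rank(series: Sequence[float]) -> np.ndarray:
    """Hazen percentile ranks, ``(r - 0.5) / n * 100`` with average ranks for ties."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    return (rankdata(x, method="average") - 0.5) / x.size * 100.0


def cluster_coherence(
    features: Sequence[str],
    articles: Sequence[dict],
    partition: dict[str, str],
) -> pd.DataFrame:
    """Check that features correlate more within their cluster than across.

    Each feature becomes a per-article binary mention indicator; pairwise
    Pearson correlations are computed at the article level.  For every
    feature the report gives its mean correlation with same-cluster
    features, its maximum mean correlation with any other cluster, and a
    ``coherent`` flag (within > every other cluster).  Zero-variance
    features are excluded from correlations and flagged ``degenerate``.
    """
    features = list(dict.fromkeys(features))
    missing = [f for f in features if f not in partition]
    if missing:
        raise ValueError(f"features without a cluster label: {missing}")
    labels = {f: partition[f] for f in features}
    clusters = sorted(set(labels.values()))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    sizes = pd.Series(list(labels.values())).value_counts()
    if (sizes < 2).any():
        raise ValueError("every cluster needs at least 2 features")

    indicator = np.array(
        [[f in set(a["ngrams"]) for f in features] for a in articles], dtype=float
    )
    variances = indicator.var(axis=0)
    ok = variances > 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(indicator[:, ok], rowvar=False)
    ok_features = [f for f, keep in zip(features, ok) if keep]
    pos = {f: i for i, f in enumerate(ok_features)}

    rows = []
    for f in features:
        if f not in pos:
            rows.append((f, labels[f], np.nan, np.nan, False, True))
            continue
        i = pos[f]
        per_cluster: dict[str, list[float]] = {c: [] for c in clusters}
        for g in ok_features:
            if g == f:
                continue
            per_cluster[labels[g]].append(corr[i, pos[g]])
        own = labels[f]
        within = float(np.mean(per_cluster[own])) if per_cluster[own] else np.nan
        others = {
            c: float(np.mean(v)) for c, v in per_cluster.items() if c != own and v
        }
        max_other = max(others.values()) if others else np.nan
        coherent = bool(np.isfinite(within) and np.isfinite(max_other) and within > max_other)
        rows.append((f, own, within, max_other, coherent, False))
    return pd.DataFrame(
        rows,
        columns=["feature", "cluster", "within_corr", "max_other_corr", "coherent", "degenerate"],
    )


def match_traditional(
    news: pd.DataFrame,
    trad: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pair each traditional factor with its best rank-correlated news factor.

    For every traditional factor ``k`` the Spearman correlation with each
    news factor is computed on pooled (district, month) observations,
    pairwise-complete; the feature with the highest correlation wins, ties
    broken lexicographically.  Pairs with fewer than ``min_pairs`` complete
    observations are skipped.

    ``news`` needs columns (feature, unit_id, month, value) at district
    level; ``trad`` needs (unit_id, month, factor, value).
    """
    news_d = news[news["level"] == "district"] if "level" in news else news
    trad_d = trad[trad["level"] == "district"] if "level" in trad else trad
    news_wide = news_d.pivot_table(
        index=["unit_id", "month"], columns="feature", values="value"
    )
    trad_wide = trad_d.pivot_table(
        index=["unit_id", "month"], columns="factor", values="value"
    )
    trad_wide.index = pd.MultiIndex.from_arrays(
        [trad_wide.index.get_level_values(0), trad_wide.index.get_level_values(1).astype(str)]
    )
    news_wide.index = pd.MultiIndex.from_arrays(
        [news_wide.index.get_level_values(0), news_wide.index.get_level_values(1).astype(str)]
    )
    common = news_wide.index.intersection(trad_wide.index)
    if common.empty:
        raise ValueError("no overlapping (district, month) observations")
    news_wide = news_wide.loc[common]
    trad_wide = trad_wide.loc[common]

    rows = []
    for k in trad_wide.columns:
        best: tuple[float, str] | None = None
        vk = trad_wide[k].to_numpy()
        for w in news_wide.columns:
            vw = news_wide[w].to_numpy()
            mask = np.isfinite(vk) & np.isfinite(vw)
            if mask.sum() < min_pairs:
                continue
            rho = spearmanr(vk[mask], vw[mask]).statistic
            if np.isnan(rho):
                continue
            if best is None or rho > best[0] or (rho == best[0] and w < best[1]):
                best = (float(rho), w)
        if best is not None:
            rows.append((k, best[1], best[0]))
    return pd.DataFrame(rows, columns=["factor", "feature", "spearman_rho"])


def aggregate_factor_panel(factors: pd.DataFrame, world: GeoHierarchy) -> pd.DataFrame:
    """Extend a district-level factor panel with province/country means.

    Traditional factors at the province (country) level are the unweighted
    mean over member districts, month by month.
    """
    dist = factors[factors["level"] == "district"].copy()
    out = [dist]
    for level, mapper in (
        ("province", lambda d: world.province_of[d]),
        ("country", lambda d: world.country_of(d)),
    ):
        g = dist.copy()
        g["unit_id"] = g["unit_id"].map(mapper)
        agg = (
            g.groupby(["unit_id", "month", "factor"], observed=True)["value"]
            .mean()
            .reset_index()
        )
        agg["level"] = level
        out.append(agg[["unit_id", "level", "month", "factor", "value"]])
    return pd.concat(out, ignore_index=True)
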