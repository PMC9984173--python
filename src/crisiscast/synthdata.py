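"""Synthetic world generator for the news-to-crisis pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage — lexicon construction, news-factor panels,
Granger screening, forecasting, outbreak evaluation — is exercisable
without the proprietary news corpus or the real food-insecurity panel:

* a district -> province -> country hierarchy;
* an ordinal 1-5 crisis phase reported quarterly before a regime-switch
  month and three times per year after it;
* a latent AR(1) risk process per component (conflict, price, weather,
  pest, displacement) with district, province and country shocks;
* traditional risk factors observed as lagged noisy transforms of the
  latent components (nine time-varying, five time-invariant);
* article streams in which mentions of planted "cause" features respond
  to the *current* latent risk while the phase responds with a per
  component delay ``lead_tau`` — so news mentions lead crisis onsets;
* cause/effect semantic frames containing seed phrases and causal-link
  triggers, plus distractor frames that must be rejected by the filter;
* cluster-structured embeddings with planted near-synonyms.

Coverage bias (how much the press writes about a district) is by default
independent of risk; ``coverage_risk_coupling`` couples it to the
district's realized mean risk when nonzero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crisiscast.embeddings import EmbeddingTable
from crisiscast.world import Calendar, ConfigurationError, GeoHierarchy

RISK_COMPONENTS = ("conflict", "price", "weather", "pest", "displacement")

#: planted cause features per risk component (the "true" lexicon)
DEFAULT_CAUSE_FEATURES: dict[str, tuple[str, ...]] = {
    "conflict": ("violence", "armed clashes"),
    "price": ("food prices", "price rise"),
    "weather": ("drought", "floods"),
    "pest": ("locusts", "crop pests"),
    "displacement": ("refugees", "displacement"),
}

#: near-synonyms sharing the embedding cluster of their component but never
#: emitted inside semantic frames — only keyword expansion can recover them
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "conflict": ("fighting",),
    "price": ("price hike",),
    "weather": ("dry spell",),
    "pest": ("armyworm",),
    "displacement": ("exodus",),
}

INITIAL_SEEDS = ("food insecurity", "hunger crisis", "famine")

DEFAULT_CAUSAL_LINKS = ("lead_to", "cause", "due_to", "result_in")

_SOURCES = (
    ("All Africa Global Media", 0.184),
    ("Reuters", 0.08),
    ("BBC", 0.06),
    ("AFP", 0.05),
) + tuple((f"local_{i:02d}", 0.0626) for i in range(10))


@dataclass(frozen=True)
class LatentRiskProcess:
    """Latent per-component risk, AR(1) in time with spatial shock sharing.

    ``z`` has shape ``(n_components, n_districts, n_months)``.  ``lead_tau``
    gives, per component, the number of months by which article mentions
    lead the component's effect on the reported phase.
    """

    z: np.ndarray
    ar_coef: float
    shock_sd: float
    lead_tau: dict[str, int]
    components: tuple[str, ...] = RISK_COMPONENTS

    def __post_init__(self) -> None:
        if not abs(self.ar_coef) < 1:
            raise ConfigurationError("|ar_coef| must be < 1")
        if any(v < 0 for v in self.lead_tau.values()):
            raise ConfigurationError("lead_tau must be >= 0")
        if self.z.shape[0] != len(self.components):
            raise ConfigurationError("z first axis must match components")


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic scenario.

    The default sizes describe the desk-scale reference world: 21
    "countries" of 3 provinces x 3 districts (189 districts), 11 years of
    months spanning the reporting regime switch, ~40 articles per
    district-month.  The seed fixes the entire generation stream.
    """

    n_countries: int = 21
    provinces_per_country: int = 3
    districts_per_province: int = 3
    start: str = "2009-07"
    n_months: int = 132
    regime_switch: str = "2016-01"

    # latent risk
    ar_coef: float = 0.8
    shock_sd: float = 1.0
    lead_tau: dict[str, int] = field(
        default_factory=lambda: {
            "conflict": 3,
            "price": 2,
            "weather": 4,
            "pest": 4,
            "displacement": 3,
        }
    )
    cutpoints: tuple[float, float, float, float] = (0.3, 0.9, 1.5, 2.1)

    # articles
    article_rate: float = 40.0
    coverage_bias_sd: float = 0.5
    coverage_risk_coupling: float = 0.0
    cause_features: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_FEATURES)
    )
    synonyms: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    seed_phrases: tuple[str, ...] = INITIAL_SEEDS
    causal_links: tuple[str, ...] = DEFAULT_CAUSAL_LINKS
    n_noise_features: int = 30
    noise_mention_prob: float = 0.05
    base_cause_prob: float = 0.02
    cause_gain: float = 0.6
    cause_z0: float = 0.8
    cause_scale: float = 1.0
    synonym_attenuation: float = 0.4
    frame_prob: float = 0.3
    distractor_prob: float = 0.02
    extra_district_prob: float = 0.05

    # traditional factors
    factor_noise_sd: float = 1.0
    report_lag_months: int = 3

    # embeddings
    embedding_dim: int = 8
    embedding_within_sd: float = 0.1
    embedding_between_sd: float = 2.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_countries", "provinces_per_country", "districts_per_province", "n_months"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("frame_prob", "noise_mention_prob", "base_cause_prob", "distractor_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.article_rate <= 0:
            raise ConfigurationError("article_rate must be positive")

    @property
    def noise_features(self) -> tuple[str, ...]:
        return tuple(f"topic{i:02d}" for i in range(self.n_noise_features))

    @property
    def planted_features(self) -> tuple[str, ...]:
        """All cause features, in component order."""
        return tuple(
            itertools.chain.from_iterable(self.cause_features.get(k, ()) for k in RISK_COMPONENTS)
        )

    def vocabulary(self) -> dict[str, str]:
        """word -> embedding-cluster label over every token the scenario uses."""
        vocab: dict[str, str] = {}
        for comp in RISK_COMPONENTS:
            for phrase in self.cause_features.get(comp, ()) + self.synonyms.get(comp, ()):
                for tok in phrase.split():
                    vocab[tok] = comp
        for phrase in self.seed_phrases:
            for tok in phrase.split():
                vocab[tok] = "food_crisis"
        for w in self.noise_features:
            vocab[w] = f"noise_{w}"
        for tok in ("hit", "farms", "looms", "markets", "reopened", "region"):
            vocab.setdefault(tok, f"filler_{tok}")
        return vocab


# ---------------------------------------------------------------------------
# world
# ---------------------------------------------------------------------------


def gen_world(config: ScenarioConfig) -> tuple[GeoHierarchy, Calendar]:
    """Build the geographic hierarchy and reporting calendar of a scenario."""
    districts: list[str] = []
    province_of: dict[str, str] = {}
    country_of: dict[str, str] = {}
    names: dict[str, str] = {}
    for ci in range(config.n_countries):
        c = f"c{ci:02d}"
        names[c] = f"Country {ci:02d}"
        for pi in range(config.provinces_per_country):
            p = f"{c}p{pi:02d}"
            country_of[p] = c
            names[p] = f"Province {ci:02d}-{pi:02d}"
            for di in range(config.districts_per_province):
                d = f"{p}d{di:02d}"
                districts.append(d)
                province_of[d] = p
                names[d] = f"District {ci:02d}-{pi:02d}-{di:02d}"
    world = GeoHierarchy(
        districts=tuple(districts),
        province_of=province_of,
        country_of_province=country_of,
        names=names,
    )
    calendar = Calendar.from_range(config.start, config.n_months, config.regime_switch)
    return world, calendar


def gen_latent_risk(
    world: GeoHierarchy,
    calendar: Calendar,
    ar_coef: float = 0.8,
    shock_sd: float = 1.0,
    lead_tau: dict[str, int] | None = None,
    seed: int = 0,
) -> LatentRiskProcess:
    """Simulate the AR(1) latent risk with shared province/country shocks.

    Innovations mix district, province and country noise with weights
    (0.75, 0.47, 0.47) — normalized so the total innovation variance is
    ``shock_sd**2`` — which induces the spatial correlation exploited by
    the province/country aggregation terms of the forecasting design.
    """
    if lead_tau is None:
        lead_tau = {k: 3 for k in RISK_COMPONENTS}
    rng = np.random.default_rng(seed)
    D, T, K = len(world.districts), len(calendar.months), len(RISK_COMPONENTS)
    provinces = world.provinces
    countries = world.countries
    p_idx = np.array([provinces.index(world.province_of[d]) for d in world.districts])
    c_idx = np.array([countries.index(world.country_of(d)) for d in world.districts])

    w = np.array([0.75, 0.47, 0.47])
    w = w / np.linalg.norm(w) * shock_sd

    def innovations(size_t: int) -> np.ndarray:
        e_d = rng.standard_normal((K, D, size_t))
        e_p = rng.standard_normal((K, len(provinces), size_t))[:, p_idx, :]
        e_c = rng.standard_normal((K, len(countries), size_t))[:, c_idx, :]
        return w[0] * e_d + w[1] * e_p + w[2] * e_c

    z = np.empty((K, D, T))
    stat_scale = 1.0 / np.sqrt(1.0 - ar_coef**2)
    z[:, :, 0] = innovations(1)[:, :, 0] * stat_scale
    eps = innovations(T - 1) if T > 1 else None
    for t in range(1, T):
        z[:, :, t] = ar_coef * z[:, :, t - 1] + eps[:, :, t - 1]
    return LatentRiskProcess(z=z, ar_coef=ar_coef, shock_sd=shock_sd, lead_tau=dict(lead_tau))


# ---------------------------------------------------------------------------
# IPC phases
# ---------------------------------------------------------------------------


def aggregate_risk(
    world: GeoHierarchy, calendar: Calendar, risk: LatentRiskProcess
) -> pd.DataFrame:
    """Per (district, reporting period) mean lagged latent risk.

    For each component the window-mean of ``z`` delayed by that component's
    ``lead_tau`` (article mentions react to current risk, the phase only
    ``lead_tau`` months later); components are then averaged.
    """
    months = calendar.months
    month_pos = {m: i for i, m in enumerate(months)}
    rows = []
    for period in calendar.reporting_periods:
        window = [month_pos[m] for m in calendar.period_window(period)]
        agg = np.zeros(len(world.districts))
        for k, comp in enumerate(risk.components):
            tau = risk.lead_tau.get(comp, 0)
            lagged = [max(i - tau, 0) for i in window]
            agg += risk.z[k][:, lagged].mean(axis=1)
        agg /= len(risk.components)
        for d, val in zip(world.districts, agg):
            rows.append((d, period, val))
    return pd.DataFrame(rows, columns=["district_id", "period", "risk"])


def gen_ipc_panel(
    world: GeoHierarchy,
    calendar: Calendar,
    risk: LatentRiskProcess,
    cutpoints: tuple[float, float, float, float] = ScenarioConfig.cutpoints,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ordinal 1-5 phase panel: 1 + number of cutpoints below aggregated risk.

    Returns a complete long panel with columns ``district_id``, ``period``
    (period-end month) and ``phase``.
    """
    cut = np.asarray(cutpoints, dtype=float)
    if cut.ndim != 1 or len(cut) != 4 or not np.all(np.diff(cut) > 0):
        raise ConfigurationError("cutpoints must be 4 strictly increasing reals")
    agg = aggregate_risk(world, calendar, risk)
    values = agg["risk"].to_numpy()
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0, noise_sd, len(values))
    phase = 1 + (values[:, None] > cut[None, :]).sum(axis=1)
    out = agg[["district_id", "period"]].copy()
    out["phase"] = phase.astype(int)
    return out


# ---------------------------------------------------------------------------
# traditional risk factors
# ---------------------------------------------------------------------------

#: (factor name, risk component, monotone transform of the latent value)
FACTOR_DEFS: tuple[tuple[str, str], ...] = (
    ("conflict_events", "conflict"),
    ("conflict_fatalities", "conflict"),
    ("food_price_index", "price"),
    ("food_price_yoy", "price"),
    ("evapotranspiration", "weather"),
    ("rainfall_deficit", "weather"),
    ("ndvi_inverted", "pest"),
    ("ndvi_anomaly", "pest"),
    ("displacement_count", "displacement"),
)

STATIC_ATTRS = ("population", "district_size", "ruggedness", "cropland_share", "pasture_share")

_TRANSFORMS = {
    "conflict_events": lambda z: 8.0 * np.exp(0.6 * z),
    "conflict_fatalities": lambda z: 2.0 * np.exp(0.5 * z),
    "food_price_index": lambda z: 100.0 + 15.0 * z,
    "food_price_yoy": lambda z: 10.0 * z,
    "evapotranspiration": lambda z: 50.0 + 10.0 * z,
    "rainfall_deficit": lambda z: 5.0 * z,
    "ndvi_inverted": lambda z: 0.5 + 0.1 * z,
    "ndvi_anomaly": lambda z: 2.0 * z,
    "displacement_count": lambda z: 20.0 * np.exp(0.5 * z),
}

factor_transform = dict(_TRANSFORMS)  # public alias used by tests


def gen_traditional_factors(
    world: GeoHierarchy,
    calendar: Calendar,
    risk: LatentRiskProcess,
    noise_sd: float = 1.0,
    report_lag_months: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nine time-varying factors plus five time-invariant district attributes.

    Each time-varying factor is a monotone transform of one latent risk
    component observed ``report_lag_months`` late through Gaussian
    measurement noise of standard deviation ``noise_sd`` on the latent
    scale (so the same ``noise_sd`` degrades every factor comparably,
    whatever the transform's output units).  The reporting lag is what
    makes traditional indicators "outdated" relative to the news.

    Returns ``(factors, static)``: long frames with columns
    (unit_id, level, month, factor, value) and (district_id, attr, value).
    """
    if report_lag_months < 0:
        raise ConfigurationError("report_lag_months must be >= 0")
    rng = np.random.default_rng(seed)
    T = len(calendar.months)
    comp_index = {c: i for i, c in enumerate(risk.components)}
    lag_idx = np.maximum(np.arange(T) - report_lag_months, 0)
    frames = []
    for fname, comp in FACTOR_DEFS:
        zlag = risk.z[comp_index[comp]][:, lag_idx]
        if noise_sd > 0:
            zlag = zlag + noise_sd * rng.standard_normal(zlag.shape)
        values = _TRANSFORMS[fname](zlag)
        df = pd.DataFrame(values, index=world.districts, columns=calendar.months)
        long = df.stack()
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": long.index.get_level_values(0),
                    "level": "district",
                    "month": long.index.get_level_values(1),
                    "factor": fname,
                    "value": long.to_numpy(),
                }
            )
        )
    factors = pd.concat(frames, ignore_index=True)

    D = len(world.districts)
    static = pd.DataFrame(
        {
            "district_id": np.repeat(world.districts, len(STATIC_ATTRS)),
            "attr": np.tile(STATIC_ATTRS, D),
            "value": np.column_stack(
                [
                    rng.lognormal(11, 1, D),
                    rng.lognormal(7, 0.8, D),
                    rng.uniform(0, 5, D),
                    rng.beta(2, 3, D),
                    rng.beta(2, 4, D),
                ]
            ).ravel(),
        }
    )
    return factors, static


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


def gen_embeddings(
    vocab: dict[str, str],
    dim: int = 8,
    within_sd: float = 0.1,
    between_sd: float = 2.0,
    seed: int = 0,
) -> EmbeddingTable:
    """Cluster-structured embeddings: centroid per cluster, words around it.

    ``vocab`` maps each word to its cluster label; a missing/empty label is
    a configuration error.  ``within_sd`` must be smaller than
    ``between_sd`` so that cluster structure actually exists.
    """
    if not within_sd < between_sd:
        raise ConfigurationError("within_sd must be < between_sd")
    for w, c in vocab.items():
        if not c:
            raise ConfigurationError(f"word {w!r} has no cluster label")
    rng = np.random.default_rng(seed)
    clusters = sorted(set(vocab.values()))
    centroids = {c: rng.normal(0, between_sd, dim) for c in clusters}
    vectors = {
        w: centroids[c] + rng.normal(0, within_sd, dim) for w, c in sorted(vocab.items())
    }
    return EmbeddingTable(vectors)


# ---------------------------------------------------------------------------
# articles and frames
# ---------------------------------------------------------------------------


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def coverage_bias(config: ScenarioConfig, world: GeoHierarchy, risk: LatentRiskProcess) -> np.ndarray:
    """Per-district multiplier on the article rate (mean-one log-normal).

    With ``coverage_risk_coupling`` nonzero the bias additionally scales
    with the district's realized mean risk (press attention follows
    crises) — off by default, as the joint distribution of coverage and
    food insecurity is a modeling choice, not an observed fact.
    """
    rng = np.random.default_rng(config.seed + 101)
    bias = rng.lognormal(0.0, config.coverage_bias_sd, len(world.districts))
    if config.coverage_risk_coupling != 0.0:
        mean_z = risk.z.mean(axis=(0, 2))
        bias = bias * np.exp(config.coverage_risk_coupling * mean_z)
    return bias / bias.mean()


def gen_articles(
    world: GeoHierarchy,
    calendar: Calendar,
    risk: LatentRiskProcess,
    config: ScenarioConfig,
) -> tuple[list[dict], list[dict]]:
    """Simulate the article stream and its cause/effect semantic frames.

    Article counts are Poisson(rate x coverage bias) per district-month.
    A cause feature of component ``k`` is mentioned with probability
    ``base + gain * logistic((z_k - z0)/scale)`` evaluated at the article's
    month — no lead applied here; the *phase* is what lags the risk.
    Synonyms are mentioned at an attenuated version of the same probability,
    noise features at a constant base rate.  A configured fraction of cause
    mentions also emits a semantic frame whose cause constituent contains
    the feature and whose effect constituent contains a seed phrase, with a
    causal-link trigger.  Distractor frames (no cause role / effect without
    a seed / non-causal trigger) are emitted at a low rate so the four-step
    filter has something to reject.
    """
    if not config.planted_features:
        raise ConfigurationError("planted cause-feature lexicon must be non-empty")
    rng = np.random.default_rng(config.seed + 202)
    bias = coverage_bias(config, world, risk)
    comp_index = {c: i for i, c in enumerate(risk.components)}

    cause_list = [(f, comp) for comp in RISK_COMPONENTS for f in config.cause_features.get(comp, ())]
    syn_list = [(s, comp) for comp in RISK_COMPONENTS for s in config.synonyms.get(comp, ())]
    noise_list = list(config.noise_features)
    seeds = list(config.seed_phrases)

    src_names = [s for s, _ in _SOURCES]
    src_probs = np.array([p for _, p in _SOURCES])
    src_probs = src_probs / src_probs.sum()

    articles: list[dict] = []
    frames: list[dict] = []
    article_counter = 0
    n_districts = len(world.districts)

    for t, month in enumerate(calendar.months):
        month_str = str(month)
        counts = rng.poisson(config.article_rate * bias)
        for di in range(n_districts):
            n = counts[di]
            if n == 0:
                continue
            d = world.districts[di]
            # mention probabilities for this district-month
            p_cause = np.array(
                [
                    config.base_cause_prob
                    + config.cause_gain
                    * _logistic(
                        (risk.z[comp_index[comp], di, t] - config.cause_z0) / config.cause_scale
                    )
                    for _, comp in cause_list
                ]
            )
            p_syn = config.synonym_attenuation * np.array(
                [
                    config.base_cause_prob
                    + config.cause_gain
                    * _logistic(
                        (risk.z[comp_index[comp], di, t] - config.cause_z0) / config.cause_scale
                    )
                    for _, comp in syn_list
                ]
            )
            zbar = risk.z[:, di, t].mean()
            p_seed = min(0.02 + 0.2 * float(_logistic((zbar - 1.0) / 0.5)), 0.95)

            m_cause = rng.random((n, len(cause_list))) < p_cause
            m_syn = rng.random((n, len(syn_list))) < p_syn
            m_noise = rng.random((n, len(noise_list))) < config.noise_mention_prob
            m_seed = rng.random(n) < p_seed
            extra = rng.random(n) < config.extra_district_prob
            extra_pick = rng.integers(0, n_districts, n)
            srcs = rng.choice(len(src_names), size=n, p=src_probs)
            u_frame = rng.random((n, len(cause_list)))
            u_distract = rng.random((n, 3))

            for a in range(n):
                article_counter += 1
                aid = f"a{article_counter:08d}"
                d_ids = [d]
                if extra[a] and world.districts[extra_pick[a]] != d:
                    d_ids.append(world.districts[extra_pick[a]])
                ngrams = [f for j, (f, _) in enumerate(cause_list) if m_cause[a, j]]
                ngrams += [s for j, (s, _) in enumerate(syn_list) if m_syn[a, j]]
                ngrams += [wrd for j, wrd in enumerate(noise_list) if m_noise[a, j]]
                if m_seed[a]:
                    ngrams.append(seeds[article_counter % len(seeds)])
                prov_ids = sorted({world.province_of[x] for x in d_ids})
                ctry_ids = sorted({world.country_of(x) for x in d_ids})
                articles.append(
                    {
                        "id": aid,
                        "month": month_str,
                        "source": src_names[srcs[a]],
                        "district_ids": d_ids,
                        "province_ids": prov_ids,
                        "country_ids": ctry_ids,
                        "ngrams": ngrams,
                    }
                )
                if config.frame_prob == 0:
                    continue  # no frame stream at all, distractors included
                sent = 0
                for j, (f, _) in enumerate(cause_list):
                    if m_cause[a, j] and u_frame[a, j] < config.frame_prob:
                        sent += 1
                        frames.append(
                            {
                                "article_id": aid,
                                "sentence_id": sent,
                                "constituents": [
                                    {"text": f"{f} hit farms", "role": "cause"},
                                    {
                                        "text": f"{seeds[(article_counter + j) % len(seeds)]} looms",
                                        "role": "effect",
                                    },
                                ],
                                "trigger": config.causal_links[
                                    (article_counter + j) % len(config.causal_links)
                                ],
                            }
                        )
                # distractor frames: rejected by filter steps 1, 2 and 3
                if u_distract[a, 0] < config.distractor_prob:
                    sent += 1
                    frames.append(
                        {
                            "article_id": aid,
                            "sentence_id": sent,
                            "constituents": [
                                {"text": f"{seeds[0]} looms", "role": "effect"}
                            ],
                            "trigger": config.causal_links[0],
                        }
                    )
                if u_distract[a, 1] < config.distractor_prob:
                    sent += 1
                    noise_w = noise_list[article_counter % len(noise_list)] if noise_list else "markets"
                    frames.append(
                        {
                            "article_id": aid,
                            "sentence_id": sent,
                            "constituents": [
                                {"text": f"{noise_w} hit farms", "role": "cause"},
                                {"text": "markets reopened", "role": "effect"},
                            ],
                            "trigger": config.causal_links[0],
                        }
                    )
                if u_distract[a, 2] < config.distractor_prob:
                    sent += 1
                    frames.append(
                        {
                            "article_id": aid,
                            "sentence_id": sent,
                            "constituents": [
                                {"text": f"{cause_list[0][0]} hit farms", "role": "cause"},
                                {"text": f"{seeds[0]} looms", "role": "effect"},
                            ],
                            "trigger": "said",
                        }
                    )
    return articles, frames


# ---------------------------------------------------------------------------
# one-call scenario generation
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """Everything one synthetic run produces."""

    config: ScenarioConfig
    world: GeoHierarchy
    calendar: Calendar
    risk: LatentRiskProcess
    ipc: pd.DataFrame
    factors: pd.DataFrame
    static: pd.DataFrame
    embeddings: EmbeddingTable
    articles: list[dict]
    frames: list[dict]


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full synthetic world from one config (seed-deterministic)."""
    world, calendar = gen_world(config)
    risk = gen_latent_risk(
        world,
        calendar,
        ar_coef=config.ar_coef,
        shock_sd=config.shock_sd,
        lead_tau=config.lead_tau,
        seed=config.seed,
    )
    ipc = gen_ipc_panel(world, calendar, risk, config.cutpoints)
    factors, static = gen_traditional_factors(
        world,
        calendar,
        risk,
        noise_sd=config.factor_noise_sd,
        report_lag_months=config.report_lag_months,
        seed=config.seed + 1,
    )
    emb = gen_embeddings(
        config.vocabulary(),
        dim=config.embedding_dim,
        within_sd=config.embedding_within_sd,
        between_sd=config.embedding_between_sd,
        seed=config.seed + 2,
    )
    articles, frames = gen_articles(world, calendar, risk, config)
    return Scenario(config, world, calendar, risk, ipc, factors, static, emb, articles, frames)
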