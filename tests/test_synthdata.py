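"""Statistical structure of the synthetic world generator."""

import json

import numpy as np
import pandas as pd
import pytest

from crisiscast.synthdata import (
    FACTOR_DEFS,
    RISK_COMPONENTS,
    STATIC_ATTRS,
    LatentRiskProcess,
    ScenarioConfig,
    factor_transform,
    gen_articles,
    gen_embeddings,
    gen_ipc_panel,
    gen_latent_risk,
    gen_traditional_factors,
    gen_world,
    generate_scenario,
)
from crisiscast.world import ConfigurationError


def _flat_risk(world, calendar, value, lead_tau=None):
    """Deterministic constant-risk process for threshold checks."""
    z = np.full((len(RISK_COMPONENTS), len(world.districts), len(calendar.months)), value)
    return LatentRiskProcess(
        z=z, ar_coef=0.5, shock_sd=1.0,
        lead_tau=lead_tau or {k: 0 for k in RISK_COMPONENTS},
    )


class TestIPCPanel:
    def test_risk_below_first_cutpoint_gives_phase_one_everywhere(self):
        world, cal = gen_world(ScenarioConfig(n_countries=2, n_months=24))
        risk = _flat_risk(world, cal, -50.0)
        ipc = gen_ipc_panel(world, cal, risk, cutpoints=(0.3, 0.9, 1.5, 2.1))
        assert (ipc["phase"] == 1).all()

    def test_extreme_cutpoints_give_constant_phase(self):
        world, cal = gen_world(ScenarioConfig(n_countries=2, n_months=24))
        risk = gen_latent_risk(world, cal, seed=4)
        low = gen_ipc_panel(world, cal, risk, cutpoints=(1e9, 2e9, 3e9, 4e9))
        high = gen_ipc_panel(world, cal, risk, cutpoints=(-4e9, -3e9, -2e9, -1e9))
        assert (low["phase"] == 1).all()
        assert (high["phase"] == 5).all()

    def test_panel_complete_and_in_range(self, tiny_scenario):
        scn = tiny_scenario
        D = len(scn.world.districts)
        P = len(scn.calendar.reporting_periods)
        assert len(scn.ipc) == D * P
        assert scn.ipc["phase"].between(1, 5).all()

    def test_nonmonotone_cutpoints_rejected(self):
        world, cal = gen_world(ScenarioConfig(n_countries=2, n_months=24))
        risk = _flat_risk(world, cal, 0.0)
        with pytest.raises(ConfigurationError):
            gen_ipc_panel(world, cal, risk, cutpoints=(1.0, 0.5, 1.5, 2.0))

    def test_phase_frequencies_match_independent_seed_stream(self):
        """Two independent seed streams agree on phase frequencies to +-3pp.

        ar 0.9, unit shocks, 200 districts x 40 reporting periods.
        """
        cfg = ScenarioConfig(
            n_countries=5, provinces_per_country=5, districts_per_province=8,
            n_months=123, ar_coef=0.9, start="2000-01",
        )
        world, cal = gen_world(cfg)
        assert len(world.districts) == 200
        assert len(cal.reporting_periods) >= 40
        freqs = []
        for seed in (7, 1007):
            risk = gen_latent_risk(world, cal, ar_coef=0.9, shock_sd=1.0, seed=seed)
            ipc = gen_ipc_panel(world, cal, risk, cfg.cutpoints)
            freqs.append(
                ipc["phase"].value_counts(normalize=True).reindex(range(1, 6), fill_value=0)
            )
        assert np.abs(freqs[0] - freqs[1]).max() < 0.03


class TestTraditionalFactors:
    def test_zero_noise_zero_lag_equals_monotone_transform(self):
        world, cal = gen_world(ScenarioConfig(n_countries=2, n_months=30))
        risk = gen_latent_risk(world, cal, seed=3)
        factors, _ = gen_traditional_factors(
            world, cal, risk, noise_sd=0.0, report_lag_months=0, seed=1
        )
        comp_index = {c: i for i, c in enumerate(risk.components)}
        for fname, comp in FACTOR_DEFS:
            sub = factors[factors["factor"] == fname]
            wide = sub.pivot(index="unit_id", columns="month", values="value")
            wide = wide.loc[list(world.districts)]
            expected = factor_transform[fname](risk.z[comp_index[comp]])
            np.testing.assert_allclose(wide.to_numpy(), expected, rtol=1e-12)

    def test_reporting_lag_shifts_cross_correlation_peak(self):
        """With lag 2, corr(factor_t, z_{t-k}) is maximized at k = 2 (n=300)."""
        world, cal = gen_world(
            ScenarioConfig(n_countries=1, provinces_per_country=1,
                           districts_per_province=1, n_months=300)
        )
        risk = gen_latent_risk(world, cal, seed=5)
        factors, _ = gen_traditional_factors(
            world, cal, risk, noise_sd=0.3, report_lag_months=2, seed=2
        )
        sub = factors[factors["factor"] == "food_price_yoy"].sort_values("month")
        series = sub["value"].to_numpy()
        z = risk.z[list(risk.components).index("price")][0]
        corrs = [
            np.corrcoef(series[k:], z[: len(z) - k if k else None])[0, 1]
            for k in range(6)
        ]
        assert int(np.argmax(corrs)) == 2

    def test_static_attributes_are_per_district_constants(self, tiny_scenario):
        static = tiny_scenario.static
        assert set(static["attr"]) == set(STATIC_ATTRS)
        counts = static.groupby("district_id").size()
        assert (counts == len(STATIC_ATTRS)).all()

    def test_negative_lag_rejected(self):
        world, cal = gen_world(ScenarioConfig(n_countries=2, n_months=30))
        risk = gen_latent_risk(world, cal, seed=3)
        with pytest.raises(ConfigurationError):
            gen_traditional_factors(world, cal, risk, report_lag_months=-1)


class TestEmbeddings:
    def test_zero_within_sd_collapses_clusters(self):
        emb = gen_embeddings({"a": "x", "b": "x", "c": "y"}, dim=4, within_sd=0.0,
                             between_sd=1.0, seed=0)
        np.testing.assert_array_equal(emb["a"], emb["b"])
        assert np.linalg.norm(emb["a"] - emb["c"]) > 0

    def test_within_cluster_distances_below_between(self):
        vocab = {f"w{i:02d}": f"c{i % 5}" for i in range(50)}
        emb = gen_embeddings(vocab, dim=8, within_sd=0.1, between_sd=2.0, seed=3)
        within, between = [], []
        words = sorted(vocab)
        for i, a in enumerate(words):
            for b in words[i + 1 :]:
                d = np.linalg.norm(emb[a] - emb[b])
                (within if vocab[a] == vocab[b] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_lookup_is_deterministic(self):
        vocab = {"a": "x", "b": "y"}
        e1 = gen_embeddings(vocab, seed=9)
        e2 = gen_embeddings(vocab, seed=9)
        np.testing.assert_array_equal(e1["a"], e2["a"])
        np.testing.assert_array_equal(e1["a"], e1["a"])

    def test_missing_cluster_label_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_embeddings({"a": "x", "b": ""}, seed=0)

    def test_degenerate_cluster_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_embeddings({"a": "x"}, within_sd=2.0, between_sd=1.0)


class TestArticles:
    def test_zero_frame_probability_emits_no_frames(self, tiny_config):
        cfg = ScenarioConfig(**{**tiny_config.__dict__, "frame_prob": 0.0})
        world, cal = gen_world(cfg)
        risk = gen_latent_risk(world, cal, seed=cfg.seed)
        _, frames = gen_articles(world, cal, risk, cfg)
        assert frames == []

    def test_empty_lexicon_rejected(self, tiny_config):
        cfg = ScenarioConfig(**{**tiny_config.__dict__, "cause_features": {}})
        world, cal = gen_world(cfg)
        risk = gen_latent_risk(world, cal, seed=cfg.seed)
        with pytest.raises(ConfigurationError):
            gen_articles(world, cal, risk, cfg)

    def test_noise_feature_mention_rate_matches_base_probability(self):
        """Observed proportion within 3 binomial SEs of the configured rate."""
        cfg = ScenarioConfig(
            n_countries=1, provinces_per_country=1, districts_per_province=1,
            n_months=12, article_rate=100.0, noise_mention_prob=0.2,
            n_noise_features=3, seed=21,
        )
        world, cal = gen_world(cfg)
        risk = gen_latent_risk(world, cal, seed=cfg.seed)
        articles, _ = gen_articles(world, cal, risk, cfg)
        n = len(articles)
        assert n > 1000
        p_hat = np.mean(["topic00" in a["ngrams"] for a in articles])
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(p_hat - 0.2) < 3 * se

    def test_planted_mentions_lead_phase_by_component_lag(self):
        """Weather mentions (lead_tau=4) cross-correlate with the phase at a
        4-to-6-month lead, the planted lead plus the aggregation window."""
        cfg = ScenarioConfig(
            n_countries=8, provinces_per_country=2, districts_per_province=2,
            n_months=96, article_rate=20.0, n_noise_features=5, seed=11,
        )
        scn = generate_scenario(cfg)
        months = list(scn.calendar.months)
        mpos = {m: i for i, m in enumerate(months)}
        dpos = {d: i for i, d in enumerate(scn.world.districts)}
        tot = np.zeros((len(dpos), len(months)))
        hit = np.zeros_like(tot)
        for a in scn.articles:
            j = mpos[pd.Period(a["month"], freq="M")]
            for d in a["district_ids"]:
                tot[dpos[d], j] += 1
                hit[dpos[d], j] += "drought" in a["ngrams"]
        prop = np.where(tot > 0, hit / np.maximum(tot, 1), 0.0)
        ipc = scn.ipc.pivot(index="district_id", columns="period", values="phase")
        corr_by_lead = []
        for lead in range(9):
            xs, ys = [], []
            for d in scn.world.districts:
                for p in ipc.columns:
                    j = mpos.get(p - lead)
                    if j is not None:
                        xs.append(prop[dpos[d], j])
                        ys.append(ipc.loc[d, p])
            corr_by_lead.append(np.corrcoef(xs, ys)[0, 1])
        assert int(np.argmax(corr_by_lead)) in (4, 5, 6)

    def test_fixed_seed_reruns_are_bit_identical(self, tiny_config, tiny_scenario):
        rerun = generate_scenario(tiny_config)
        assert json.dumps(rerun.articles) == json.dumps(tiny_scenario.articles)
        assert json.dumps(rerun.frames) == json.dumps(tiny_scenario.frames)
        np.testing.assert_array_equal(rerun.risk.z, tiny_scenario.risk.z)
        pd.testing.assert_frame_equal(rerun.ipc, tiny_scenario.ipc)
        pd.testing.assert_frame_equal(rerun.factors, tiny_scenario.factors)

    def test_articles_carry_ancestor_unit_ids(self, tiny_scenario):
        world = tiny_scenario.world
        for a in tiny_scenario.articles[:200]:
            provs = {world.province_of[d] for d in a["district_ids"]}
            ctrys = {world.country_of(d) for d in a["district_ids"]}
            assert set(a["province_ids"]) == provs
            assert set(a["country_ids"]) == ctrys
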