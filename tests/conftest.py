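"""Shared fixtures: a tiny synthetic scenario and hand-set embeddings."""

import numpy as np
import pytest

from crisiscast.embeddings import EmbeddingTable
from crisiscast.synthdata import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def tiny_config():
    return ScenarioConfig(
        n_countries=2,
        provinces_per_country=2,
        districts_per_province=2,
        n_months=48,
        article_rate=8.0,
        n_noise_features=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_scenario(tiny_config):
    return generate_scenario(tiny_config)


@pytest.fixture
def toy_embeddings():
    """Small planar embedding with known geometry."""
    return EmbeddingTable(
        {
            "a": np.array([0.0, 0.0]),
            "b": np.array([3.0, 4.0]),
            "c": np.array([0.0, 1.0]),
            "d": np.array([1.0, 1.0]),
            "e": np.array([1.0, 0.0]),
            "food": np.array([0.1, 0.1]),
            "hunger": np.array([0.2, 0.0]),
            "famine": np.array([0.15, 0.05]),
        }
    )
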