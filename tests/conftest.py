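import hypothesis
import numpy as np
import pandas as pd
import pytest

import ancbayes as ab

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def intention_truth():
    """Generating coefficients used across recovery checks."""
    return {"Intercept": 0.3, "intention[mistimed]": -0.3,
            "intention[unwanted]": -0.37}


@pytest.fixture(scope="session")
def small_derived(intention_truth):
    """A derived analysis table from a mid-sized simulated wave."""
    cfg = ab.SimConfig(year_label=2014, seed=42, n_clusters=100,
                       households_per_cluster=20, beta=intention_truth,
                       sigma_u=0.8, p_recent_birth=1.0, p_missing_intention=0.0)
    wave = ab.generate_wave(cfg)
    derived, _ = ab.derive(wave.women)
    return derived


@pytest.fixture(scope="session")
def toy_model():
    """10 observations in 2 clusters with lognormal weights."""
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 10).astype(float)
    X = np.column_stack([np.ones(10), rng.normal(size=10)])
    groups = np.array([0] * 5 + [1] * 5)
    w = rng.lognormal(0, 0.3, 10)
    return ab.MultilevelLogit(y, X, groups, weights=w,
                              exog_names=["Intercept", "x"])


@pytest.fixture(scope="session")
def intercept_model():
    """20 Bernoulli observations, intercept-only, 4 nominal clusters."""
    rng = np.random.default_rng(3)
    y = (rng.random(20) < 0.6).astype(float)
    return ab.MultilevelLogit(y, np.ones((20, 1)), np.arange(20) % 4,
                              exog_names=["Intercept"])


@pytest.fixture()
def raw_toy_records():
    """Six raw records: 3 eligible, 2 without a recent birth, 1 missing intention."""
    base = {"woman_id": 0, "cluster_id": 1, "weight": 1.0, "birth_within_3y": 1,
            "anc_visits": 2.0, "anc_provider_skilled": 1.0, "intention": "wanted",
            "age_at_delivery_years": 25, "education": "primary",
            "husband_education": "primary", "children_ever_born": 2,
            "husband_occupation": "business", "newspaper_weekly": 0,
            "radio_weekly": 0, "tv_weekly": 1, "wealth_quintile": "middle",
            "residence": "rural", "region": "dhaka", "anc_quality": 0.0}
    rows = []
    for i in range(6):
        row = dict(base, woman_id=i + 1)
        if i in (3, 4):
            row["birth_within_3y"] = 0
            row["intention"] = ""
            row["anc_visits"] = np.nan
            row["anc_provider_skilled"] = np.nan
        if i == 5:
            row["intention"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
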