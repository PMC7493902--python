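"""ICC closed form, Gelman-Rubin behaviour, and the M0-M3 model ladder."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ancbayes as ab
from ancbayes.diagnostics import LATENT_RESIDUAL_VARIANCE, MODEL_TERMS


class TestICC:
    @pytest.mark.parametrize("sigma_u2,expected", [
        (0.0, 0.0),
        (np.pi ** 2 / 3, 0.5),
        (9.8696, 0.75),              # pi^2 over (pi^2 + pi^2/3) by hand
    ])
    def test_closed_form(self, sigma_u2, expected):
        assert ab.icc_latent(sigma_u2) == pytest.approx(expected, abs=1e-4)

    def test_exact_at_latent_variance(self):
        assert ab.icc_latent(LATENT_RESIDUAL_VARIANCE) == 0.5

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ab.icc_latent(-0.1)

    @given(st.floats(min_value=0.0, max_value=80.0, allow_nan=False))
    def test_monotone_and_bounded(self, s2):
        icc = ab.icc_latent(s2)
        assert 0.0 <= icc < 1.0
        assert ab.icc_latent(s2 + 0.5) > icc


class TestGelmanRubin:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 10_000))
        assert 0.99 <= ab.gelman_rubin(chains) <= 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 2000), rng.normal(5, 1, 2000)])
        assert ab.gelman_rubin(chains) > 1.5

    def test_chain_against_its_own_halves(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20_000)
        rc = ab.gelman_rubin(x.reshape(2, 10_000))
        assert rc == pytest.approx(1.0, abs=0.01)

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False),
           st.floats(min_value=0.1, max_value=10, allow_nan=False))
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(7)
        chains = rng.standard_normal((3, 500))
        assert ab.gelman_rubin(chains * scale + shift) == pytest.approx(
            ab.gelman_rubin(chains), rel=1e-9)

    def test_degenerate_chains_rejected(self):
        with pytest.raises(ValueError):
            ab.gelman_rubin(np.ones((2, 100)))
        with pytest.raises(ValueError):
            ab.gelman_rubin(np.random.default_rng(0).standard_normal((1, 100)))

    def test_agrees_with_arviz_on_stationary_chains(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 5_000))
        ours = ab.gelman_rubin(chains)
        theirs = float(arviz.rhat(chains))
        assert ours == pytest.approx(theirs, abs=0.02)


@pytest.fixture(scope="module")
def community_effect_data():
    """Cluster-level covariates carry the signal; random intercept is small."""
    cfg = ab.SimConfig(
        year_label=2014, seed=31, n_clusters=80, households_per_cluster=15,
        beta={"Intercept": 0.2, "residence[rural]": -0.9,
              "region[dhaka]": 0.8, "region[sylhet]": -0.8},
        sigma_u=0.4, p_recent_birth=1.0, p_missing_intention=0.0)
    derived, _ = ab.derive(ab.generate_wave(cfg).women)
    return derived


class TestModelSequence:
    def test_ladder_shapes_and_nesting(self, community_effect_data):
        table = ab.model_sequence(community_effect_data, outcomes=("y_any",),
                                  run_mcmc=False)
        assert list(table["model"]) == ["M0", "M1", "M2", "M3"]
        assert (table["error"] == "").all()
        llf = table.set_index("model")["llf"]
        # nested-model monotonicity of the maximised likelihood
        assert llf["M1"] >= llf["M0"] - 1e-6
        assert llf["M2"] >= llf["M0"] - 1e-6
        assert llf["M3"] >= llf["M1"] - 1e-6
        assert llf["M3"] >= llf["M2"] - 1e-6

    def test_covariates_absorb_cluster_variance(self, community_effect_data):
        """Cluster-level effects in truth: adjusting for them drops the ICC."""
        table = ab.model_sequence(community_effect_data, outcomes=("y_any",),
                                  run_mcmc=False).set_index("model")
        assert table.loc["M0", "icc"] > table.loc["M3", "icc"]

    def test_null_truth_prefers_null_model_by_bic(self):
        cfg = ab.SimConfig(year_label=2014, seed=33, n_clusters=70,
                           households_per_cluster=15, beta={"Intercept": 0.0},
                           sigma_u=0.0, p_recent_birth=1.0,
                           p_missing_intention=0.0)
        derived, _ = ab.derive(ab.generate_wave(cfg).women)
        table = ab.model_sequence(derived, outcomes=("y_any",),
                                  run_mcmc=False).set_index("model")
        assert table["bic"].idxmin() == "M0"
        for label in ("M1", "M2", "M3"):
            dk = table.loc[label, "k"] - table.loc["M0", "k"]
            assert table.loc[label, "aic"] - table.loc["M0", "aic"] <= 2 * dk

    def test_icc_recovery_with_large_cluster_effect(self):
        cfg = ab.SimConfig(year_label=2014, seed=35, n_clusters=200,
                           households_per_cluster=20, beta={"Intercept": 0.0},
                           sigma_u=float(np.sqrt(np.pi ** 2 / 3)),
                           p_recent_birth=1.0, p_missing_intention=0.0)
        derived, _ = ab.derive(ab.generate_wave(cfg).women)
        table = ab.model_sequence(derived, outcomes=("y_any",),
                                  run_mcmc=False).set_index("model")
        assert table.loc["M0", "icc"] == pytest.approx(0.5, abs=0.1)

    def test_mcmc_rows_carry_convergence(self, community_effect_data):
        table = ab.model_sequence(
            community_effect_data, outcomes=("y_any",), run_mcmc=True,
            mcmc_settings={"n_chains": 2, "n_burnin": 200, "n_kept": 500},
            seed=5)
        sub = table[table["model"].isin(["M0", "M2"])]
        assert sub["max_rc"].notna().all()
        assert "preferred" in table.attrs

    def test_model_groups_cover_all_terms(self):
        assert set(MODEL_TERMS["M3"]) == set(MODEL_TERMS["M1"]) | set(MODEL_TERMS["M2"])
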