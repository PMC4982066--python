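"""Sampler correctness: identification, truncation, diagnostics, recovery."""

import numpy as np
import pytest
from scipy.stats import chi2

from ipdmix import (
    DGPParams,
    JointLatentNormalModel,
    MCMCConfig,
    ScenarioConfig,
    draw_complete_ipd,
    gelman_rubin,
    joint_region_contains,
)
from ipdmix.results import JointModelResults, PARAM_NAMES


class TestIdentificationInvariants:
    def test_sigma2_fixed_to_one_at_every_retained_draw(self, small_fit):
        assert np.all(small_fit.chains("sigma2_sq") == 1.0)

    def test_latent_sign_consistency_at_every_retained_draw(self, small_fit):
        # fraction of observed-y2 rows whose latent has the right sign
        assert np.all(small_fit.chains("z_sign_frac") == 1.0)

    def test_draw_count_and_finiteness(self, small_fit):
        assert small_fit.n_chains == 2
        assert small_fit.n_draws == 1200  # (2000 - 800) / thin 1
        frame = small_fit.to_frame()
        assert np.isfinite(frame.to_numpy()).all()


class TestModelValidation:
    def test_single_study_rejected(self, small_complete):
        one = small_complete[small_complete.study_id == 0]
        with pytest.raises(ValueError, match="2 studies"):
            JointLatentNormalModel(one)

    def test_constant_treatment_rejected(self, small_complete):
        bad = small_complete.copy()
        bad["treatment"] = 0
        with pytest.raises(ValueError, match="treatment"):
            JointLatentNormalModel(bad)

    def test_fully_missing_outcome_rejected(self, small_complete):
        bad = small_complete.copy()
        bad["y_bin"] = np.nan
        with pytest.raises(ValueError, match="binary"):
            JointLatentNormalModel(bad)

    def test_iteration_budget_validated(self):
        with pytest.raises(ValueError):
            MCMCConfig(100, 200)


class TestRecovery:
    def test_continuous_margin_matches_mixed_model_oracle(self, small_complete, small_fit):
        """Posterior mean of the continuous-margin coefficients agrees with
        an independent likelihood fit (statsmodels MixedLM) within
        Monte-Carlo error."""
        sm = pytest.importorskip("statsmodels.formula.api")
        oracle = sm.mixedlm(
            "y_cont ~ treatment + x1 + x2 + x3 + x4",
            small_complete,
            groups=small_complete["study_id"],
        ).fit(reml=True)
        post = small_fit.summary()
        for name, sm_name in [("b1_treat", "treatment"), ("b1_x1", "x1"), ("b1_x2", "x2")]:
            diff = abs(post.loc[name, "mean"] - oracle.params[sm_name])
            assert diff < 2.0 * post.loc[name, "sd"]

    def test_null_correlation_recovered(self):
        tab = draw_complete_ipd(
            ScenarioConfig(8, 150, 0.0, 0.1, seed=55), DGPParams(rho=0.0)
        )
        res = JointLatentNormalModel(tab).fit(MCMCConfig(1200, 400, 1, 1, seed=3))
        rho = res.pooled("rho")
        assert abs(rho.mean()) < 3.0 * rho.std()

    def test_treatment_effects_recovered_on_paper_cell(self):
        tab = draw_complete_ipd(ScenarioConfig(20, 150, 0.2, 0.1, seed=91))
        res = JointLatentNormalModel(tab).fit(MCMCConfig(2500, 1000, 1, 1, seed=4))
        s = res.summary()
        assert abs(s.loc["b1_treat", "mean"] - 1.0) < 3 * s.loc["b1_treat", "sd"]
        assert abs(s.loc["b2_treat", "mean"] - 0.06) < 3 * s.loc["b2_treat", "sd"]

    def test_sampler_handles_sporadic_and_systematic_gaps(self, small_complete):
        """Missing entries (including a whole study without the binary
        outcome) are sampled internally and the fit still recovers."""
        tab = small_complete.copy()
        rng = np.random.default_rng(8)
        tab.loc[rng.random(len(tab)) < 0.2, "y_cont"] = np.nan
        tab.loc[tab.study_id == 3, "y_bin"] = np.nan
        res = JointLatentNormalModel(tab).fit(MCMCConfig(1200, 500, 1, 1, seed=5))
        assert abs(res.theta_hat[0] - 1.0) < 0.3


class TestGelmanRubin:
    def test_identical_chains_give_unit_psrf(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        psrf = gelman_rubin(np.stack([x, x]))
        assert psrf < 1.01

    def test_well_mixed_independent_chains_below_threshold(self):
        """Chains drawn from the same normal by an independent generator."""
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 5000))
        assert gelman_rubin(chains) < 1.1

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 2.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.random.default_rng(3).standard_normal((1, 100)))

    def test_agrees_with_arviz_reference(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        chains = np.cumsum(rng.standard_normal((2, 400)), axis=1) * 0.05
        chains += rng.standard_normal((2, 400))
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        assert abs(ours - theirs) < 0.05

    def test_results_object_reports_psrf_per_parameter(self, small_fit):
        psrf = small_fit.gelman_rubin()
        assert set(psrf.index) >= {"b1_treat", "b2_treat", "rho", "phi"}
        assert (psrf < 1.3).all()


class TestJointRegion:
    def test_truth_at_posterior_mean_always_contained(self, small_fit):
        m = small_fit.treatment_draws.mean(axis=0)
        assert small_fit.joint_region_contains(m, level=0.5)

    def test_distant_truth_not_contained(self, small_fit):
        sd = small_fit.treatment_draws.std(axis=0)
        far = small_fit.theta_hat + 10 * sd
        assert not small_fit.joint_region_contains(far, level=0.95)

    def test_containment_frequency_calibrated(self):
        """Posterior draws around a centre that is itself normally
        distributed about truth (matching covariance): containment frequency
        over repeated experiments approximates the level."""
        rng = np.random.default_rng(6)
        level, n_rep = 0.9, 2000
        hits = 0
        truth = np.array([1.0, 0.06])
        A = np.array([[0.5, 0.0], [0.3, 0.2]])
        for _ in range(n_rep):
            centre = truth + A @ rng.standard_normal(2)  # estimation error
            draws = centre + rng.standard_normal((400, 2)) @ A.T
            hits += joint_region_contains(draws, truth, level)
        freq = hits / n_rep
        assert abs(freq - level) < 3.5 * np.sqrt(level * (1 - level) / n_rep)

    def test_degenerate_covariance_rejected(self):
        draws = np.ones((100, 2))
        with pytest.raises(ValueError):
            joint_region_contains(draws, [1.0, 1.0], 0.95)

    def test_chain_order_exchangeability(self, small_fit):
        permuted = JointModelResults(
            small_fit._draws[::-1].copy(), PARAM_NAMES, small_fit.mcmc
        )
        assert np.allclose(permuted.theta_hat, small_fit.theta_hat)
        assert np.allclose(permuted.cov_theta, small_fit.cov_theta)
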