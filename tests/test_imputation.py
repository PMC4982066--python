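"""Chained-equations imputation: immutability, stationarity, systematic gaps."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import ks_2samp

from ipdmix import (
    DGPParams,
    FCSImputer,
    ImputationConfig,
    ImputedSet,
    ScenarioConfig,
    draw_complete_ipd,
    run_chained_equations,
)
from ipdmix.data import design_matrix
from ipdmix.imputation import impute_continuous_step


@pytest.fixture(scope="module")
def incomplete_table():
    tab = draw_complete_ipd(ScenarioConfig(10, 100, 0.2, 0.1, seed=61))
    rng = np.random.default_rng(62)
    tab.loc[rng.random(len(tab)) < 0.25, "y_cont"] = np.nan
    tab.loc[rng.random(len(tab)) < 0.25, "y_bin"] = np.nan
    # keep rows with both missing out of the picture for clarity? no --
    # sporadic double gaps are legitimate and must be handled
    return tab


def test_complete_input_returns_identical_copies(small_complete):
    imp = run_chained_equations(small_complete, ImputationConfig(m=3, n_cycles=2, seed=1))
    assert imp.m == 3
    for tab in imp.tables:
        assert tab["y_cont"].equals(small_complete["y_cont"])
        assert tab["y_bin"].equals(small_complete["y_bin"])


def test_observed_entries_immutable_and_gaps_filled(incomplete_table):
    imp = run_chained_equations(incomplete_table, ImputationConfig(m=4, n_cycles=3, seed=2))
    obs_c = incomplete_table["y_cont"].notna()
    obs_b = incomplete_table["y_bin"].notna()
    for tab in imp.tables:
        assert tab[["y_cont", "y_bin"]].notna().all().all()
        # bit-identical observed entries in every completed table
        assert np.array_equal(
            tab.loc[obs_c, "y_cont"].to_numpy(),
            incomplete_table.loc[obs_c, "y_cont"].to_numpy(),
        )
        assert np.array_equal(
            tab.loc[obs_b, "y_bin"].to_numpy(),
            incomplete_table.loc[obs_b, "y_bin"].to_numpy(),
        )
        assert np.isin(tab["y_bin"].to_numpy(), [0.0, 1.0]).all()


def test_imputations_vary_between_copies(incomplete_table):
    imp = run_chained_equations(incomplete_table, ImputationConfig(m=3, n_cycles=3, seed=3))
    mis = incomplete_table["y_cont"].isna()
    a = imp.tables[0].loc[mis, "y_cont"].to_numpy()
    b = imp.tables[1].loc[mis, "y_cont"].to_numpy()
    assert not np.allclose(a, b)


def test_deterministic_under_fixed_seed(incomplete_table):
    cfg = ImputationConfig(m=2, n_cycles=2, seed=9)
    a = run_chained_equations(incomplete_table, cfg)
    b = run_chained_equations(incomplete_table, cfg)
    for ta, tb in zip(a.tables, b.tables):
        assert ta["y_cont"].equals(tb["y_cont"])
        assert ta["y_bin"].equals(tb["y_bin"])


def test_single_level_step_matches_conjugate_predictive_oracle():
    """One study, no random intercept: the chained sampler's stationary
    imputation distribution equals the Bayesian linear-regression posterior
    predictive (conjugate normal-inverse-chi-square), checked by a
    two-sample KS test at alpha = 0.01."""
    rng = np.random.default_rng(71)
    n, p_miss = 150, 40
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    beta_true = np.array([1.0, 0.7, -0.4])
    y = X @ beta_true + 0.8 * rng.standard_normal(n)
    obs = np.ones(n, dtype=bool)
    obs[:p_miss] = False
    g = np.zeros(n, dtype=np.int64)

    # chained draws: persistent state, one target cell tracked
    state = None
    chain_draws = []
    step_rng = np.random.default_rng(72)
    for _ in range(3000):
        filled, state = impute_continuous_step(
            y.copy(), X, g, 1, obs, step_rng, state=state, single_level=True
        )
        chain_draws.append(filled[0])

    # conjugate oracle: sigma2 ~ Inv-chi2(n_obs - p, s2), beta | sigma2 normal
    orng = np.random.default_rng(73)
    Xo, yo = X[obs], y[obs]
    XtX = Xo.T @ Xo
    bhat = np.linalg.solve(XtX, Xo.T @ yo)
    resid = yo - Xo @ bhat
    n_obs, k = Xo.shape
    s2 = resid @ resid
    L = np.linalg.cholesky(np.linalg.inv(XtX))
    oracle = []
    for _ in range(3000):
        sig2 = s2 / orng.chisquare(n_obs - k)
        beta = bhat + np.sqrt(sig2) * (L @ orng.standard_normal(k))
        oracle.append(X[0] @ beta + np.sqrt(sig2) * orng.standard_normal())
    stat = ks_2samp(np.array(chain_draws[200:]), np.array(oracle))
    assert stat.pvalue > 0.01


def test_systematically_missing_studies_imputed_near_marginal_prevalence():
    """Four of twenty studies lose y_bin entirely; imputed prevalence in
    those studies approximates the generating marginal prevalence computed
    by an independent Monte-Carlo oracle."""
    tab = draw_complete_ipd(ScenarioConfig(20, 150, 0.2, 0.1, seed=81))
    lost = [0, 5, 11, 17]
    tab.loc[tab.study_id.isin(lost), "y_bin"] = np.nan
    imp = run_chained_equations(tab, ImputationConfig(m=5, n_cycles=5, variant="fcs1", seed=82))
    orng = np.random.default_rng(83)
    n_o = 500_000
    eta = (
        -0.5
        + 0.1 * orng.integers(0, 2, n_o)
        + 0.2 * orng.standard_normal(n_o)
        + 0.2 * orng.standard_normal(n_o)
        + orng.standard_normal(n_o)
    )
    oracle_prev = expit(eta).mean()
    mask = tab.study_id.isin(lost)
    prev = np.mean([t.loc[mask, "y_bin"].mean() for t in imp.tables])
    # tolerance dominated by tau2 uncertainty for four unseen intercepts
    assert abs(prev - oracle_prev) < 0.1


def test_fcs2_learns_positive_outcome_association_when_rho_high():
    tab = draw_complete_ipd(
        ScenarioConfig(10, 150, 0.7, 0.1, seed=84), DGPParams(rho=0.7)
    )
    rng = np.random.default_rng(85)
    tab.loc[rng.random(len(tab)) < 0.3, "y_cont"] = np.nan
    imp = run_chained_equations(tab, ImputationConfig(m=4, n_cycles=6, variant="fcs2", seed=86))
    # alpha2: coefficient of y_cont in the binary imputation model
    late = imp.alpha2[:, 2:]
    assert late.mean() > 2 * late.std() / np.sqrt(late.size)


def test_round_trip_persistence(tmp_path, incomplete_table):
    imp = run_chained_equations(incomplete_table, ImputationConfig(m=2, n_cycles=2, seed=4))
    imp.save(tmp_path / "imp")
    back = ImputedSet.load(tmp_path / "imp")
    assert back.m == 2
    assert np.allclose(back.alpha2, imp.alpha2)
    assert np.allclose(
        back.tables[1]["y_cont"].to_numpy(), imp.tables[1]["y_cont"].to_numpy()
    )


def test_error_cases(small_complete):
    bad = small_complete.copy()
    bad["y_cont"] = np.nan
    with pytest.raises(ValueError):
        FCSImputer(bad)
    with pytest.raises(ValueError):
        ImputationConfig(m=0)
    with pytest.raises(ValueError):
        ImputationConfig(variant="joint")
    # collinear predictor named in the error
    dup = small_complete.copy()
    dup["x2"] = dup["x1"]
    dup.loc[0, "y_cont"] = np.nan
    with pytest.raises(ValueError, match="x2"):
        run_chained_equations(dup, ImputationConfig(m=1, n_cycles=1, seed=5))
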