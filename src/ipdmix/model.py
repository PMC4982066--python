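"""Latent-normal joint hierarchical model for a continuous and a binary outcome.

The model couples a linear mixed margin for the continuous outcome with a
probit mixed margin for the binary outcome through correlated
individual-level residuals and correlated study-level random intercepts:

    y1_ij = b1'x_ij + u1_j + e1_ij
    z_ij  = b2'x_ij + u2_j + e2_ij,     y2_ij = 1{z_ij > 0}
    (e1, e2)_ij ~ N(0, Omega_e),  Omega_e = [[sigma1^2, rho*sigma1], [., 1]]
    (u1, u2)_j  ~ N(0, Omega_u),  Omega_u = [[tau1^2, phi*tau1*tau2], [., tau2^2]]

The residual variance of the probit margin is fixed to 1 for identification.
Missing outcome entries are treated as unknowns and sampled inside the Gibbs
sweep, so a single fit handles complete data, sporadically missing outcomes
and studies in which the binary outcome was never collected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _gibbs
from .data import design_matrix, study_index, validate_ipd
from .results import PARAM_NAMES, JointModelResults

__all__ = ["PriorSpec", "MCMCConfig", "JointLatentNormalModel", "fit_joint"]


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the joint model; defaults are vague/weakly informative.

    Coefficients get independent N(0, coef_sd^2) priors.  Both covariance
    matrices get inverse-Wishart priors (the residual one on the expanded,
    unconstrained scale used by the parameter-expansion step), which keeps
    every update conjugate.
    """

    coef_sd: float = 10.0
    nu_u: float = 3.0
    scale_u: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    nu_e: float = 3.0
    scale_e: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))

    def __post_init__(self):
        if self.coef_sd <= 0 or self.nu_u <= 1 or self.nu_e <= 1:
            raise ValueError("priors must be proper: coef_sd > 0 and IW dof > 1")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  ``reduced()`` is the desk-scale default (5000
    iterations, half burn-in); ``paper_mode()`` runs 50 000 iterations."""

    n_iter: int = 5000
    n_burn: int = 2500
    n_chains: int = 2
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < self.n_burn:
            raise ValueError("n_iter must be >= n_burn")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")

    @classmethod
    def reduced(cls, seed: int = 0, n_chains: int = 2) -> "MCMCConfig":
        return cls(5000, 2500, n_chains, 1, seed)

    @classmethod
    def paper_mode(cls, seed: int = 0) -> "MCMCConfig":
        return cls(50_000, 25_000, 2, 10, seed)

    def to_dict(self) -> dict:
        return dict(
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            n_chains=self.n_chains,
            thin=self.thin,
            seed=self.seed,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "MCMCConfig":
        return cls(**d)


class JointLatentNormalModel:
    """Full-Bayes joint model built from a long-format IPD table.

    Parameters
    ----------
    data : pandas.DataFrame
        IPD table (see :mod:`ipdmix.data`); outcome entries may be NaN.
    priors : PriorSpec, optional

    Examples
    --------
    >>> model = JointLatentNormalModel(table)
    >>> res = model.fit(MCMCConfig(seed=1))
    >>> res.summary()
    """

    def __init__(self, data: pd.DataFrame, priors: PriorSpec | None = None):
        data = validate_ipd(data)
        self.data = data
        self.priors = priors or PriorSpec()

        self._X = design_matrix(data)
        self._g, self._study_ids = study_index(data)
        self.n_studies = len(self._study_ids)
        if self.n_studies < 2:
            raise ValueError("joint model needs at least 2 studies to identify "
                             "the random-intercept covariance")
        t = self._X[:, 1]
        if np.all(t == t[0]):
            raise ValueError("treatment indicator is constant; effect unidentifiable")

        y1 = data["y_cont"].to_numpy(dtype=float)
        y2 = data["y_bin"].to_numpy(dtype=float)
        self._miss1 = np.isnan(y1)
        self._miss2 = np.isnan(y2)
        if self._miss1.all():
            raise ValueError("continuous outcome has no observed values")
        if self._miss2.all():
            raise ValueError("binary outcome has no observed values")
        self._y1 = np.where(self._miss1, 0.0, y1)
        self._y2 = np.where(self._miss2, 0.0, y2)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, priors: PriorSpec | None = None):
        return cls(data, priors)

    def fit(self, mcmc: MCMCConfig | None = None, seed: int | None = None) -> JointModelResults:
        """Run the Gibbs sampler and return the posterior draws."""
        mcmc = mcmc or MCMCConfig()
        if seed is not None:
            mcmc = MCMCConfig(mcmc.n_iter, mcmc.n_burn, mcmc.n_chains, mcmc.thin, seed)
        pr = self.priors
        ss = np.random.SeedSequence(mcmc.seed)
        chain_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(mcmc.n_chains)]
        chains = []
        for cs in chain_seeds:
            draws = _gibbs.gibbs_chain(
                self._X,
                self._y1,
                self._y2,
                self._miss1,
                self._miss2,
                self._g,
                self.n_studies,
                mcmc.n_iter,
                mcmc.n_burn,
                mcmc.thin,
                1.0 / pr.coef_sd**2,
                pr.nu_u,
                np.asarray(pr.scale_u, dtype=float),
                pr.nu_e,
                np.asarray(pr.scale_e, dtype=float),
                cs,
            )
            if not np.isfinite(draws).all():
                raise RuntimeError("sampler produced non-finite draws")
            chains.append(draws)
        draws = np.stack(chains)  # (n_chains, n_keep, n_cols)
        return JointModelResults(draws, PARAM_NAMES, mcmc, self)


def fit_joint(
    data: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> JointModelResults:
    """Functional wrapper: build the model and fit in one call."""
    return JointLatentNormalModel(data, priors).fit(mcmc)
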