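"""Posterior-draw containers, convergence diagnostics and joint regions."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = ["JointModelResults", "gelman_rubin", "joint_region_contains", "PARAM_NAMES"]

PARAM_NAMES = [
    "b1_const", "b1_treat", "b1_x1", "b1_x2", "b1_x3", "b1_x4",
    "b2_const", "b2_treat", "b2_x1", "b2_x2", "b2_x3", "b2_x4",
    "sigma1_sq", "sigma2_sq", "rho", "tau1_sq", "tau2_sq", "phi",
    "z_sign_frac",
]

#: parameters with non-degenerate posteriors (sigma2_sq is fixed at 1 and
#: z_sign_frac is a bookkeeping diagnostic)
MONITORED = [p for p in PARAM_NAMES if p not in ("sigma2_sq", "z_sign_frac")]


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half,
    so the statistic is sensitive to trends within a chain as well as to
    disagreement between chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of draws")
    m, n = chains.shape
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0  # constant chains agree trivially
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def joint_region_contains(draws: np.ndarray, truth, level: float = 0.95) -> bool:
    """Elliptical empirical credible region membership test.

    ``draws`` is an (N, k) matrix of pooled posterior draws.  The region is
    {t : (t - m)' S^-1 (t - m) <= chi2_k(level)} with m, S the posterior
    mean and covariance -- the normal-approximation contour of the joint
    posterior.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    truth = np.asarray(truth, dtype=float)
    k = draws.shape[1]
    m = draws.mean(axis=0)
    S = np.cov(draws, rowvar=False)
    S = np.atleast_2d(S)
    if np.linalg.det(S) <= 0 or not np.isfinite(S).all():
        raise ValueError("degenerate posterior covariance")
    d = truth - m
    maha = float(d @ np.linalg.solve(S, d))
    return maha <= chi2.ppf(level, df=k)


class JointModelResults:
    """Posterior draws from :class:`~ipdmix.model.JointLatentNormalModel`.

    Draws are stored as an (n_chains, n_draws, n_params) array; pooled and
    per-chain views, Rubin-style summaries and joint credible regions are
    derived on demand.
    """

    def __init__(self, draws: np.ndarray, names: list[str], mcmc, model=None):
        self._draws = draws
        self.names = list(names)
        self.mcmc = mcmc
        self.model = model
        self._index = {nm: i for i, nm in enumerate(self.names)}

    # ---- access ---------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self._draws.shape[0]

    @property
    def n_draws(self) -> int:
        """Retained draws per chain."""
        return self._draws.shape[1]

    def chains(self, name: str) -> np.ndarray:
        """Per-chain draws for one parameter, shape (n_chains, n_draws)."""
        return self._draws[:, :, self._index[name]]

    def pooled(self, name: str) -> np.ndarray:
        return self.chains(name).reshape(-1)

    @property
    def treatment_draws(self) -> np.ndarray:
        """Pooled (N, 2) draws of the treatment effects (b1_treat, b2_treat)."""
        return np.column_stack([self.pooled("b1_treat"), self.pooled("b2_treat")])

    @property
    def theta_hat(self) -> np.ndarray:
        return self.treatment_draws.mean(axis=0)

    @property
    def cov_theta(self) -> np.ndarray:
        return np.cov(self.treatment_draws, rowvar=False)

    # ---- diagnostics ----------------------------------------------------
    def gelman_rubin(self, params: list[str] | None = None) -> pd.Series:
        """Split-chain PSRF per monitored parameter (needs >= 2 chains)."""
        from .results import MONITORED  # self-import keeps list in one place

        params = params or MONITORED
        return pd.Series({p: gelman_rubin(self.chains(p)) for p in params}, name="psrf")

    def converged(self, threshold: float = 1.1) -> bool:
        return bool((self.gelman_rubin() < threshold).all())

    def joint_region_contains(self, truth, level: float = 0.95) -> bool:
        """Whether the level-% joint credible ellipse for the two treatment
        effects contains ``truth``."""
        return joint_region_contains(self.treatment_draws, truth, level)

    # ---- summaries ------------------------------------------------------
    def summary(self, params: list[str] | None = None) -> pd.DataFrame:
        from .results import MONITORED

        params = params or MONITORED
        rows = {}
        for pnm in params:
            x = self.pooled(pnm)
            row = {
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "q2.5": np.quantile(x, 0.025),
                "q97.5": np.quantile(x, 0.975),
            }
            if self.n_chains >= 2:
                row["psrf"] = gelman_rubin(self.chains(pnm))
            rows[pnm] = row
        return pd.DataFrame(rows).T

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (chain, draw, one column per parameter)."""
        n_c, n_d, _ = self._draws.shape
        out = pd.DataFrame(
            self._draws.reshape(n_c * n_d, -1), columns=self.names
        )
        out.insert(0, "draw", np.tile(np.arange(n_d), n_c))
        out.insert(0, "chain", np.repeat(np.arange(n_c), n_d))
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
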