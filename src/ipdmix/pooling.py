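"""Substantive-model fits, complete-case filtering and Rubin's rules.

The substantive (analysis) model is the bivariate linear/probit
random-intercept model; it is fitted by the same Gibbs sampler as the joint
missing-data model, with the posterior mean serving as the point estimate
and the posterior covariance as its sampling covariance.  Multiply-imputed
estimates are combined with Rubin's rules and tested against elliptical
simultaneous confidence regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist

from .data import is_complete, observed_mask, validate_ipd
from .model import JointLatentNormalModel, MCMCConfig, PriorSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SubstantiveEstimate",
    "PooledEstimate",
    "fit_substantive",
    "complete_case_filter",
    "rubin_pool",
    "simultaneous_region_contains",
]


@dataclass
class SubstantiveEstimate:
    """Treatment-effect estimate (continuous, probit-scale binary) with
    covariance and convergence diagnostics."""

    theta: np.ndarray  # shape (2,)
    cov: np.ndarray  # shape (2, 2)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta.tolist(),
                "cov": self.cov.tolist(),
                "diagnostics": self.diagnostics,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SubstantiveEstimate":
        d = json.loads(s)
        return cls(np.asarray(d["theta"]), np.asarray(d["cov"]), d.get("diagnostics", {}))


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of M estimates of the treatment-effect pair."""

    theta_bar: np.ndarray
    W_bar: np.ndarray  # mean within-imputation covariance
    B: np.ndarray  # between-imputation covariance
    m: int

    @property
    def T_total(self) -> np.ndarray:
        return self.W_bar + (1.0 + 1.0 / self.m) * self.B


def fit_substantive(
    table: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
) -> SubstantiveEstimate:
    """Fit the bivariate random-intercept substantive model to complete data."""
    table = validate_ipd(table)
    if not is_complete(table):
        raise ValueError(
            "substantive model requires complete outcomes; impute or filter first"
        )
    model = JointLatentNormalModel(table, priors)
    res = model.fit(mcmc)
    diag: dict = {"n_chains": res.n_chains, "n_draws": res.n_draws}
    if res.n_chains >= 2:
        psrf = res.gelman_rubin()
        diag["max_psrf"] = float(psrf.max())
        diag["converged"] = bool(psrf.max() < 1.1)
    return SubstantiveEstimate(res.theta_hat, res.cov_theta, diag)


def complete_case_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows with both outcomes observed; drop emptied studies.

    Complete-case analysis discards whole studies when an outcome is
    systematically missing; the number of dropped studies is logged.
    """
    table = validate_ipd(table)
    keep = observed_mask(table, "y_cont") & observed_mask(table, "y_bin")
    out = table.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("complete-case filter removed every row")
    lost = set(table["study_id"].unique()) - set(out["study_id"].unique())
    if lost:
        logger.info(
            "complete-case filter dropped %d studies entirely: %s",
            len(lost),
            sorted(lost),
        )
    return out


def rubin_pool(estimates: list[SubstantiveEstimate]) -> PooledEstimate:
    """Combine M >= 2 estimates: mean, within, between and total covariance."""
    m = len(estimates)
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    thetas = np.stack([e.theta for e in estimates])
    covs = np.stack([e.cov for e in estimates])
    theta_bar = thetas.mean(axis=0)
    W_bar = covs.mean(axis=0)
    B = np.cov(thetas, rowvar=False, ddof=1)
    return PooledEstimate(theta_bar, W_bar, np.atleast_2d(B), m)


def simultaneous_region_contains(
    pooled: PooledEstimate,
    truth,
    level: float = 0.95,
    small_sample: bool = False,
) -> bool:
    """Whether the simultaneous level-% confidence ellipse contains truth.

    The default reference distribution is chi-square with k degrees of
    freedom on the Wald statistic formed with the total covariance T.  With
    ``small_sample=True`` the statistic is compared against a scaled F
    quantile with the Li-Raghunathan-Rubin degrees of freedom, which widens
    the region when the number of imputations is small relative to the
    fraction of missing information.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    truth = np.asarray(truth, dtype=float)
    k = truth.shape[0]
    T = pooled.T_total
    if not np.isfinite(T).all() or np.linalg.det(T) <= 0:
        raise ValueError("singular total covariance")
    d = truth - pooled.theta_bar
    stat = float(d @ np.linalg.solve(T, d))
    if not small_sample:
        return stat <= chi2.ppf(level, df=k)
    # average relative increase in variance and its F reference
    r = (1.0 + 1.0 / pooled.m) * float(
        np.trace(np.linalg.solve(pooled.W_bar, pooled.B))
    ) / k
    nu = k * (pooled.m - 1) * (1.0 + 1.0 / max(r, 1e-12)) ** 2
    return stat / k <= f_dist.ppf(level, k, nu)
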