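"""Gaussian-copula data generator for two-level IPD with mixed outcomes.

Generates complete individual-participant data for a meta-analysis of a
continuous and a binary outcome, then imposes missing-at-random (MAR)
missingness.  The complete-data model per individual i in study j is

    y_cont ~ N(mu1, sigma1^2),   mu1 = b10 + b11*t + b12*x1 + b13*x2 + u1j
    y_bin  ~ Bernoulli(pi),      logit(pi) = b20 + b21*t + b22*x3 + b23*x4 + u2j
    (u1j, u2j) ~ N(0, [[tau1^2, phi*tau1*tau2], [., tau2^2]])

with the two outcomes linked through a Gaussian copula: a bivariate standard
normal pair (v1, v2) with correlation rho is mapped through the normal CDF to
uniforms; the first coordinate drives the normal outcome (y_cont = mu1 +
sigma1*v1) and the second the Bernoulli one (y_bin = 1 iff Phi(v2) > 1 - pi,
so that larger latent values map to 1 and rho's sign matches the sign of the
outcome association).

Missingness mechanisms (all MAR by construction):

* ``covariate_only`` -- each outcome k goes missing independently with
  probability expit(theta_k0 + theta_k1 * x_k), where x_k is the first
  covariate of that outcome's own linear predictor (x1 for the continuous,
  x3 for the binary outcome).
* ``outcome_dependent`` -- the table is randomly split in half; in one half
  only the continuous outcome can be missing, with probability depending on
  x1 and the (observed) binary outcome; in the other half only the binary
  outcome can be missing, depending on x3 and the observed continuous
  outcome.  Each row can therefore lose at most one outcome and the
  probability of missingness only ever involves values that stay observed.
* ``systematic_binary`` -- sporadic 20% covariate-only missingness on the
  continuous outcome, plus the binary outcome set fully missing in a number
  of randomly chosen studies.

The theta coefficients are not fixed constants of the design: they are
calibrated numerically (on a large simulated sample with a fixed internal
seed) so that the marginal missingness rate and the correlation between the
missingness indicator and its predictors hit requested targets (0.3 for the
correlation in the reproduction scenarios).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .data import IPD_COLUMNS, validate_ipd

__all__ = [
    "DGPParams",
    "MissingnessParams",
    "ScenarioConfig",
    "PAPER_GRID",
    "draw_complete_ipd",
    "calibrate_theta",
    "impose_sporadic_mar",
    "impose_systematic",
    "impose_missingness",
]


@dataclass(frozen=True)
class DGPParams:
    """Parameters of the complete-data generating process.

    Defaults are the reproduction values: unit residual and random-intercept
    variances, treatment effects of 1 (continuous) and 0.1 on the logit scale
    (binary, i.e. 0.06 on the probit scale).
    """

    beta_cont: tuple[float, ...] = (1.0, 1.0, 0.5, 0.5)
    beta_bin: tuple[float, ...] = (-0.5, 0.1, 0.2, 0.2)
    sigma1_sq: float = 1.0
    rho: float = 0.2
    phi: float = 0.1
    tau_sq: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if not abs(self.phi) < 1:
            raise ValueError(f"|phi| must be < 1, got {self.phi}")
        if self.sigma1_sq <= 0:
            raise ValueError("sigma1_sq must be positive")
        if min(self.tau_sq) <= 0:
            raise ValueError("tau_sq components must be positive")


@dataclass(frozen=True)
class MissingnessParams:
    """Calibrated missingness-model coefficients for both outcomes.

    ``theta`` has one row per outcome (continuous first), columns
    (intercept, covariate coefficient, other-outcome coefficient).
    """

    mechanism: str  # covariate_only | outcome_dependent | systematic_binary
    target_rate: float
    theta: tuple[tuple[float, float, float], tuple[float, float, float]]
    n_systematic_studies: int = 0

    _MECHANISMS = ("covariate_only", "outcome_dependent", "systematic_binary")

    def __post_init__(self):
        if self.mechanism not in self._MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0 < self.target_rate < 1:
            raise ValueError("target_rate must lie in (0, 1)")
        if self.mechanism == "covariate_only":
            if any(row[2] != 0.0 for row in self.theta):
                raise ValueError("covariate_only requires theta2 == 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid."""

    n_studies: int
    n_per_study: int
    rho: float
    phi: float
    missingness: MissingnessParams | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1 or self.n_per_study < 1:
            raise ValueError("study count and size must be positive")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if not abs(self.phi) < 1:
            raise ValueError(f"|phi| must be < 1, got {self.phi}")


#: The reproduction grid: {(20,150),(5,600)} x rho x phi x missingness rate.
PAPER_GRID = [
    dict(n_studies=ns, n_per_study=nps, rho=r, phi=p, rate=m)
    for (ns, nps) in [(20, 150), (5, 600)]
    for r in (0.2, 0.7)
    for p in (0.1, 0.3)
    for m in (0.2, 0.5)
]


def _scenario_params(config: ScenarioConfig, params: DGPParams) -> DGPParams:
    return replace(params, rho=config.rho, phi=config.phi)


def draw_complete_ipd(
    config: ScenarioConfig, params: DGPParams = DGPParams(), seed: int | None = None
) -> pd.DataFrame:
    """Draw a complete (no missing entries) IPD table for one scenario.

    Treatment is assigned by permuted blocks within study, so the 1:1
    allocation is exact whenever the study size is even.
    """
    params = _scenario_params(config, params)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    J, nj = config.n_studies, config.n_per_study
    n = J * nj

    tau1, tau2 = np.sqrt(params.tau_sq)
    cov_u = np.array(
        [
            [tau1**2, params.phi * tau1 * tau2],
            [params.phi * tau1 * tau2, tau2**2],
        ]
    )
    u = rng.multivariate_normal(np.zeros(2), cov_u, size=J, method="cholesky")

    g = np.repeat(np.arange(J), nj)
    X = rng.standard_normal((n, 4))

    block = np.zeros(nj)
    block[: nj // 2] = 1.0
    t = np.empty(n)
    for j in range(J):
        t[j * nj : (j + 1) * nj] = rng.permutation(block)

    b1 = np.asarray(params.beta_cont)
    b2 = np.asarray(params.beta_bin)
    mu1 = b1[0] + b1[1] * t + b1[2] * X[:, 0] + b1[3] * X[:, 1] + u[g, 0]
    eta2 = b2[0] + b2[1] * t + b2[2] * X[:, 2] + b2[3] * X[:, 3] + u[g, 1]
    pi = expit(eta2)

    # Gaussian copula: correlated standard-normal pair -> uniforms -> marginals
    v1 = rng.standard_normal(n)
    v2 = params.rho * v1 + np.sqrt(1 - params.rho**2) * rng.standard_normal(n)
    y_cont = mu1 + np.sqrt(params.sigma1_sq) * v1
    # y_bin = 1 iff w2 = Phi(v2) > 1 - pi, i.e. v2 > Phi^-1(1 - pi)
    y_bin = (v2 > ndtri(1.0 - pi)).astype(float)

    df = pd.DataFrame(
        {
            "study_id": g,
            "treatment": t.astype(int),
            "x1": X[:, 0],
            "x2": X[:, 1],
            "x3": X[:, 2],
            "x4": X[:, 3],
            "y_cont": y_cont,
            "y_bin": y_bin,
        },
        columns=IPD_COLUMNS,
    )
    return validate_ipd(df)


# --------------------------------------------------------------------------
# theta calibration
# --------------------------------------------------------------------------

_CAL_N = 1_000_000
_CAL_SEED = 20160418  # fixed oracle seed for the calibration sample


def _rate_corr(theta0, theta1, x, theta2=0.0, w=None):
    """Expected missingness rate and corr(R, x) on a simulated sample.

    Uses the expectation of the Bernoulli indicator given the sample
    (smooth in theta), which makes root-finding deterministic.
    """
    eta = theta0 + theta1 * x
    if w is not None:
        eta = eta + theta2 * w
    p = expit(eta)
    m = p.mean()
    # Cov(R, x) = E[x p(x)] - E[x] m ; Var(R) = m(1-m)
    c = (x * p).mean() - x.mean() * m
    denom = np.sqrt(max(m * (1 - m), 1e-12)) * x.std()
    return m, c / denom


def _solve_rate(theta1, x, rate, theta2=0.0, w=None):
    return brentq(
        lambda t0: _rate_corr(t0, theta1, x, theta2, w)[0] - rate, -30.0, 30.0, xtol=1e-10
    )


def _solve_pair(x, rate, corr, theta2=0.0, w=None):
    """Find (theta0, theta1) matching the rate and corr(R, x) targets."""
    if abs(corr) < 1e-12:
        return _solve_rate(0.0, x, rate, theta2, w), 0.0

    def f(t1):
        t0 = _solve_rate(t1, x, rate, theta2, w)
        return _rate_corr(t0, t1, x, theta2, w)[1] - corr

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 64:
            raise RuntimeError(
                f"correlation target {corr} unreachable for rate {rate}"
            )
    t1 = brentq(f, 1e-8, hi, xtol=1e-8)
    return _solve_rate(t1, x, rate, theta2, w), t1


def calibrate_theta(
    target_rate: float,
    target_corr: float,
    params: DGPParams = DGPParams(),
    mechanism: str = "covariate_only",
    *,
    n_studies: int = 20,
    rho: float | None = None,
    phi: float | None = None,
    n_cal: int = _CAL_N,
    max_passes: int = 8,
) -> MissingnessParams:
    """Calibrate the missingness-model coefficients for one scenario.

    Finds theta such that, on a large simulated sample (fixed internal seed),
    the marginal missingness proportion matches ``target_rate`` (within
    +-0.01) and corr(R_k, x_k) matches ``target_corr`` (within +-0.03).  For
    the outcome-dependent mechanism the other-outcome coefficient theta2 is
    additionally calibrated so that corr(R_k, y_other) ~ ``target_corr``,
    and the rate target applies within the half-sample in which the outcome
    is eligible to be missing (each participant can lose at most one
    outcome, so this is also the proportion of incomplete participants).
    For the systematic mechanism the binary outcome is removed study-wise
    and only the continuous outcome's sporadic coefficients are calibrated
    (at a 20% rate).
    """
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must lie in (0, 1)")
    if rho is not None or phi is not None:
        params = replace(
            params,
            rho=params.rho if rho is None else rho,
            phi=params.phi if phi is None else phi,
        )

    rng = np.random.default_rng(_CAL_SEED)

    if mechanism == "covariate_only":
        x = rng.standard_normal(n_cal)
        t0, t1 = _solve_pair(x, target_rate, target_corr)
        theta = ((t0, t1, 0.0), (t0, t1, 0.0))
        return MissingnessParams(mechanism, target_rate, theta)

    if mechanism == "systematic_binary":
        x = rng.standard_normal(n_cal)
        t0, t1 = _solve_pair(x, 0.2, target_corr)
        n_sys = int(round(target_rate * n_studies))
        if n_sys >= n_studies:
            raise ValueError("at least one study must observe the binary outcome")
        theta = ((t0, t1, 0.0), (0.0, 0.0, 0.0))
        return MissingnessParams(mechanism, target_rate, theta, n_systematic_studies=n_sys)

    if mechanism != "outcome_dependent":
        raise ValueError(f"unknown mechanism {mechanism!r}")

    # Large complete draw from the DGP itself so that the other-outcome
    # distribution (which depends on rho, phi, tau) is faithful.
    n_per = max(n_cal // 200, 1)
    cfg = ScenarioConfig(200, n_per, params.rho, params.phi, seed=_CAL_SEED)
    big = draw_complete_ipd(cfg, params, seed=_CAL_SEED)
    rows = []
    for xk, wk in (("x1", "y_bin"), ("x3", "y_cont")):
        x = big[xk].to_numpy()
        w = big[wk].to_numpy()
        t2 = 0.0
        t0, t1 = _solve_pair(x, target_rate, target_corr)
        for _ in range(max_passes):
            # theta2 from the corr(R, y_other) target, holding (t0, t1)
            def fcorr(t2_):
                t0_ = _solve_rate(t1, x, target_rate, t2_, w)
                _, cw = _rate_corr(t0_, t2_, w, t1, x)  # corr with w, swap roles
                return cw - target_corr

            hi = 1.0
            while fcorr(hi) < 0:
                hi *= 2.0
                if hi > 64:
                    raise RuntimeError("theta2 target unreachable")
            t2_new = brentq(fcorr, 1e-8, hi, xtol=1e-8)
            t0_new, t1_new = _solve_pair(x, target_rate, target_corr, t2_new, w)
            if (
                abs(t2_new - t2) < 1e-6
                and abs(t1_new - t1) < 1e-6
                and abs(t0_new - t0) < 1e-6
            ):
                t0, t1, t2 = t0_new, t1_new, t2_new
                break
            t0, t1, t2 = t0_new, t1_new, t2_new
        rows.append((t0, t1, t2))
    return MissingnessParams("outcome_dependent", target_rate, (rows[0], rows[1]))


# --------------------------------------------------------------------------
# imposing missingness
# --------------------------------------------------------------------------


def impose_sporadic_mar(
    data: pd.DataFrame, mp: MissingnessParams, seed: int | None = None
) -> pd.DataFrame:
    """Impose sporadic MAR missingness on a complete table.

    ``covariate_only``: each outcome independently missing given its own
    covariate.  ``outcome_dependent``: split-sample construction -- the
    missingness probability of each entry depends only on quantities that
    remain observed in that row, so at most one outcome per row is removed.
    """
    if mp.mechanism == "systematic_binary":
        raise ValueError("systematic_binary must go through impose_systematic")
    if not (data[["y_cont", "y_bin"]].notna().all().all()):
        raise ValueError("input table must be complete")
    rng = np.random.default_rng(seed)
    out = data.copy()
    n = len(out)
    th_c, th_b = mp.theta

    if mp.mechanism == "covariate_only":
        p1 = expit(th_c[0] + th_c[1] * out["x1"].to_numpy())
        p2 = expit(th_b[0] + th_b[1] * out["x3"].to_numpy())
        r1 = rng.random(n) < p1
        r2 = rng.random(n) < p2
    else:  # outcome_dependent
        half_a = rng.random(n) < 0.5
        y_bin = out["y_bin"].to_numpy()
        y_cont = out["y_cont"].to_numpy()
        p1 = expit(th_c[0] + th_c[1] * out["x1"].to_numpy() + th_c[2] * y_bin)
        p2 = expit(th_b[0] + th_b[1] * out["x3"].to_numpy() + th_b[2] * y_cont)
        r1 = half_a & (rng.random(n) < p1)
        r2 = (~half_a) & (rng.random(n) < p2)

    out.loc[r1, "y_cont"] = np.nan
    out.loc[r2, "y_bin"] = np.nan
    return out


def impose_systematic(
    data: pd.DataFrame, mp: MissingnessParams, seed: int | None = None
) -> pd.DataFrame:
    """Sporadic MAR on the continuous outcome plus whole-study loss of y_bin."""
    if mp.mechanism != "systematic_binary":
        raise ValueError("impose_systematic requires mechanism='systematic_binary'")
    if not (data[["y_cont", "y_bin"]].notna().all().all()):
        raise ValueError("input table must be complete")
    studies = np.unique(data["study_id"].to_numpy())
    if mp.n_systematic_studies >= len(studies):
        raise ValueError("at least one study must observe the binary outcome")
    rng = np.random.default_rng(seed)
    out = data.copy()
    th_c = mp.theta[0]
    p1 = expit(th_c[0] + th_c[1] * out["x1"].to_numpy())
    r1 = rng.random(len(out)) < p1
    out.loc[r1, "y_cont"] = np.nan
    lost = rng.choice(studies, size=mp.n_systematic_studies, replace=False)
    out.loc[out["study_id"].isin(lost), "y_bin"] = np.nan
    return out


def impose_missingness(
    data: pd.DataFrame, mp: MissingnessParams, seed: int | None = None
) -> pd.DataFrame:
    """Dispatch to the sporadic or systematic routine by mechanism."""
    if mp.mechanism == "systematic_binary":
        return impose_systematic(data, mp, seed)
    return impose_sporadic_mar(data, mp, seed)
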