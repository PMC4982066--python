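"""Multilevel multiple imputation by chained equations for the two outcomes.

Two univariate random-intercept imputation models are iterated in turn
(continuous first, then binary), each fitted to the rows where its target is
currently observed and used to draw replacement values for the missing rows:

* continuous: y1 | . ~ N(x'a + alpha1*y2 + u_j, sigma^2), a linear mixed
  model updated by conjugate Gibbs draws (flat prior on coefficients,
  scale-invariant prior on sigma^2, weakly informative inverse-chi-square
  on the intercept variance tau^2);
* binary: y2 | . ~ Bernoulli(expit(x'a + alpha2*y1 + u_j)), a logistic
  mixed model approximated by a penalised-likelihood (Laplace) fit; the
  coefficient vector and study intercepts are drawn jointly from the
  normal approximation at the penalised mode.

Studies in which an outcome was never observed (systematically missing)
contribute no rows to that outcome's fit; their study intercept is drawn
from the estimated random-effect distribution N(0, tau^2), which is what
lets whole-study gaps borrow strength from the remaining studies.

Two variants mirror the two chained-equations strategies under comparison:
``fcs1`` excludes the other outcome from each imputation model, ``fcs2``
includes it.  The binary model is logistic even though the analysis model
is probit; this mild uncongeniality is deliberate and standard practice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import COVARIATES, validate_ipd, study_index

__all__ = ["ImputationConfig", "ImputedSet", "FCSImputer", "run_chained_equations"]

# weakly informative scaled-inverse-chi-square prior for tau^2, guarding the
# random-intercept variance against collapse when few studies are observed
_TAU_NU0 = 1.0
_TAU_S0 = 0.25


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equations settings (defaults: M=10 imputations, 10 cycles)."""

    m: int = 10
    n_cycles: int = 10
    variant: str = "fcs2"
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n_cycles < 1:
            raise ValueError("m and n_cycles must be >= 1")
        if self.variant not in ("fcs1", "fcs2"):
            raise ValueError("variant must be 'fcs1' or 'fcs2'")


@dataclass
class ImputedSet:
    """M completed tables plus provenance (config, seeds, parameter traces).

    ``alpha1``/``alpha2`` trace the drawn other-outcome coefficients per
    (imputation, cycle); they are zero by construction under ``fcs1``.
    """

    tables: list[pd.DataFrame]
    config: ImputationConfig
    seeds: list[int]
    alpha1: np.ndarray
    alpha2: np.ndarray

    @property
    def m(self) -> int:
        return len(self.tables)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, tab in enumerate(self.tables):
            tab.to_csv(directory / f"imputation_{i:02d}.csv", index=False)
        manifest = {
            "m": self.config.m,
            "n_cycles": self.config.n_cycles,
            "variant": self.config.variant,
            "seed": self.config.seed,
            "seeds": self.seeds,
            "alpha1": self.alpha1.tolist(),
            "alpha2": self.alpha2.tolist(),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ImputedSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        cfg = ImputationConfig(
            manifest["m"], manifest["n_cycles"], manifest["variant"], manifest["seed"]
        )
        tables = [
            pd.read_csv(directory / f"imputation_{i:02d}.csv") for i in range(cfg.m)
        ]
        return cls(
            tables,
            cfg,
            manifest["seeds"],
            np.asarray(manifest["alpha1"]),
            np.asarray(manifest["alpha2"]),
        )


def _drop_collinear_check(X: np.ndarray, names: list[str]) -> None:
    # rank check naming the first offending column
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for k in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : k + 1]) < np.linalg.matrix_rank(X[:, :k]) + 1:
                raise ValueError(f"collinear predictor column: {names[k]}")
        raise ValueError("collinear predictors")


def impute_continuous_step(
    y: np.ndarray,
    Xp: np.ndarray,
    g: np.ndarray,
    J: int,
    obs: np.ndarray,
    rng: np.random.Generator,
    state: dict | None = None,
    single_level: bool = False,
    names: list[str] | None = None,
    n_sweeps: int = 2,
) -> tuple[np.ndarray, dict]:
    """One chained-equations update of the continuous outcome.

    Draws (u, beta, sigma^2, tau^2) from their full conditionals given the
    currently observed/imputed data (a short Gibbs sweep warm-started from
    the previous cycle's state), then replaces the missing entries with
    draws from the predictive normal.  Returns the completed outcome vector
    and the updated parameter state.
    """
    if obs.sum() == 0:
        raise ValueError("continuous outcome has no observed values")
    n, p = Xp.shape
    if names is not None:
        _drop_collinear_check(Xp[obs], names)

    yo = y[obs]
    Xo = Xp[obs]
    go = g[obs]
    A = Xo.T @ Xo + 1e-8 * np.eye(p)
    nj = np.bincount(go, minlength=J).astype(float)

    if state is None:
        beta = np.linalg.solve(A, Xo.T @ yo)
        resid = yo - Xo @ beta
        state = {
            "beta": beta,
            "u": np.zeros(J),
            "sigma2": max(resid.var(), 1e-8),
            "tau2": 0.0 if single_level else 1.0,
        }

    beta, u, sigma2, tau2 = state["beta"], state["u"], state["sigma2"], state["tau2"]
    for _ in range(n_sweeps):
        # study intercepts
        if single_level:
            u = np.zeros(J)
        else:
            resid_sum = np.bincount(go, weights=yo - Xo @ beta, minlength=J)
            var_j = 1.0 / (nj / sigma2 + 1.0 / tau2)
            mean_j = var_j * resid_sum / sigma2
            u = mean_j + np.sqrt(var_j) * rng.standard_normal(J)
            # studies with no observed rows revert to the population draw
            empty = nj == 0
            if empty.any():
                u[empty] = np.sqrt(tau2) * rng.standard_normal(int(empty.sum()))
            tau2 = (_TAU_NU0 * _TAU_S0 + u @ u) / rng.chisquare(_TAU_NU0 + J)
        # coefficients
        bhat = np.linalg.solve(A, Xo.T @ (yo - u[go]))
        L = np.linalg.cholesky(np.linalg.inv(A) * sigma2)
        beta = bhat + L @ rng.standard_normal(p)
        # residual variance
        rss = np.sum((yo - Xo @ beta - u[go]) ** 2)
        sigma2 = rss / rng.chisquare(len(yo))

    out = y.copy()
    mis = ~obs
    if mis.any():
        mu = Xp[mis] @ beta + u[g[mis]]
        out[mis] = mu + np.sqrt(sigma2) * rng.standard_normal(int(mis.sum()))
    return out, {"beta": beta, "u": u, "sigma2": sigma2, "tau2": tau2}


def impute_binary_step(
    y: np.ndarray,
    Xp: np.ndarray,
    g: np.ndarray,
    J: int,
    obs: np.ndarray,
    rng: np.random.Generator,
    state: dict | None = None,
    names: list[str] | None = None,
) -> tuple[np.ndarray, dict]:
    """One chained-equations update of the binary outcome.

    Penalised IRLS for the logistic mixed model (ridge 1/tau^2 on the study
    intercepts, N(0, 10^2) prior on coefficients), joint normal draw at the
    mode (Laplace approximation), Bernoulli imputation from the predictive
    probabilities.  Separation triggers a ridge-stabilised refit.
    """
    if obs.sum() == 0:
        raise ValueError("binary outcome has no observed values")
    n, p = Xp.shape
    if names is not None:
        _drop_collinear_check(Xp[obs], names)

    yo = y[obs]
    go = g[obs]
    # map studies with observed rows to dense dummy columns
    obs_studies = np.unique(go)
    col_of = -np.ones(J, dtype=int)
    col_of[obs_studies] = np.arange(len(obs_studies))
    Jo = len(obs_studies)
    D = np.zeros((len(yo), Jo))
    D[np.arange(len(yo)), col_of[go]] = 1.0
    Z = np.concatenate([Xp[obs], D], axis=1)
    k = p + Jo

    if state is None:
        state = {"psi": np.zeros(k), "tau2": 1.0}
    psi = state["psi"]
    if len(psi) != k:
        psi = np.zeros(k)
    tau2 = state["tau2"]

    beta_prec = 0.01
    ridge = 0.0
    n_iter = 8 if state.get("cold", True) else 4
    for attempt in range(2):
        psi_try = psi.copy()
        ok = True
        for _ in range(n_iter):
            eta = np.clip(Z @ psi_try, -30, 30)
            mu = expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-10)
            prec = np.full(k, beta_prec + ridge)
            prec[p:] = 1.0 / max(tau2, 1e-4) + ridge
            H = (Z * w[:, None]).T @ Z + np.diag(prec)
            grad = Z.T @ (yo - mu) - prec * psi_try
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                ok = False
                break
            psi_try = psi_try + step
            if not np.isfinite(psi_try).all() or np.abs(psi_try).max() > 15:
                ok = False
                break
        if ok:
            psi = psi_try
            break
        warnings.warn(
            "separation detected in binary imputation model; refitting with ridge",
            stacklevel=2,
        )
        ridge = 1.0
    else:
        raise RuntimeError("binary imputation model failed to converge")

    eta = np.clip(Z @ psi, -30, 30)
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    prec = np.full(k, beta_prec + ridge)
    prec[p:] = 1.0 / max(tau2, 1e-4) + ridge
    H = (Z * w[:, None]).T @ Z + np.diag(prec)
    # joint draw of (coefficients, observed-study intercepts)
    Lh = np.linalg.cholesky(H)
    draw = psi + np.linalg.solve(Lh.T, rng.standard_normal(k))

    u_draw = np.zeros(J)
    u_draw[obs_studies] = draw[p:]
    tau2 = (_TAU_NU0 * _TAU_S0 + u_draw[obs_studies] @ u_draw[obs_studies]) / rng.chisquare(
        _TAU_NU0 + Jo
    )
    # systematically missing studies: intercept from the population draw
    unseen = col_of < 0
    if unseen.any():
        u_draw[unseen] = np.sqrt(tau2) * rng.standard_normal(int(unseen.sum()))

    out = y.copy()
    mis = ~obs
    if mis.any():
        eta_m = np.clip(Xp[mis] @ draw[:p] + u_draw[g[mis]], -30, 30)
        out[mis] = (rng.random(int(mis.sum())) < expit(eta_m)).astype(float)
    return out, {"psi": draw, "tau2": tau2, "u": u_draw, "cold": False}


class FCSImputer:
    """Chained-equations imputer for one incomplete IPD table."""

    def __init__(self, data: pd.DataFrame, config: ImputationConfig | None = None):
        self.data = validate_ipd(data)
        self.config = config or ImputationConfig()
        self._g, self._ids = study_index(self.data)
        self._J = len(self._ids)
        base = [self.data["treatment"].to_numpy(dtype=float)] + [
            self.data[c].to_numpy(dtype=float) for c in COVARIATES
        ]
        self._Xbase = np.column_stack([np.ones(len(self.data))] + base)
        self._names = ["const", "treatment", *COVARIATES]
        y1 = self.data["y_cont"].to_numpy(dtype=float)
        y2 = self.data["y_bin"].to_numpy(dtype=float)
        self._y1, self._y2 = y1, y2
        self._obs1 = ~np.isnan(y1)
        self._obs2 = ~np.isnan(y2)
        if not self._obs1.any() or not self._obs2.any():
            raise ValueError("each outcome needs at least one observed value")

    def impute(self) -> ImputedSet:
        cfg = self.config
        fcs2 = cfg.variant == "fcs2"
        ss = np.random.SeedSequence(cfg.seed)
        children = ss.spawn(cfg.m)
        seeds = [int(c.generate_state(1)[0]) for c in children]
        tables = []
        a1 = np.zeros((cfg.m, cfg.n_cycles))
        a2 = np.zeros((cfg.m, cfg.n_cycles))
        single = self._J == 1

        for m_idx, child in enumerate(children):
            rng = np.random.default_rng(child)
            y1 = self._y1.copy()
            y2 = self._y2.copy()
            # initial fills from the observed marginals
            if (~self._obs1).any():
                y1[~self._obs1] = rng.choice(
                    y1[self._obs1], size=int((~self._obs1).sum()), replace=True
                )
            if (~self._obs2).any():
                y2[~self._obs2] = rng.choice(
                    y2[self._obs2], size=int((~self._obs2).sum()), replace=True
                )
            st1 = st2 = None
            for cyc in range(cfg.n_cycles):
                X1 = np.column_stack([self._Xbase, y2]) if fcs2 else self._Xbase
                nm1 = self._names + (["y_bin"] if fcs2 else [])
                y1, st1 = impute_continuous_step(
                    y1, X1, self._g, self._J, self._obs1, rng,
                    state=st1, single_level=single, names=nm1 if cyc == 0 else None,
                )
                X2 = np.column_stack([self._Xbase, y1]) if fcs2 else self._Xbase
                nm2 = self._names + (["y_cont"] if fcs2 else [])
                y2, st2 = impute_binary_step(
                    y2, X2, self._g, self._J, self._obs2, rng,
                    state=st2, names=nm2 if cyc == 0 else None,
                )
                if fcs2:
                    a1[m_idx, cyc] = st1["beta"][-1]
                    a2[m_idx, cyc] = st2["psi"][X2.shape[1] - 1]
            tab = self.data.copy()
            tab["y_cont"] = y1
            tab["y_bin"] = y2
            tables.append(tab)
        return ImputedSet(tables, cfg, seeds, a1, a2)


def run_chained_equations(
    table: pd.DataFrame, cfg: ImputationConfig | None = None
) -> ImputedSet:
    """Functional wrapper over :class:`FCSImputer`."""
    return FCSImputer(table, cfg).impute()
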