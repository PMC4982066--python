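# ipdmix

Joint latent-normal modelling and multilevel chained-equations imputation
for incomplete correlated continuous and binary outcomes in
individual-participant-data (IPD) meta-analysis.

## The problem

Meta-analyses of participant-level trial data routinely face outcomes that
are missing for some participants (*sporadically missing*) or never
collected in some studies (*systematically missing*), and trials usually
record several correlated endpoints — say a functional score (continuous)
and a clinical response (binary).  Discarding incomplete participants
(complete-case analysis) wastes data and can bias treatment effects; a
principled analysis must exploit the correlation between outcomes and the
between-study heterogeneity while respecting a missing-at-random (MAR)
assumption.  This package implements, and provides the machinery to
compare, the two principled strategies:

1. **Full-Bayes joint model** — a latent-normal joint hierarchical model

   ```
   y1_ij = b1'x_ij + u1_j + e1_ij                       (continuous)
   z_ij  = b2'x_ij + u2_j + e2_ij,   y2_ij = 1{z_ij > 0}  (probit latent)
   (e1, e2)_ij ~ N(0, Omega_e),  Omega_e = [[s1^2, rho*s1], [rho*s1, 1]]
   (u1, u2)_j  ~ N(0, Omega_u),  Omega_u = [[t1^2, phi*t1*t2], [., t2^2]]
   ```

   estimated by a blocked Gibbs sampler (numba-compiled) in which missing
   outcomes are just more unknowns: latent probit values are drawn from
   truncated normals, missing entries from their conditional normals, and
   the residual covariance is updated under the identification constraint
   `sigma2^2 = 1` by parameter expansion.

2. **Fully conditional specification (FCS)** — multilevel multiple
   imputation by chained equations: a random-intercept linear model for
   the continuous outcome and a random-intercept logistic model for the
   binary one, iterated 10 cycles for each of M = 10 imputations, in two
   variants (the imputation model excluding or including the other
   outcome).  Completed datasets are analysed with the bivariate
   substantive model and pooled by Rubin's rules.

A Gaussian-copula data generator produces two-level IPD with known
treatment effects (1 on the continuous outcome; logit 0.1, i.e. probit
0.06, on the binary one) and imposes calibrated MAR missingness —
covariate-dependent, outcome-dependent (via a split-sample construction
that keeps the mechanism MAR), or whole-study loss of the binary outcome.
A simulation harness scores every method by percent bias, rMSE and joint
95% region coverage.

## Worked example

```python
from ipdmix import (ScenarioConfig, calibrate_theta, draw_complete_ipd,
                    impose_missingness, JointLatentNormalModel, MCMCConfig)

mp = calibrate_theta(0.2, 0.3, mechanism="covariate_only")   # 20% MAR
cfg = ScenarioConfig(n_studies=20, n_per_study=150, rho=0.2, phi=0.1,
                     missingness=mp, seed=5)
table = impose_missingness(draw_complete_ipd(cfg), mp, seed=6)

res = JointLatentNormalModel(table).fit(MCMCConfig(seed=2))
print(res.summary().loc[["b1_treat", "b2_treat", "rho"]].round(3))
print("joint 95% region contains (1, 0.06):",
      res.joint_region_contains([1.0, 0.06]))
```

prints (seeds as above)

```
           mean     sd   q2.5  q97.5   psrf
b1_treat  1.035  0.041  0.955  1.118  1.000
b2_treat  0.099  0.055 -0.008  0.209  1.002
rho       0.252  0.030  0.193  0.310  1.001
joint 95% region contains (1, 0.06): True
```

i.e. with a fifth of each outcome missing at random, this particular
dataset's posterior is centred about one posterior standard deviation from
the generating effects (1 and 0.06) and outcome correlation (0.2) — the
ordinary sampling variability of a single 3000-participant draw — and the
95% joint credible ellipse covers the truth.  The chained-equations route for the same table:

```python
from ipdmix import run_chained_equations, ImputationConfig, fit_substantive, rubin_pool
imp = run_chained_equations(table, ImputationConfig(m=10, n_cycles=10,
                                                    variant="fcs2", seed=3))
pooled = rubin_pool([fit_substantive(t, MCMCConfig(1000, 400, 1, 1, seed=i))
                     for i, t in enumerate(imp.tables)])
print(pooled.theta_bar.round(3))   # -> [1.029 0.103]
```

The command line mirrors the library: `ipdmix simulate`, `ipdmix fit`,
`ipdmix run-grid`, `ipdmix report` (see `ipdmix --help`).

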