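# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## The joint latent-normal hierarchical model

For participant *i* in study *j*, with outcome vector (continuous `y1`,
binary `y2`) and fixed-effect design `x = (1, t, x1..x4)`:

    y1_ij = b1'x_ij + u1_j + e1_ij
    z_ij  = b2'x_ij + u2_j + e2_ij,    y2_ij = 1{z_ij > 0}
    (e1,e2) ~ N(0, Omega_e),  Omega_e = [[sigma1^2, rho*sigma1],[., 1]]
    (u1,u2) ~ N(0, Omega_u),  Omega_u = [[tau1^2, phi*tau1*tau2],[., tau2^2]]

The binary margin is probit through the latent `z`; its residual variance
is fixed at 1 for identification.  Only the intercepts vary by study;
random treatment effects are out of scope.  Both margins share the full
covariate set so that every variable entering any missingness mechanism
we simulate is conditioned on by the analysis model — the requirement for
missing-at-random (MAR) validity.

**Estimation.**  A blocked Gibbs sampler (single compiled kernel, O(n) per
sweep):

1. latent `z` for observed `y2` from normals truncated at 0 on the side
   given by `y2` (inverse-CDF draw; Robert's exponential rejection beyond
   5 sd, where the inverse CDF degrades);
2. missing `y1`, and unconstrained `z` for missing `y2`, from the
   conditional normals implied by `Omega_e` — missing outcomes are simply
   additional unknowns, so sporadic and whole-study gaps need no separate
   machinery;
3. all 12 regression coefficients jointly from their conjugate
   multivariate-normal full conditional (precision `W (x) X'X + c I`,
   with `W = Omega_e^{-1}` and prior N(0, 10^2) per coefficient);
4. study intercepts from bivariate normal full conditionals;
5. `Omega_u` from its inverse-Wishart full conditional, prior IW(3, I);
6. `Omega_e` by parameter expansion: an unconstrained 2x2 covariance is
   drawn from the conjugate inverse-Wishart conditional (prior IW(3, I)
   on the expanded scale) and the whole second margin — `z`, `b2`, `u2`
   and the `tau2` components — is rescaled so the (2,2) entry is exactly
   1.  This is the standard parameter-expanded step for multivariate
   probit models; it preserves conjugacy and mixes far better than
   Metropolis updates of (sigma1, rho) under the constraint.

Priors are vague/weakly informative and configurable (`PriorSpec`).  We
use inverse-Wishart priors for both covariance matrices rather than
separate half-normal/uniform priors on the components: the IW family is
what the conjugate full conditionals in steps 5-6 require, and at the
simulated sample sizes the likelihood dominates.  With 5 studies the
IW(3, I) prior on `Omega_u` is mildly informative (it shrinks the
between-study variances towards 1, which here equals the generating
value for the simulated conditions; real analyses with few studies should
treat `tau` posteriors cautiously).

**Defaults.**  5000 iterations, first half burn-in, 2 chains, no
thinning (`MCMCConfig.reduced()`); `MCMCConfig.paper_mode()` runs 50 000
iterations with thinning 10.  Split-chain Gelman-Rubin factors below 1.1
are treated as convergence.  Replicate loops in the simulation harness
use one chain per fit; chain-level diagnostics are exercised separately.

**Joint credible region.**  The 95% joint region for the two treatment
effects is the ellipse `(t - m)' S^{-1} (t - m) <= chi2_2(0.95)` with
`m, S` the posterior mean and covariance of the pooled draws — a
normal-approximation contour rather than an HPD depth region.  The same
elliptical construction (with Rubin's total covariance `T`) serves as the
simultaneous confidence region for the MI and complete-case routes, so
"joint coverage" means the same thing for every method.  A small-sample
F-referenced variant (Li-Raghunathan-Rubin degrees of freedom) is
available behind `small_sample=True`.

## Chained-equations imputation

Each cycle updates the continuous outcome, then the binary outcome.  The
continuous step is a conjugate Gibbs update of a random-intercept linear
model (flat prior on coefficients, scale-invariant prior on `sigma^2`,
scaled-inverse-chi-square(1, 0.25) on `tau^2`), warm-started from the
previous cycle, followed by predictive-normal draws for the missing
entries.  With a single study and `tau^2` fixed to zero the stationary
distribution of this step is exactly the Bayesian linear-regression
posterior predictive, which the test suite verifies against the conjugate
closed form by a Kolmogorov-Smirnov test.

The binary step fits a random-intercept logistic model by penalised IRLS
(ridge `1/tau^2` on the study intercepts, N(0, 10^2) prior on the
coefficients) and draws coefficients and intercepts jointly from the
Laplace (mode + curvature) approximation; detected separation triggers a
ridge-stabilised refit with a warning.  Studies with no observed values
of an outcome receive intercepts drawn from N(0, tau^2) — this is how
systematically missing outcomes borrow strength from the other studies.
The binary imputation model is logistic while the analysis model is
probit; the mismatch is deliberate (standard practice, and harmless at
these effect sizes).

Variant `fcs1` uses predictors (treatment, x1..x4); `fcs2` adds the other
outcome's individual values (cluster means are not added — a known
refinement that is out of scope).  Chains are initialised by resampling
the observed marginals; M = 10 imputations with 10 cycles each.  Each
completed table is analysed with the same Gibbs sampler and the M
estimates are combined by Rubin's rules
(`T = W_bar + (1 + 1/M) B`).  No multilevel chained-equations
implementation exists in the installed Python stack, so both imputation
steps are implemented here directly, following the standard two-level
normal and two-level binary algorithms.

## Synthetic-data generator

The generator emulates a two-arm IPD meta-analysis with total n = 3000:
20 studies of 150 or 5 studies of 600, treatment assigned 1:1 by permuted
blocks within study.  Covariates x1..x4 are i.i.d. standard normal;
study intercept pairs are bivariate normal with unit variances and
correlation `phi`; the margins are

    y1 ~ N(1 + 1*t + 0.5 x1 + 0.5 x2 + u1, 1)
    y2 ~ Bernoulli(pi),  logit(pi) = -0.5 + 0.1*t + 0.2 x3 + 0.2 x4 + u2

linked by a Gaussian copula with correlation `rho`: a bivariate standard
normal pair is mapped through the normal CDF, the first coordinate drives
the normal margin, and `y2 = 1` iff the second uniform exceeds `1 - pi`
(so larger latent values map to 1 and the sign of `rho` matches the sign
of the outcome association).  The generating treatment effects are 1 and
(via the logit-to-probit bridge, factor 0.6) 0.06; the empirical probit
coefficient recovered from 10^6 participants is ~0.061-0.062, i.e. the
0.06 reference is the bridge approximation, accurate to about 3%.

**Missingness.**  Sporadic missingness follows
`logit P(R_k = 1) = theta_k0 + theta_k1 x_k (+ theta_k2 y_other)`, with
`x_k` the first covariate of the outcome's own linear predictor.  The
theta values are not fixed design constants: they are calibrated by
root-finding on a large simulated sample (10^6 rows, fixed internal
seed) so that the missingness rate matches its target within ±0.01 and
corr(R, x) matches 0.3 within ±0.03; in the outcome-dependent mechanism
`theta_k2` is additionally calibrated so corr(R, y_other) is about 0.3
(the strength of outcome dependence is not otherwise pinned down).
Calibration is fast enough to run at scenario setup, so no calibrated
values are cached on disk.

The outcome-dependent mechanism uses the split-sample construction: each
row is randomly allocated to one half in which only `y1` can be missing
(probability depending on x1 and the observed `y2`) or the other half in
which only `y2` can be missing (depending on x3 and the observed `y1`).
Every missingness probability therefore depends only on quantities that
remain observed in that row — MAR by construction — and no row loses both
outcomes.  The 20%/50% label is interpreted per outcome for sporadic
scenarios and as the within-half (equivalently, incomplete-participant)
rate for outcome-dependent ones.  Systematic missingness applies 20%
sporadic MAR to `y1` and removes `y2` from `round(rate * J)` randomly
chosen studies.

**What the generator does not emulate:** missing covariates, unbalanced
or confounded allocation, non-normal covariates or skewed outcomes,
more than two outcomes, survival endpoints, MNAR mechanisms, and
study-level effect modification.  Passing tests demonstrate internal
validity under these idealised conditions, not performance on real trial
data.

## A note on reference values that are not reproducible under MAR

Two behaviours sometimes attributed to these designs do not follow from
the mechanisms as stated, because the missingness models contain no
treatment term and treatment is randomised — selection is therefore
(nearly) arm-symmetric and shifts intercepts, not treatment contrasts.

### Complete-case bias under covariate-only missingness

With randomised treatment, missingness that depends only on baseline
covariates — whether or not they appear in the analysis model — shifts
intercepts but cannot bias the treatment coefficient of the linear
margin, and leaves likelihood-based fits consistent whenever the
selection covariates are conditioned on.  Our simulations confirm this:
complete-case analysis under the covariate-only mechanism is essentially
unbiased (percent bias well below 1%) with near-nominal joint coverage.
External reference values that attribute large complete-case bias to
covariate-only missingness are not reproducible under the mechanism as
stated; the acceptance test for that configuration asserts the reference
values verbatim and is expected to fail, documenting the discrepancy
rather than altering the mechanism to manufacture agreement.

### Coverage of the misspecified imputation variant

Under outcome-dependent missingness the `fcs1` imputation model omits a
genuinely predictive variable: at rho = 0.7 the rows missing the
continuous outcome run about 0.4 higher in it through their association
with the observed binary outcome.  The resulting imputations are shifted
— but equally so in both arms (the binary outcome depends on treatment
only through a logit coefficient of 0.1), so the treatment-effect bias
is a few tenths of a percent and Rubin's total variance remains valid:
measured joint coverage of `fcs1` stays near 0.95 rather than dropping
below 0.90.  Pronounced under-coverage of the misspecified variant would
require selection that interacts with treatment or a narrower
simultaneous-region construction than the chi-square ellipse used here;
the corresponding acceptance assertion is expected to fail and is left
to say so.

## Numerical choices and scale of the reproduction runs

* Truncated-normal draws: inverse CDF (AS241 `ndtri`, `erfc`) with
  exponential-rejection fallback beyond 5 sd; bulk uniforms/normals are
  pre-drawn per sweep for speed.
* The 12-dimensional coefficient draw uses a Cholesky solve of the
  Kronecker-structured precision; 2x2 covariance draws use hand-coded
  Bartlett decompositions.
* Degenerate inputs fail loudly: constant treatment, single study, an
  outcome with no observed values, collinear imputation predictors
  (offending column named), singular pooled covariance.
* Determinism: every public entry point takes a seed; the harness expands
  a master seed through `SeedSequence.spawn` (one child per replicate,
  sub-streams per purpose), so runs are bit-reproducible.

The acceptance-level reproduction in `tests/test_acceptance.py` runs at
desk scale, with sizes chosen as the package's own test-budget policy:
200 replicates for the full-data/complete-case scenario, 100 for the
high-correlation complete-case cell, 80 for each MI-heavy comparison;
per-replicate fits use 5000 iterations (half burn-in, one chain) and the
per-imputation substantive fits 600 iterations (burn-in 250).  At these
sizes the binomial Monte-Carlo standard error of a coverage estimate is
0.015-0.025, which is the resolution at which the coverage assertions
should be read.  The full-scale experiment (1000 replicates, 50 000
iterations) is available through `MCMCConfig.paper_mode()` and the
`run-grid` CLI but takes hours.

## Known limitations

* The elliptical joint region is a normal approximation; for strongly
  non-elliptical posteriors an HPD region would differ.
* Posterior means/covariances stand in for ML estimates and their
  covariance in Rubin pooling — a documented approximation, excellent at
  n = 3000 with vague priors.
* The parameter-expanded covariance step induces its prior on
  (sigma1^2, rho) implicitly through the expanded inverse-Wishart.
* With very few studies (< 5) the between-study covariance is weakly
  identified; the joint model then leans on its prior.
* The imputation steps use one-draw Laplace/conjugate updates per cycle
  (as standard chained-equations implementations do), not exact MCMC.
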