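"""Blocked Gibbs sampler core for the latent-normal joint hierarchical model.

One compiled function runs a single chain.  The model per row i (study j):

    y1_i = x_i' b1 + u1_j + e1_i          (continuous outcome)
    z_i  = x_i' b2 + u2_j + e2_i,  y2_i = 1{z_i > 0}   (probit latent)
    (e1, e2) ~ N(0, Omega_e),  Omega_e[1,1] = sigma2^2 fixed to 1
    (u1_j, u2_j) ~ N(0, Omega_u)

Sweep: (1) latent z for observed y2 from truncated normals conditional on
y1; (2) missing y1 and unconstrained z for missing y2 from conditional
normals; (3) all regression coefficients jointly from their conjugate
multivariate-normal full conditional; (4) study random intercepts; (5)
Omega_u from its inverse-Wishart full conditional; (6) Omega_e by parameter
expansion: an unconstrained 2x2 covariance is drawn from the conjugate
inverse-Wishart conditional and the whole second margin (z, b2, u2 and the
tau2 components of Omega_u) is rescaled so the (2,2) entry is exactly 1.

Everything is hand-vectorised 2x2 / small-p linear algebra so the whole
sweep JIT-compiles; per-iteration cost is O(n).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EMPTY = np.empty(0)

# Monitored parameter layout (columns of the draws matrix) for p = 6:
#   0..5   b1 (const, treat, x1..x4)
#   6..11  b2 (const, treat, x1..x4)
#   12 sigma1_sq   13 sigma2_sq (== 1)   14 rho
#   15 tau1_sq     16 tau2_sq            17 phi
#   18 z_sign_frac (fraction of observed-y2 rows with sign-consistent z)
N_EXTRA = 7


@njit(cache=True)
def _ndtri(q):
    """Inverse standard-normal CDF (Wichura's AS241, double precision)."""
    if q <= 0.0:
        return -np.inf
    if q >= 1.0:
        return np.inf
    r = q - 0.5
    if abs(r) <= 0.425:
        s = 0.180625 - r * r
        num = (((((((2509.0809287301226727 * s + 33430.575583588128105) * s
                    + 67265.770927008700853) * s + 45921.953931549871457) * s
                  + 13731.693765509461125) * s + 1971.5909503065514427) * s
                + 133.14166789178437745) * s + 3.387132872796366608)
        den = (((((((5226.495278852545703 * s + 28729.085735721942674) * s
                    + 39307.89580009271061) * s + 21213.794301586595867) * s
                  + 5394.1960214247511077) * s + 687.1870074920579083) * s
                + 42.313330701600911252) * s + 1.0)
        return r * num / den
    if r < 0.0:
        s = q
    else:
        s = 1.0 - q
    t = math.sqrt(-math.log(s))
    if t <= 5.0:
        t = t - 1.6
        num = (((((((7.7454501427834140764e-4 * t + 0.0227238449892691845833) * t
                    + 0.24178072517745061177) * t + 1.27045825245236838258) * t
                  + 3.64784832476320460504) * t + 5.7694972214606914055) * t
                + 4.6303378461565452959) * t + 1.42343711074968357734)
        den = (((((((1.05075007164441684324e-9 * t + 5.475938084995344946e-4) * t
                    + 0.0151986665636164571966) * t + 0.14810397642748007459) * t
                  + 0.68976733498510000455) * t + 1.6763848301838038494) * t
                + 2.05319162663775882187) * t + 1.0)
    else:
        t = t - 5.0
        num = (((((((2.01033439929228813265e-7 * t + 2.71155556874348757815e-5) * t
                    + 0.0012426609473880784386) * t + 0.026532189526576123093) * t
                  + 0.29656057182850489123) * t + 1.7848265399172913358) * t
                + 5.4637849111641143699) * t + 6.6579046435011037772)
        den = (((((((2.04426310338993978564e-15 * t + 1.4215117583164458887e-7) * t
                    + 1.8463183175100546818e-5) * t + 7.868691311456132591e-4) * t
                  + 0.0148753612908506148525) * t + 0.13692988092273580531) * t
                + 0.59983220655588793769) * t + 1.0)
    val = num / den
    if r < 0.0:
        val = -val
    return val


@njit(cache=True)
def _ndtr(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _trunc_from_u(m, sd, positive, uin):
    """Inverse-CDF draw from N(m, sd^2) truncated at 0, consuming uniform uin.

    Falls back to Robert's exponential rejection (with its own RNG calls)
    when the truncation sits more than 5 sd into the tail, where the
    inverse CDF loses accuracy.
    """
    if positive:
        a = -m / sd  # standardised lower bound
        if a < 5.0:
            fa = _ndtr(a)
            u = fa + uin * (1.0 - fa)
            if u > 1.0 - 1e-16:
                u = 1.0 - 1e-16
            return m + sd * _ndtri(u)
        # deep tail: Robert (1995) exponential rejection on the standard scale
        alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
        while True:
            e = np.random.exponential(1.0 / alpha)
            x = a + e
            r = math.exp(-0.5 * (x - alpha) ** 2)
            if np.random.random() <= r:
                return m + sd * x
    else:
        b = -m / sd  # standardised upper bound
        if b > -5.0:
            fb = _ndtr(b)
            u = uin * fb
            if u < 1e-300:
                u = 1e-300
            return m + sd * _ndtri(u)
        a = -b
        alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
        while True:
            e = np.random.exponential(1.0 / alpha)
            x = a + e
            r = math.exp(-0.5 * (x - alpha) ** 2)
            if np.random.random() <= r:
                return m - sd * x


@njit(cache=True)
def _inv2(a00, a01, a11):
    det = a00 * a11 - a01 * a01
    return a11 / det, -a01 / det, a00 / det


@njit(cache=True)
def _invwishart2(df, s00, s01, s11):
    """Draw a 2x2 matrix from IW(df, S) via the Bartlett decomposition."""
    # V = S^-1, L = chol(V)
    v00, v01, v11 = _inv2(s00, s01, s11)
    l00 = math.sqrt(v00)
    l10 = v01 / l00
    l11 = math.sqrt(v11 - l10 * l10)
    # Bartlett factor of Wishart(df, V)
    b00 = math.sqrt(np.random.chisquare(df))
    b11 = math.sqrt(np.random.chisquare(df - 1.0))
    b10 = np.random.standard_normal()
    # T = L @ B (lower triangular), W = T T'
    t00 = l00 * b00
    t10 = l10 * b00 + l11 * b10
    t11 = l11 * b11
    w00 = t00 * t00
    w01 = t00 * t10
    w11 = t10 * t10 + t11 * t11
    return _inv2(w00, w01, w11)


@njit(cache=True)
def _chol_solve_draw(P, s, out_mean, out_draw):
    """Given precision P and linear term s: mean = P^-1 s, draw ~ N(mean, P^-1)."""
    L = np.linalg.cholesky(P)
    k = s.shape[0]
    v = np.empty(k)
    for i in range(k):
        acc = s[i]
        for j in range(i):
            acc -= L[i, j] * v[j]
        v[i] = acc / L[i, i]
    for i in range(k - 1, -1, -1):
        acc = v[i]
        for j in range(i + 1, k):
            acc -= L[j, i] * out_mean[j]
        out_mean[i] = acc / L[i, i]
    eps = np.empty(k)
    for i in range(k):
        eps[i] = np.random.standard_normal()
    for i in range(k - 1, -1, -1):
        acc = eps[i]
        for j in range(i + 1, k):
            acc -= L[j, i] * out_draw[j]
        out_draw[i] = acc / L[i, i]
    for i in range(k):
        out_draw[i] += out_mean[i]


@njit(cache=True, fastmath=True)
def gibbs_chain(
    X,
    y1,
    y2,
    miss1,
    miss2,
    g,
    J,
    n_iter,
    n_burn,
    thin,
    beta_prec,
    nu_u,
    Su,
    nu_e,
    Se,
    seed,
):
    np.random.seed(seed)
    n, p = X.shape
    k = 2 * p

    XT = np.ascontiguousarray(X.T)
    XtX = XT @ X

    nj = np.zeros(J)
    for i in range(n):
        nj[g[i]] += 1.0

    # ---- initial state -------------------------------------------------
    y1w = np.empty(n)
    m_obs = 0.0
    n_obs1 = 0
    for i in range(n):
        if not miss1[i]:
            m_obs += y1[i]
            n_obs1 += 1
    m_obs = m_obs / max(n_obs1, 1)
    for i in range(n):
        y1w[i] = m_obs if miss1[i] else y1[i]

    z = np.empty(n)
    for i in range(n):
        if miss2[i]:
            z[i] = 0.0
        else:
            z[i] = 0.5 if y2[i] > 0.5 else -0.5

    b1 = np.zeros(p)
    b1[0] = m_obs
    b2 = np.zeros(p)
    u = np.zeros((J, 2))
    s1sq = 1.0
    rho = 0.0
    ou00, ou01, ou11 = 1.0, 0.0, 1.0  # Omega_u

    n_keep = (n_iter - n_burn + thin - 1) // thin
    draws = np.empty((n_keep, k + N_EXTRA))
    keep = 0

    P = np.empty((k, k))
    svec = np.empty(k)
    bmean = np.empty(k)
    bdraw = np.empty(k)

    xb1 = X @ b1
    xb2 = X @ b2
    v1 = np.empty(n)
    v2 = np.empty(n)
    nm1 = 0
    nm2 = 0
    for i in range(n):
        if miss1[i]:
            nm1 += 1
        if miss2[i]:
            nm2 += 1

    for it in range(n_iter):
        # ---- (1)+(2) latent z and missing y1 ---------------------------
        s1 = math.sqrt(s1sq)
        sd_y1 = s1 * math.sqrt(1.0 - rho * rho)
        sd_z = math.sqrt(1.0 - rho * rho)
        c_y1 = rho * s1       # slope of y1 on z
        c_z = rho / s1        # slope of z on y1
        w00, w01, w11 = _inv2(s1sq, rho * s1, 1.0)
        un = np.random.random(n)
        nrm1 = np.random.standard_normal(nm1) if nm1 > 0 else _EMPTY
        nrm2 = np.random.standard_normal(nm2) if nm2 > 0 else _EMPTY
        c1 = 0
        c2 = 0
        for i in range(n):
            j = g[i]
            m1 = xb1[i] + u[j, 0]
            m2 = xb2[i] + u[j, 1]
            if miss1[i]:
                y1w[i] = m1 + c_y1 * (z[i] - m2) + sd_y1 * nrm1[c1]
                c1 += 1
            mz = m2 + c_z * (y1w[i] - m1)
            if miss2[i]:
                z[i] = mz + sd_z * nrm2[c2]
                c2 += 1
            else:
                z[i] = _trunc_from_u(mz, sd_z, y2[i] > 0.5, un[i])
            # residuals feeding the coefficient update
            r1 = y1w[i] - u[j, 0]
            r2 = z[i] - u[j, 1]
            v1[i] = w00 * r1 + w01 * r2
            v2[i] = w01 * r1 + w11 * r2

        # ---- (3) regression coefficients -------------------------------
        svec[:p] = XT @ v1
        svec[p:] = XT @ v2
        for a in range(p):
            for b in range(p):
                P[a, b] = w00 * XtX[a, b]
                P[a, p + b] = w01 * XtX[a, b]
                P[p + a, b] = w01 * XtX[a, b]
                P[p + a, p + b] = w11 * XtX[a, b]
            P[a, a] += beta_prec
            P[p + a, p + a] += beta_prec
        _chol_solve_draw(P, svec, bmean, bdraw)
        for q in range(p):
            b1[q] = bdraw[q]
            b2[q] = bdraw[p + q]
        xb1 = X @ b1
        xb2 = X @ b2

        # ---- (4) study random intercepts -------------------------------
        S1 = np.zeros(J)
        S2 = np.zeros(J)
        for i in range(n):
            S1[g[i]] += y1w[i] - xb1[i]
            S2[g[i]] += z[i] - xb2[i]
        wu00, wu01, wu11 = _inv2(ou00, ou01, ou11)
        for j in range(J):
            p00 = nj[j] * w00 + wu00
            p01 = nj[j] * w01 + wu01
            p11 = nj[j] * w11 + wu11
            c00, c01, c11 = _inv2(p00, p01, p11)
            t1 = w00 * S1[j] + w01 * S2[j]
            t2 = w01 * S1[j] + w11 * S2[j]
            mu_u1 = c00 * t1 + c01 * t2
            mu_u2 = c01 * t1 + c11 * t2
            l00 = math.sqrt(c00)
            l10 = c01 / l00
            l11 = math.sqrt(max(c11 - l10 * l10, 1e-300))
            e1 = np.random.standard_normal()
            e2 = np.random.standard_normal()
            u[j, 0] = mu_u1 + l00 * e1
            u[j, 1] = mu_u2 + l10 * e1 + l11 * e2

        # ---- (5) Omega_u ------------------------------------------------
        q00 = Su[0, 0]
        q01 = Su[0, 1]
        q11 = Su[1, 1]
        for j in range(J):
            q00 += u[j, 0] * u[j, 0]
            q01 += u[j, 0] * u[j, 1]
            q11 += u[j, 1] * u[j, 1]
        ou00, ou01, ou11 = _invwishart2(nu_u + J, q00, q01, q11)

        # ---- (6) Omega_e by parameter expansion ------------------------
        r00 = Se[0, 0]
        r01 = Se[0, 1]
        r11 = Se[1, 1]
        for i in range(n):
            j = g[i]
            e1 = y1w[i] - xb1[i] - u[j, 0]
            e2 = z[i] - xb2[i] - u[j, 1]
            r00 += e1 * e1
            r01 += e1 * e2
            r11 += e2 * e2
        oe00, oe01, oe11 = _invwishart2(nu_e + n, r00, r01, r11)
        sc = math.sqrt(oe11)
        # rescale the whole binary margin so sigma2^2 == 1 exactly
        for i in range(n):
            z[i] /= sc
        for q in range(p):
            b2[q] /= sc
        for j in range(J):
            u[j, 1] /= sc
        ou01 /= sc
        ou11 /= sc * sc
        s1sq = oe00
        rho = oe01 / (sc * math.sqrt(oe00))

        # ---- record ----------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            ok = 0
            n2 = 0
            for i in range(n):
                if not miss2[i]:
                    n2 += 1
                    if (y2[i] > 0.5 and z[i] > 0.0) or (y2[i] <= 0.5 and z[i] <= 0.0):
                        ok += 1
            for q in range(p):
                draws[keep, q] = b1[q]
                draws[keep, p + q] = b2[q]
            draws[keep, k] = s1sq
            draws[keep, k + 1] = 1.0
            draws[keep, k + 2] = rho
            draws[keep, k + 3] = ou00
            draws[keep, k + 4] = ou11
            draws[keep, k + 5] = ou01 / math.sqrt(ou00 * ou11)
            draws[keep, k + 6] = ok / max(n2, 1)
            keep += 1

    return draws
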