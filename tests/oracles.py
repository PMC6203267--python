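"""Independent reference implementations used to validate the samplers.

Everything here deliberately takes a different computational route from
the package: dense-grid / adaptive quadrature where the package uses
Gibbs sampling or closed forms, determinant algebra where the package
uses the R-squared identity.
"""

from __future__ import annotations

from math import lgamma, log, pi

import numpy as np
from scipy import stats


def grid_posterior_linreg(y, X, m0, s0, nu, omega, ngrid=4000):
    """Numerical posterior for the normal linear model with independent
    normal coefficient priors and an inverse-gamma variance prior.

    beta is integrated analytically conditional on sigma^2 (a Gaussian
    identity); sigma^2 is handled on a dense log grid.  Returns
    (E[beta], sd[beta], E[sigma^2], sd[sigma^2]).
    """
    y, X = np.asarray(y, float), np.asarray(X, float)
    n = len(y)
    V0 = np.diag(np.asarray(s0, float) ** 2)
    r = y - X @ np.asarray(m0, float)

    def conditional(s2):
        C = s2 * np.eye(n) + X @ V0 @ X.T
        Ci = np.linalg.inv(C)
        mean = m0 + V0 @ X.T @ Ci @ r
        cov = V0 - V0 @ X.T @ Ci @ X @ V0
        _, ld = np.linalg.slogdet(C)
        logml = -0.5 * (n * np.log(2 * np.pi) + ld + r @ Ci @ r)
        return mean, cov, logml

    coarse = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 300))
    lp = np.array([conditional(s2)[2]
                   + stats.invgamma.logpdf(s2, nu, scale=omega) for s2 in coarse])
    center = coarse[np.argmax(lp)]
    grid = np.exp(np.linspace(np.log(center) - 5, np.log(center) + 5, ngrid))
    means, covs, lps = [], [], []
    for s2 in grid:
        m, c, lml = conditional(s2)
        means.append(m)
        covs.append(c)
        lps.append(lml + stats.invgamma.logpdf(s2, nu, scale=omega))
    means, covs, lps = np.array(means), np.array(covs), np.array(lps)
    w = np.exp(lps - lps.max()) * np.gradient(grid)
    w /= w.sum()
    eb = w @ means
    ebb = np.einsum("i,ijk->jk", w,
                    covs + np.einsum("ij,ik->ijk", means, means))
    vb = np.clip(np.diag(ebb) - eb**2, 0, None)
    es2 = w @ grid
    vs2 = max(w @ grid**2 - es2**2, 0.0)
    return eb, np.sqrt(vb), es2, np.sqrt(vs2)


def gprior_logml_determinant(y, X, g):
    """g-prior log marginal by explicit determinant/quadratic-form algebra.

    Integrates the flat intercept analytically, leaving the centered
    response with covariance sigma^2 (I + g P_X); the sigma^2 integral
    is an inverse-gamma normalizing constant.  No R-squared identity is
    used anywhere.
    """
    y = np.asarray(y, float)
    n = len(y)
    yc = y - y.mean()
    if X is None or np.size(X) == 0:
        M = np.eye(n)
    else:
        Xc = np.asarray(X, float) - np.asarray(X, float).mean(axis=0)
        P = Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T)
        M = np.eye(n) + g * P
    _, ld = np.linalg.slogdet(M)
    S = float(yc @ np.linalg.solve(M, yc))
    return (lgamma((n - 1) / 2) - ((n - 1) / 2) * log(pi) - 0.5 * log(n)
            - 0.5 * ld - ((n - 1) / 2) * log(S))


def gprior_logml_quadrature(y, x, g, n_nodes=400):
    """Brute-force numeric integration of the one-slope g-prior marginal.

    Tensor Gauss-Legendre quadrature over (beta, log sigma^2) of
    likelihood x prior, with the flat intercept integrated in closed
    form (a 1-D Gaussian integral) and p(sigma^2) = 1/sigma^2.  Only for
    tiny n; node counts generous enough for ~1e-8 accuracy.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float).ravel()
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    ols_b = float(xc @ yc) / sxx
    s2_hat = max(float(np.var(y)) / 2, 1e-8)

    half = 14 * np.sqrt(s2_hat / sxx) * max(1.0, np.sqrt(g)) + abs(ols_b)
    b_nodes, b_w = np.polynomial.legendre.leggauss(n_nodes)
    beta = ols_b + half * b_nodes          # (B,)
    bw = half * b_w
    t_nodes, t_w = np.polynomial.legendre.leggauss(n_nodes)
    logs2 = np.log(s2_hat) + 14 * t_nodes  # (S,)
    s2 = np.exp(logs2)
    sw = 14 * t_w * s2                     # d sigma^2 = s2 d log s2

    # after integrating alpha flat: (2 pi s2)^{-(n-1)/2} n^{-1/2}
    #   exp(-0.5 ||yc - beta xc||^2 / s2)
    resid2 = (yc[None, :] - beta[:, None] * xc[None, :])
    q = np.einsum("bi,bi->b", resid2, resid2)  # (B,)
    loglik = (-0.5 * (n - 1) * np.log(2 * pi * s2)[None, :]
              - 0.5 * np.log(n)
              - 0.5 * q[:, None] / s2[None, :])
    logprior_b = stats.norm.logpdf(beta[:, None], 0.0,
                                   np.sqrt(g * s2 / sxx)[None, :])
    logf = loglik + logprior_b - np.log(s2)[None, :]
    shift = logf.max()
    total = float(bw @ np.exp(logf - shift) @ sw)
    return np.log(total) + shift


def kr20(items):
    """Kuder-Richardson formula 20 for dichotomous items.

    Item variances via p q n/(n-1) so the coefficient is exactly
    comparable with Cronbach's alpha computed with (n-1) variances.
    """
    x = np.asarray(items, float)
    n, k = x.shape
    p = x.mean(axis=0)
    item_var = (p * (1 - p) * n / (n - 1)).sum()
    total_var = np.var(x.sum(axis=1), ddof=1)
    return k / (k - 1) * (1 - item_var / total_var)
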