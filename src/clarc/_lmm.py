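"""Fast ML/REML fitter for linear mixed models with many small groups.

Specialised to the structure used here: hundreds of subjects each with a
handful of scans and q random effects (intercept + optional slope).  The
scaled random-effect covariance is parametrised by its log-Cholesky factor
(3 free parameters for q=2), the residual variance and the fixed effects are
profiled out in closed form, and all per-group operations are batched over
groups with equal scan counts so each likelihood evaluation is a few
vectorised (m, ni, ni) linear-algebra calls.  This reaches the same optimum
as a generic mixed-model fitter (asserted against statsmodels MixedLM in the
test suite) two orders of magnitude faster, which is what makes
subject-level bootstrap confidence intervals affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_SIGMA2_FLOOR = 1e-10


@dataclass
class LmmResult:
    fe_params: np.ndarray
    bse_fe: np.ndarray
    cov_re: np.ndarray      # q x q random-effect covariance, original scale
    scale: float            # residual variance
    llf: float
    converged: bool
    theta: np.ndarray       # log-Cholesky parameters at the optimum


def _batches(endog, exog, groups, exog_re):
    """Group rows by subject, then batch subjects with equal scan counts."""
    order = np.argsort(groups, kind="mergesort")
    g = groups[order]
    y = endog[order]
    X = exog[order]
    Z = exog_re[order]
    _, starts, counts = np.unique(g, return_index=True, return_counts=True)
    out = []
    for ni in np.unique(counts):
        idx = starts[counts == ni]
        rows = (idx[:, None] + np.arange(ni)[None, :]).ravel()
        m = len(idx)
        out.append((X[rows].reshape(m, ni, -1),
                    y[rows].reshape(m, ni),
                    Z[rows].reshape(m, ni, -1)))
    return out


def _theta_to_D(theta: np.ndarray, q: int) -> np.ndarray:
    """Scaled covariance D = L L' from log-Cholesky parameters."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L @ L.T


def _cov_to_theta(D: np.ndarray) -> np.ndarray:
    q = D.shape[0]
    # regularize toward PD before the Cholesky
    w, V = np.linalg.eigh(D)
    D = (V * np.maximum(w, 1e-6)) @ V.T
    L = np.linalg.cholesky(D)
    theta = []
    for i in range(q):
        for j in range(i + 1):
            theta.append(np.log(max(L[i, i], 1e-8)) if i == j else L[i, j])
    return np.asarray(theta)


def _profile(theta, batches, n, p, q, reml):
    """Profiled criterion plus the quantities needed to reassemble the fit."""
    D = _theta_to_D(theta, q)
    logdet = 0.0
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    yWy = 0.0
    for X, y, Z in batches:
        ni = y.shape[1]
        W = Z @ D @ np.swapaxes(Z, 1, 2) + np.eye(ni)
        Wi = np.linalg.inv(W)
        _, ld = np.linalg.slogdet(W)
        logdet += float(ld.sum())
        XtWX += np.einsum("mip,mij,mjq->pq", X, Wi, X, optimize=True)
        XtWy += np.einsum("mip,mij,mj->p", X, Wi, y, optimize=True)
        yWy += float(np.einsum("mi,mij,mj->", y, Wi, y, optimize=True))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(yWy - float(XtWy @ beta), _SIGMA2_FLOOR)
    if reml:
        sigma2 = rss / (n - p)
        _, ld_x = np.linalg.slogdet(XtWX)
        crit = (n - p) * np.log(sigma2) + logdet + ld_x + (n - p)
    else:
        sigma2 = rss / n
        crit = n * np.log(sigma2) + logdet + n
    return crit, beta, sigma2, XtWX, logdet, rss


def loglike(theta, batches, n, p, q, reml) -> float:
    crit, beta, sigma2, XtWX, logdet, rss = _profile(theta, batches, n, p, q, reml)
    if reml:
        # statsmodels MixedLM convention: |X' W^-1 X| enters unscaled
        _, ld_x = np.linalg.slogdet(XtWX)
        return -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logdet
                       + rss / sigma2) - 0.5 * ld_x
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + rss / sigma2)


def fit_lmm(endog, exog, groups, exog_re, reml: bool = False,
            start_cov: np.ndarray | None = None,
            start_scale: float | None = None) -> LmmResult:
    """Fit y = X beta + Z_i b_i + e by (RE)ML.

    ``start_cov``/``start_scale`` (original-scale covariance and residual
    variance) warm-start the 3-parameter covariance optimization.
    """
    endog = np.asarray(endog, dtype=float)
    exog = np.asarray(exog, dtype=float)
    exog_re = np.asarray(exog_re, dtype=float)
    groups = np.asarray(groups)
    n, p = exog.shape
    q = exog_re.shape[1]
    batches = _batches(endog, exog, groups, exog_re)

    if start_cov is None:
        start_cov, start_scale = _moment_start(endog, exog, groups, exog_re)
    theta0 = _cov_to_theta(start_cov / max(start_scale, 1e-8))

    def objective(th):
        try:
            return _profile(th, batches, n, p, q, reml)[0]
        except np.linalg.LinAlgError:
            return 1e12

    res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    theta = res.x
    crit, beta, sigma2, XtWX, logdet, rss = _profile(theta, batches, n, p, q, reml)
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return LmmResult(
        fe_params=beta,
        bse_fe=np.sqrt(np.diag(cov_beta)),
        cov_re=sigma2 * _theta_to_D(theta, q),
        scale=float(sigma2),
        llf=float(loglike(theta, batches, n, p, q, reml)),
        converged=bool(res.success),
        theta=theta,
    )


def _moment_start(endog, exog, groups, exog_re):
    """OLS fixed effects; covariance of per-subject OLS residual coefficients."""
    beta, *_ = np.linalg.lstsq(exog, endog, rcond=None)
    resid = endog - exog @ beta
    q = exog_re.shape[1]
    uniq, inv = np.unique(groups, return_inverse=True)
    coefs = np.zeros((len(uniq), q))
    within = []
    for i in range(len(uniq)):
        m = inv == i
        Z = exog_re[m]
        b, res_ss, rank, _ = np.linalg.lstsq(Z, resid[m], rcond=None)
        coefs[i] = np.where(np.abs(Z).sum(axis=0) > 0, b, 0.0)
        if len(res_ss) and m.sum() > rank:
            within.append(res_ss[0] / (m.sum() - rank))
    scale = float(np.mean(within)) if within else max(float(resid.var()) * 0.1, 1e-3)
    scale = max(scale, 1e-3)
    cov = np.cov(coefs.T) + np.eye(q) * 1e-3
    return cov, scale
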