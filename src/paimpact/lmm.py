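"""Profiled-REML linear mixed model with crossed random intercepts.

Implements the penalized-least-squares / profiled-deviance formulation
(Bates et al.) for the specific structure needed here: Gaussian response,
arbitrary fixed effects, and K crossed random-intercept factors.  The
variance-ratio parameters ``lambda_k = sigma_k / sigma_e`` are optimized
by bounded quasi-Newton over [0, inf); a boundary optimum pins the
corresponding variance at zero, and with all lambdas at zero the fit
collapses exactly to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import solve_triangular


@dataclass
class LMMResult:
    params: pd.Series  # fixed effects
    bse: pd.Series  # standard errors
    sigma2: float  # residual variance
    re_variances: dict[str, float]  # per-factor random-intercept variance
    resid: np.ndarray  # conditional residuals y - Xb - Zu
    converged: bool
    reml_criterion: float
    n_obs: int


def _one_hot(codes: np.ndarray) -> sparse.csr_matrix:
    n = len(codes)
    k = codes.max() + 1
    return sparse.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, k))


def fit_crossed_lmm(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    factors: dict[str, np.ndarray],
) -> LMMResult:
    """REML fit of ``y = X b + sum_k Z_k u_k + e`` with crossed intercepts.

    ``factors`` maps factor name -> integer-coded group labels per row.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(float)
    else:
        Xm = np.asarray(X, float)
        names = [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError("more parameters than observations")

    fnames = list(factors)
    codes = [pd.factorize(np.asarray(factors[f]))[0] for f in fnames]
    Zs = [_one_hot(c) for c in codes]
    sizes = [Z.shape[1] for Z in Zs]
    Z = sparse.hstack(Zs, format="csr")
    q = Z.shape[1]
    block = np.repeat(np.arange(len(sizes)), sizes)

    ZtZ = (Z.T @ Z).toarray()
    ZtX = Z.T @ Xm
    Zty = Z.T @ y
    XtX = Xm.T @ Xm
    Xty = Xm.T @ y
    yty = float(y @ y)

    def pls(lam: np.ndarray):
        lam_col = lam[block]
        A = ZtZ * np.outer(lam_col, lam_col)
        A[np.diag_indices(q)] += 1.0
        L = np.linalg.cholesky(A)
        RZX = solve_triangular(L, lam_col[:, None] * ZtX, lower=True)
        cu = solve_triangular(L, lam_col * Zty, lower=True)
        RXtRX = XtX - RZX.T @ RZX
        beta = np.linalg.solve(RXtRX, Xty - RZX.T @ cu)
        u_s = solve_triangular(L.T, cu - RZX @ beta, lower=False)
        # r^2 = |y - Xb - Z Lam u|^2 + |u|^2, computed via the identity
        fitted_quad = (
            yty
            - 2 * beta @ Xty
            - 2 * (lam_col * u_s) @ Zty
            + beta @ XtX @ beta
            + 2 * u_s @ (lam_col * (ZtX @ beta))
            + (lam_col * u_s) @ (ZtZ @ (lam_col * u_s))
            + u_s @ u_s
        )
        r2 = max(float(fitted_quad), 1e-300)
        logdet_L2 = 2.0 * np.log(np.diag(L)).sum()
        sign, logdet_RX = np.linalg.slogdet(RXtRX)
        crit = logdet_L2 + logdet_RX + (n - p) * (1.0 + np.log(2.0 * np.pi * r2 / (n - p)))
        return crit, beta, u_s, lam_col, r2, RXtRX

    def objective(lam: np.ndarray) -> float:
        return pls(lam)[0]

    x0 = np.ones(len(fnames))
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, 1e3)] * len(fnames),
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if not res.success:
        # L-BFGS-B line searches can fail near the lambda = 0 boundary;
        # a simplex polish from the best point is cheap and robust
        res2 = optimize.minimize(
            lambda v: objective(np.abs(v)),
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
        )
        if res2.fun <= res.fun:
            res2.x = np.abs(res2.x)
            res = res2
    lam = res.x
    crit, beta, u_s, lam_col, r2, RXtRX = pls(lam)

    sigma2 = r2 / (n - p)
    cov_beta = sigma2 * np.linalg.inv(RXtRX)
    bse = np.sqrt(np.diag(cov_beta))
    re_var = {f: float(lam[i] ** 2 * sigma2) for i, f in enumerate(fnames)}
    resid = y - Xm @ beta - Z @ (lam_col * u_s)
    return LMMResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        sigma2=float(sigma2),
        re_variances=re_var,
        resid=np.asarray(resid).ravel(),
        converged=bool(res.success),
        reml_criterion=float(crit),
        n_obs=n,
    )
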