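"""Single-random-intercept linear mixed model via profile REML.

The pipeline only ever needs one random effect: a per-participant
intercept that absorbs the correlation between the two depot samples
(subcutaneous and visceral) contributed by the same individual.  Rather
than a general mixed-model solver we profile the restricted likelihood
over the single variance ratio lambda = sigma_u^2 / sigma_e^2, with
closed-form GLS at each lambda: for a group of size m the marginal
covariance is sigma_e^2 (I_m + lambda J_m), whose inverse and
log-determinant are available in closed form.

At lambda = 0 the fit reduces exactly to OLS, which the tests exploit as
a degenerate-limit oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MixedFit", "fit_random_intercept"]

_LAMBDA_MAX = 1e6


@dataclass
class MixedFit:
    params: pd.Series          # fixed-effect estimates
    bse: pd.Series             # standard errors
    pvalues: pd.Series         # Wald t, df = n - p
    sigma_u2: float            # random-intercept variance
    sigma_e2: float            # residual variance
    lam: float                 # sigma_u2 / sigma_e2
    loglik: float              # restricted log-likelihood (up to a constant)
    nobs: int
    method: str = "reml"
    converged: bool = True

    def reml_criterion(self, lam: float) -> float:
        """-2 restricted log-likelihood at an arbitrary variance ratio
        (same data), for profile-optimality checks."""
        return self._crit(lam)


def _group_indices(groups) -> list[np.ndarray]:
    pos = pd.Series(np.arange(len(groups)))
    return [np.asarray(ix) for ix in pos.groupby(list(groups)).groups.values()]


def _gls_pieces(y, X, idx_by_group, lam):
    """X'V^-1X, X'V^-1y, y'V^-1y and log|V| for V = I + lam*J per group."""
    A = X.T @ X
    b = X.T @ y
    yy = float(y @ y)
    logdet = 0.0
    for ix in idx_by_group:
        m = len(ix)
        c = lam / (1.0 + lam * m)
        sx = X[ix].sum(axis=0)
        sy = float(y[ix].sum())
        A -= c * np.outer(sx, sx)
        b -= c * sx * sy
        yy -= c * sy * sy
        logdet += np.log1p(lam * m)
    return A, b, yy, logdet


def fit_random_intercept(y, X: pd.DataFrame, groups) -> MixedFit:
    """Fit y = X beta + u_group + eps with u ~ N(0, sigma_u^2) by REML.

    ``X`` must include an intercept column if one is wanted.  Falls back
    to OLS with cluster-robust (by group) standard errors if the profile
    optimisation fails numerically.
    """
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n - p < 2:
        raise ValueError("too few observations for the design")
    idx = _group_indices(groups)

    def crit(lam: float) -> float:
        A, b, yy, logdet = _gls_pieces(yv, Xv, idx, lam)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, b)
        quad = yy - b @ beta
        if quad <= 0:
            return np.inf
        sigma2 = quad / (n - p)
        return logdet + logdetA + (n - p) * np.log(sigma2)

    # coarse log-grid scan then local refinement; include the OLS boundary
    grid = np.concatenate([[0.0], np.logspace(-4, 5, 46)])
    vals = np.array([crit(l) for l in grid])
    k = int(np.nanargmin(vals))
    lam_hat = grid[k]
    converged = True
    try:
        lo = grid[max(k - 1, 0)]
        hi = min(grid[min(k + 1, len(grid) - 1)], _LAMBDA_MAX)
        if hi > lo:
            res = optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-8})
            if res.success and res.fun <= vals[k] + 1e-12:
                lam_hat = float(res.x)
    except Exception:
        converged = False

    if not converged or not np.isfinite(crit(lam_hat)):
        # OLS with cluster-robust covariance as a flagged fallback
        beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
        r = yv - Xv @ beta
        XtX_inv = np.linalg.inv(Xv.T @ Xv)
        meat = np.zeros((p, p))
        for ix in idx:
            s = Xv[ix].T @ r[ix]
            meat += np.outer(s, s)
        cov = XtX_inv @ meat @ XtX_inv
        se = np.sqrt(np.diag(cov))
        t = beta / se
        fit = MixedFit(
            params=pd.Series(beta, index=names), bse=pd.Series(se, index=names),
            pvalues=pd.Series(2 * stats.t.sf(np.abs(t), n - p), index=names),
            sigma_u2=np.nan, sigma_e2=float(r @ r / (n - p)), lam=np.nan,
            loglik=np.nan, nobs=n, method="ols_cluster", converged=False)
        fit._crit = crit
        return fit

    A, b, yy, logdet = _gls_pieces(yv, Xv, idx, lam_hat)
    A_inv = np.linalg.inv(A)
    beta = A_inv @ b
    quad = yy - b @ beta
    sigma_e2 = quad / (n - p)
    se = np.sqrt(np.diag(A_inv) * sigma_e2)
    t = beta / se
    fit = MixedFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(np.clip(2 * stats.t.sf(np.abs(t), n - p),
                                  np.finfo(float).tiny, 1.0), index=names),
        sigma_u2=float(lam_hat * sigma_e2),
        sigma_e2=float(sigma_e2),
        lam=float(lam_hat),
        loglik=-0.5 * crit(lam_hat),
        nobs=n,
    )
    fit._crit = crit
    return fit
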