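"""Classical-test-theory scoring: standardized mean scores and regression
factor scores from a one-factor maximum-likelihood CFA.

The CFA treats the 5-category items as continuous (the common applied
practice for rating scales) and fixes the factor variance at 1 for
identification.  Regression factor scores are the linear projection
Phi Lambda' Sigma^{-1} x of the centered responses onto the factor; they
shrink toward zero, so their sample variance is below 1 on model-conformant
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

RESIDUAL_FLOOR = 1e-4


@dataclass
class ScoreVector:
    """One person-level score series, tagged by scoring method."""

    method: str
    values: np.ndarray
    standardized: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")


@dataclass
class CFAParams:
    """One-factor ML CFA estimates (factor variance fixed at 1)."""

    loadings: np.ndarray
    residual_variances: np.ndarray
    loglik: float
    converged: bool
    factor_variance: float = 1.0

    @property
    def implied_cov(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) * self.factor_variance + np.diag(self.residual_variances)


def sms(items: np.ndarray) -> ScoreVector:
    """Standardized mean scores: per-person item means, z-standardized.

    Standardization uses the sample (n-1) standard deviation of the person
    means.  Raises on degenerate samples where every person has the same
    mean.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[0] < 2:
        raise ValueError("need an n x k matrix with n >= 2")
    means = items.mean(axis=1)
    sd = means.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate sample: all person means identical")
    return ScoreVector(method="SMS", values=(means - means.mean()) / sd, standardized=True)


def _cfa_objective(params, S, k):
    lam = params[:k]
    psi = params[k:]
    sigma = np.outer(lam, lam) + np.diag(psi)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(params)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    sigma_inv = np.linalg.inv(sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    f = logdet + np.trace(S @ sigma_inv) - logdet_s - k
    # dF = tr(A dSigma), A = Sigma^-1 (Sigma - S) Sigma^-1
    A = sigma_inv @ (sigma - S) @ sigma_inv
    grad = np.concatenate([2.0 * A @ lam, np.diag(A)])
    return f, grad


def fit_cfa(items: np.ndarray, treat_as_continuous: bool = True) -> CFAParams:
    """Fit the one-factor model by normal-theory ML on the sample covariance.

    Starts loadings at 0.5 and residuals at 0.75; residual variances are
    bounded below at a small positive floor (Heywood cases are floored and
    flagged through ``converged``).
    """
    if not treat_as_continuous:
        raise NotImplementedError("only the continuous-item ML CFA is implemented")
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if k < 3:
        raise ValueError("one-factor CFA needs k >= 3 items for identification")
    S = np.cov(items, rowvar=False, ddof=1)
    x0 = np.concatenate([np.full(k, 0.5), np.full(k, 0.75)])
    bounds = [(None, None)] * k + [(RESIDUAL_FLOOR, None)] * k
    res = optimize.minimize(
        _cfa_objective,
        x0,
        args=(S, k),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    lam = res.x[:k]
    psi = res.x[k:]
    if lam.sum() < 0:  # sign indeterminacy: orient the factor positively
        lam = -lam
    heywood = bool(np.any(psi <= RESIDUAL_FLOOR * 1.01))
    # Gaussian log-likelihood of the sample covariance at the optimum
    sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    loglik = -0.5 * n * (logdet + np.trace(S @ np.linalg.inv(sigma)) + k * np.log(2 * np.pi))
    return CFAParams(
        loadings=lam,
        residual_variances=psi,
        loglik=float(loglik),
        converged=bool(res.success) and not heywood,
    )


def rfs(params: CFAParams, items: np.ndarray) -> ScoreVector:
    """Regression factor scores Phi Lambda' Sigma^{-1} x from centered items."""
    items = np.asarray(items, dtype=float)
    centered = items - items.mean(axis=0)
    sigma = params.implied_cov
    try:
        weights = np.linalg.solve(sigma, params.loadings) * params.factor_variance
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("implied covariance is singular") from err
    return ScoreVector(method="RFS", values=centered @ weights, standardized=False)
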