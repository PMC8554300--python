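"""Full structural equation model: one-factor measurement model plus the
structural regression Y = beta*theta + gamma*C + e, fitted by normal-theory
maximum likelihood on the joint covariance of (items, C, Y).

The latent skill's variance is fixed at 1 for identification; loadings,
item residuals, cov(theta, C), Var(C), the structural coefficients, and the
outcome residual are free.  The fit minimizes the ML discrepancy

    F = log|Sigma(p)| + tr(S Sigma(p)^-1) - log|S| - (k + 2)

with an analytic gradient; F reaches ~0 when S is exactly model-conformant,
which is the recovery oracle used by the tests.  Items are treated as
continuous even though they are 5-category ordinal — the same practical
choice made when rating scales are analyzed with an ML SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_PSI_FLOOR = 1e-4


@dataclass
class SemFit:
    """Estimated SEM parameters for one sample."""

    loadings: np.ndarray
    residuals: np.ndarray
    theta_cov_corr: float  # estimated corr(theta, C)
    beta_hat: float
    gamma_hat: float
    y_residual: float
    discrepancy: float
    converged: bool
    var_c: float = 1.0

    def to_table(self):
        import pandas as pd

        rows = [(f"lambda_{j + 1}", v) for j, v in enumerate(self.loadings)]
        rows += [(f"psi_{j + 1}", v) for j, v in enumerate(self.residuals)]
        rows += [
            ("corr_theta_c", self.theta_cov_corr),
            ("beta", self.beta_hat),
            ("gamma", self.gamma_hat),
            ("y_residual", self.y_residual),
        ]
        return pd.DataFrame(rows, columns=["parameter", "estimate"])


def implied_covariance(
    lam: np.ndarray,
    psi: np.ndarray,
    phi_cov: float,
    var_c: float,
    beta: float,
    gamma: float,
    y_resid: float,
) -> np.ndarray:
    """Model-implied covariance over (X_1..X_k, C, Y) under the path model.

    theta has unit variance; phi_cov is cov(theta, C).
    """
    lam = np.asarray(lam, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.any(psi <= 0):
        raise ValueError("item residual variances must be positive")
    k = lam.shape[0]
    m = k + 2
    sigma = np.zeros((m, m))
    sigma[:k, :k] = np.outer(lam, lam)
    sigma[np.arange(k), np.arange(k)] += psi
    ic, iy = k, k + 1
    sigma[:k, ic] = sigma[ic, :k] = lam * phi_cov
    cov_theta_y = beta + gamma * phi_cov
    sigma[:k, iy] = sigma[iy, :k] = lam * cov_theta_y
    sigma[ic, ic] = var_c
    sigma[ic, iy] = sigma[iy, ic] = beta * phi_cov + gamma * var_c
    sigma[iy, iy] = beta**2 + gamma**2 * var_c + 2 * beta * gamma * phi_cov + y_resid
    return sigma


def _unpack(params: np.ndarray, k: int):
    return (
        params[:k],
        params[k : 2 * k],
        params[2 * k],
        params[2 * k + 1],
        params[2 * k + 2],
        params[2 * k + 3],
        params[2 * k + 4],
    )


def _objective(params: np.ndarray, S: np.ndarray, logdet_s: float, k: int):
    lam, psi, phi_cov, var_c, beta, gamma, sy2 = _unpack(params, k)
    sigma = implied_covariance(lam, psi, phi_cov, var_c, beta, gamma, sy2)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(params)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + np.sum(S * sigma_inv) - logdet_s - (k + 2)

    # dF = tr(A dSigma), A = Sigma^-1 (Sigma - S) Sigma^-1
    A = sigma_inv @ (sigma - S) @ sigma_inv
    Axx, axc, axy = A[:k, :k], A[:k, k], A[:k, k + 1]
    acc, acy, ayy = A[k, k], A[k, k + 1], A[k + 1, k + 1]
    cov_ty = beta + gamma * phi_cov
    g_lam = 2.0 * (Axx @ lam) + 2.0 * axc * phi_cov + 2.0 * axy * cov_ty
    g_psi = np.diag(Axx).copy()
    g_phi = 2.0 * (axc @ lam) + 2.0 * acy * beta + 2.0 * gamma * (axy @ lam) + 2.0 * beta * gamma * ayy
    g_vc = acc + 2.0 * acy * gamma + ayy * gamma**2
    g_beta = 2.0 * (axy @ lam) + 2.0 * acy * phi_cov + ayy * (2.0 * beta + 2.0 * gamma * phi_cov)
    g_gamma = (
        2.0 * (axy @ lam) * phi_cov
        + 2.0 * acy * var_c
        + ayy * (2.0 * gamma * var_c + 2.0 * beta * phi_cov)
    )
    g_sy2 = ayy
    grad = np.concatenate([g_lam, g_psi, [g_phi, g_vc, g_beta, g_gamma, g_sy2]])
    return f, grad


def _start_values(S: np.ndarray, k: int) -> np.ndarray:
    """Measurement starts from a quick CFA on the item block; structural
    starts from the regression of Y on (scaled item mean, C)."""
    from scorebias.ctt_scores import _cfa_objective

    Sxx = S[:k, :k]
    x0 = np.concatenate([np.full(k, 0.5), np.full(k, 0.75)])
    res = optimize.minimize(
        _cfa_objective, x0, args=(Sxx, k), jac=True, method="L-BFGS-B",
        bounds=[(None, None)] * k + [(_PSI_FLOOR, None)] * k,
        options={"maxiter": 200},
    )
    lam0, psi0 = res.x[:k], res.x[k:]
    if lam0.sum() < 0:
        lam0 = -lam0
    # proxy score: item mean scaled to unit variance
    w = np.ones(k) / k
    var_m = w @ Sxx @ w
    sd_m = np.sqrt(max(var_m, 1e-8))
    cov_m = S[:k, k:] .T @ w / sd_m  # cov of scaled mean with (C, Y)
    phi0 = float(np.clip(cov_m[0], -0.9, 0.9))
    var_c = S[k, k]
    # OLS of Y on (proxy, C)
    G = np.array([[1.0, cov_m[0]], [cov_m[0], var_c]])
    h = np.array([cov_m[1], S[k, k + 1]])
    try:
        bg = np.linalg.solve(G, h)
    except np.linalg.LinAlgError:
        bg = np.array([0.3, 0.3])
    sy2 = max(S[k + 1, k + 1] - bg @ h, 0.05)
    return np.concatenate([lam0, psi0, [phi0, var_c, bg[0], bg[1], sy2]])


def fit_sem_cov(S: np.ndarray, k: int, n_restarts: int = 1) -> SemFit:
    """Fit the SEM to a covariance matrix over (X_1..X_k, C, Y)."""
    S = np.asarray(S, dtype=float)
    if S.shape != (k + 2, k + 2):
        raise ValueError("covariance must be (k+2) x (k+2) over items, C, Y")
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance must be positive definite")
    bounds = (
        [(None, None)] * k
        + [(_PSI_FLOOR, None)] * k
        + [(None, None), (1e-6, None), (None, None), (None, None), (1e-6, None)]
    )
    x0 = _start_values(S, k)
    best = None
    rng = np.random.Generator(np.random.Philox(20210679))
    for attempt in range(1 + n_restarts):
        start = x0 if attempt == 0 else x0 * (1 + 0.1 * rng.standard_normal(x0.shape))
        start = np.clip(start, [b[0] if b[0] is not None else -np.inf for b in bounds],
                        [b[1] if b[1] is not None else np.inf for b in bounds])
        res = optimize.minimize(
            _objective, start, args=(S, logdet_s, k), jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and res.fun < 1e8:
            best = res
            break
    lam, psi, phi_cov, var_c, beta, gamma, sy2 = _unpack(best.x, k)
    if lam.sum() < 0:  # orient the factor positively
        lam, phi_cov, beta = -lam, -phi_cov, -beta
    return SemFit(
        loadings=lam.copy(),
        residuals=psi.copy(),
        theta_cov_corr=float(phi_cov / np.sqrt(var_c)),
        beta_hat=float(beta),
        gamma_hat=float(gamma),
        y_residual=float(sy2),
        discrepancy=float(best.fun),
        converged=bool(best.success),
        var_c=float(var_c),
    )


def fit_sem(items: np.ndarray, covariate: np.ndarray, outcome: np.ndarray) -> SemFit:
    """Fit the SEM to raw data: k >= 3 items, observed covariate and outcome."""
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if k < 3:
        raise ValueError("SEM needs k >= 3 items for identification")
    data = np.column_stack([items, np.asarray(covariate, float), np.asarray(outcome, float)])
    S = np.cov(data, rowvar=False, ddof=1)
    return fit_sem_cov(S, k)
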