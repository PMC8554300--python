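"""Plausible values: latent-regression GPCM conditioning model, posterior
draws, and Rubin's-rules pooling of per-draw regression fits.

The conditioning ("background") model replaces the N(0,1) prior of the plain
GPCM calibration with a person-specific prior g(theta | c_i) =
N(mu + beta'c_i, sigma2).  Item and conditioning parameters are estimated by
marginal ML via EM; the latent metric is renormalized each iteration so the
marginal of theta keeps mean 0 and variance 1, which identifies the jointly
estimated model on the same scale as the plain calibration.  Plausible
values are then m independent draws per person from the discrete quadrature
posterior proportional to L(x_i | theta) g(theta | c_i), with a uniform
jitter inside the node spacing; parameters stay fixed at their ML estimates
while drawing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from scorebias.irt_scores import (
    GPCMParams,
    NODES,
    NODE_SPACING,
    N_NODES,
    _fit_em,
    _log_prob_table,
    _onehot,
    _recode_items,
    _steps_from_xi,
)

DEFAULT_N_PV = 10


@dataclass
class LatentRegressionModel:
    """GPCM measurement model plus the latent-regression conditioning model."""

    item_params: GPCMParams
    cond_coefs: np.ndarray  # (p + 1,): intercept mu then slopes
    residual_var: float
    background_names: list

    def __post_init__(self) -> None:
        if self.residual_var <= 0:
            raise ValueError("conditioning residual variance must be positive")

    def prior_means(self, background: np.ndarray) -> np.ndarray:
        B = np.asarray(background, dtype=float)
        if B.ndim == 1:
            B = B[:, None]
        return self.cond_coefs[0] + B @ self.cond_coefs[1:]


@dataclass
class PVDraws:
    """n x m matrix of plausible values for one sample."""

    draws: np.ndarray
    seed: int
    model_ref: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("plausible values must be finite")

    @property
    def m(self) -> int:
        return self.draws.shape[1]


@dataclass
class PooledFit:
    """Rubin's-rules pooled estimates over m imputation fits."""

    coef: np.ndarray
    within_var: np.ndarray
    between_var: np.ndarray
    total_var: np.ndarray
    m: int


def fit_latent_regression(
    items: np.ndarray,
    background: np.ndarray,
    background_names: Sequence[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> LatentRegressionModel:
    """Jointly estimate GPCM item parameters and the conditioning model.

    ``background`` is an n x p full-column-rank matrix (an intercept is added
    internally).  Returns the fitted model with theta's marginal standardized
    to mean 0, variance 1.
    """
    B = np.asarray(background, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    codes, n_cats, cat_maps, collapsed = _recode_items(items)
    a, xi, loglik, history, converged, latent = _fit_em(
        codes, n_cats, background=B, max_iter=max_iter, tol=tol
    )
    mu, beta, sigma2 = latent
    params = GPCMParams(
        discriminations=a,
        steps=_steps_from_xi(a, xi, n_cats),
        xi=xi,
        n_cats=n_cats,
        cat_maps=cat_maps,
        loglik=loglik,
        converged=converged,
        collapsed=collapsed,
        loglik_history=history,
    )
    names = list(background_names) if background_names is not None else [
        f"bg_{i + 1}" for i in range(B.shape[1])
    ]
    return LatentRegressionModel(
        item_params=params,
        cond_coefs=np.concatenate([[mu], beta]),
        residual_var=float(sigma2),
        background_names=names,
    )


def _posterior_over_nodes(model: LatentRegressionModel, items, background) -> np.ndarray:
    """Discrete posterior P(theta_q | x_i, c_i) per person, shape (n, Q)."""
    p = model.item_params
    codes = p.recode(items)
    oh = _onehot(codes)
    logp = _log_prob_table(p.discriminations, p.xi, NODES)
    ll_nodes = oh @ logp.transpose(1, 0, 2).reshape(N_NODES, p.k * 5).T
    m_i = model.prior_means(background)
    log_prior = -0.5 * (NODES[None, :] - m_i[:, None]) ** 2 / model.residual_var
    joint = ll_nodes + log_prior
    return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))


def draw_pv(
    model: LatentRegressionModel,
    items: np.ndarray,
    background: np.ndarray,
    m: int = DEFAULT_N_PV,
    seed: int = 0,
) -> PVDraws:
    """Draw m plausible values per person from the conditioning posterior.

    Draws are taken column by column from a counter-based stream, so the
    first column is identical for any m given the same seed.  Each draw
    selects a quadrature node from the discrete posterior and adds a uniform
    jitter within the node spacing.
    """
    if m < 1:
        raise ValueError("need at least one plausible value")
    post = _posterior_over_nodes(model, items, background)
    cdf = np.cumsum(post, axis=1)
    cdf[:, -1] = 1.0
    n = post.shape[0]
    rng = np.random.Generator(np.random.Philox(int(seed)))
    draws = np.empty((n, m))
    for col in range(m):
        u = rng.random(n)
        idx = (cdf < u[:, None]).sum(axis=1)
        jitter = rng.uniform(-0.5, 0.5, n) * NODE_SPACING
        draws[:, col] = NODES[idx] + jitter
    return PVDraws(draws=draws, seed=int(seed))


def pool_rubin(fits: Sequence[tuple]) -> PooledFit:
    """Pool m regression fits by Rubin's rules.

    Each fit is a (coef, squared_se) pair of equal-length arrays.  Pooled
    point estimate is the mean; within-imputation variance W the mean of the
    squared SEs; between-imputation variance B the (n-1)-denominator sample
    variance of the estimates; total variance T = W + (1 + 1/m) B.
    """
    if len(fits) < 2:
        raise ValueError("Rubin pooling needs at least two fits")
    coefs = np.asarray([np.asarray(c, float) for c, _ in fits])
    sq_ses = np.asarray([np.asarray(v, float) for _, v in fits])
    if coefs.shape != sq_ses.shape:
        raise ValueError("coefficient and squared-SE layouts must match")
    m = coefs.shape[0]
    qbar = coefs.mean(axis=0)
    W = sq_ses.mean(axis=0)
    B = coefs.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    return PooledFit(coef=qbar, within_var=W, between_var=B, total_var=T, m=m)
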