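"""Polytomous IRT: the generalized partial credit model (GPCM), its marginal
maximum-likelihood estimation, and WLE / EAP / posterior-mode person scores.

The GPCM gives category probabilities

    P(c | theta) = exp(sum_{t<=c} a (theta - b_t)) / normalizer,  c = 0..r-1,

with discrimination a > 0 and step parameters b_t.  Writing the cumulative
step sums as free category intercepts xi_c = -a * sum_{t<=c} b_t turns the
model into a log-linear (exponential-family) form  P(c|theta) ∝
exp(xi_c + a*c*theta), which this module exploits twice: the M-step of the
EM algorithm is a concave Newton problem solved batched across items, and
the person log-likelihood depends on the response pattern only through the
weighted score T_i = sum_j a_j x_ij, so scoring collapses to the unique
values of T.

Estimation integrates over a N(0,1) latent density with 41 equally spaced
quadrature nodes on [-6, 6] (rectangular quadrature, density weights
renormalized to sum to one).  Categories that are unobserved in a sample are
collapsed into their lower neighbor, the replication is flagged, and scoring
proceeds on the collapsed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, log_softmax, softmax

from scorebias.ctt_scores import ScoreVector

N_NODES = 41
THETA_BOUNDS = (-6.0, 6.0)
NODES = np.linspace(*THETA_BOUNDS, N_NODES)
NODE_SPACING = NODES[1] - NODES[0]
_NEG = -1e10  # stand-in for -inf that survives arithmetic

EM_TOL = 1e-4
EM_MAX_ITER = 500


def _prior_weights(mean: float = 0.0, var: float = 1.0) -> np.ndarray:
    w = np.exp(-0.5 * (NODES - mean) ** 2 / var)
    return w / w.sum()


@dataclass
class GPCMParams:
    """Fitted GPCM item parameters plus the latent prior and quadrature."""

    discriminations: np.ndarray  # (k,)
    steps: np.ndarray  # (k, 4), NaN-padded when categories were collapsed
    xi: np.ndarray  # (k, 5) category intercepts, xi[:, 0] = 0, _NEG padding
    n_cats: np.ndarray  # (k,) observed category counts after collapsing
    cat_maps: np.ndarray  # (k, 5) original 0-based category -> collapsed code
    loglik: float
    converged: bool
    latent_mean: float = 0.0
    latent_var: float = 1.0
    collapsed: bool = False
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    nodes: np.ndarray = field(default_factory=lambda: NODES.copy())

    @property
    def weights(self) -> np.ndarray:
        return _prior_weights(self.latent_mean, self.latent_var)

    @property
    def k(self) -> int:
        return self.discriminations.shape[0]

    def recode(self, items: np.ndarray) -> np.ndarray:
        """Map raw 1..5 responses to the (possibly collapsed) 0-based codes."""
        items = np.asarray(items, dtype=int)
        cols = np.arange(self.k)
        return self.cat_maps[cols[None, :], items - 1]


def gpcm_category_probs(a: float, b: np.ndarray, theta) -> np.ndarray:
    """GPCM category probabilities at ability ``theta``.

    ``b`` holds the r-1 step parameters of an r-category item.  Returns an
    array of shape (..., r) summing to one; stabilized through log-sum-exp.
    """
    if a <= 0:
        raise ValueError("discrimination must be positive")
    b = np.asarray(b, dtype=float)
    theta = np.asarray(theta, dtype=float)
    steps = a * (theta[..., None] - b)  # (..., r-1)
    cum = np.concatenate([np.zeros(theta.shape + (1,)), np.cumsum(steps, axis=-1)], axis=-1)
    return softmax(cum, axis=-1)


# ---------------------------------------------------------------------------
# internal fitting machinery (shared with the latent-regression model)
# ---------------------------------------------------------------------------

def _recode_items(items: np.ndarray):
    """0-base responses, collapsing unobserved categories into the neighbor below.

    Returns (codes, n_cats, cat_maps, collapsed_flag).
    """
    items = np.asarray(items, dtype=int)
    if items.ndim != 2:
        raise ValueError("items must be an n x k matrix")
    n, k = items.shape
    raw = items - 1
    if raw.min() < 0 or raw.max() > 4:
        raise ValueError("item responses must lie in 1..5")
    codes = np.zeros_like(raw)
    n_cats = np.zeros(k, dtype=int)
    cat_maps = np.zeros((k, 5), dtype=int)
    collapsed = False
    for j in range(k):
        observed = np.zeros(5, dtype=bool)
        observed[np.unique(raw[:, j])] = True
        m = int(observed.sum())
        if m < 2:
            raise ValueError(f"item {j + 1} shows a single response category")
        if m < 5:
            collapsed = True
        # map each original category to the rank of the nearest observed
        # category at or below it (category 0 is observed or mapped up)
        ranks = np.cumsum(observed) - 1  # rank of the last observed cat <= c
        ranks = np.maximum(ranks, 0)
        cat_maps[j] = ranks
        codes[:, j] = ranks[raw[:, j]]
        n_cats[j] = m
    return codes, n_cats, cat_maps, collapsed


def _log_prob_table(a: np.ndarray, xi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """log P(c | theta) for every (item, theta, category): shape (k, m, 5)."""
    scores = np.arange(5.0)
    logits = xi[:, None, :] + a[:, None, None] * scores[None, None, :] * theta[None, :, None]
    return log_softmax(logits, axis=-1)


def _onehot(codes: np.ndarray) -> np.ndarray:
    n, k = codes.shape
    oh = np.zeros((n, k * 5))
    cols = (np.arange(k) * 5)[None, :] + codes
    oh[np.arange(n)[:, None], cols] = 1.0
    return oh


def _expected_q(R: np.ndarray, logp: np.ndarray) -> np.ndarray:
    """Per-item expected complete-data log-likelihood Q_j = sum R * log p."""
    return np.where(R > 0, R * np.maximum(logp, _NEG), 0.0).sum(axis=(1, 2))


def _mstep_items(R: np.ndarray, a: np.ndarray, xi: np.ndarray, n_cats: np.ndarray,
                 n_newton: int = 3):
    """Batched Newton ascent of the expected GPCM log-likelihood per item.

    The objective is concave in (a, xi_1..xi_4) (log-linear model); invalid
    (collapsed-away) intercepts are frozen through masked Hessian rows.
    """
    k = a.shape[0]
    scores = np.arange(5.0)
    valid = scores[None, :] < n_cats[:, None]  # (k, 5)
    sobs_a = np.einsum("kqc,q,c->k", R, NODES, scores)  # constant across Newton steps
    r_cat = R.sum(axis=1)  # (k, 5)
    for _ in range(n_newton):
        logp = _log_prob_table(a, xi, NODES)
        p = np.exp(logp)
        n_q = R.sum(axis=2)  # (k, Q)
        sbar = np.einsum("kqc,c->kq", p, scores)
        s2bar = np.einsum("kqc,c->kq", p, scores**2)
        svar = s2bar - sbar**2
        grad_a = sobs_a - np.einsum("kq,q,kq->k", n_q, NODES, sbar)
        grad_xi = r_cat - np.einsum("kq,kqc->kc", n_q, p)
        h_aa = -np.einsum("kq,q,kq->k", n_q, NODES**2, svar)
        h_axi = -np.einsum("kq,q,kqc->kc", n_q, NODES, p * (scores[None, None, :] - sbar[:, :, None]))
        h_xx = -(
            np.einsum("kq,kqc,cd->kcd", n_q, p, np.eye(5))
            - np.einsum("kq,kqc,kqd->kcd", n_q, p, p)
        )
        grad = np.zeros((k, 5))
        grad[:, 0] = grad_a
        grad[:, 1:] = grad_xi[:, 1:]
        hess = np.zeros((k, 5, 5))
        hess[:, 0, 0] = h_aa
        hess[:, 0, 1:] = h_axi[:, 1:]
        hess[:, 1:, 0] = h_axi[:, 1:]
        hess[:, 1:, 1:] = h_xx[:, 1:, 1:]
        # freeze intercepts of collapsed-away categories
        mask = np.ones((k, 5), dtype=bool)
        mask[:, 1:] = valid[:, 1:]
        grad[~mask] = 0.0
        for c in range(1, 5):
            off = ~mask[:, c]
            hess[off, c, :] = 0.0
            hess[off, :, c] = 0.0
            hess[off, c, c] = -1.0
        hess -= 1e-9 * np.eye(5)[None]
        delta = np.clip(np.linalg.solve(-hess, grad[..., None])[..., 0], -2.0, 2.0)

        q_old = _expected_q(R, logp)
        step = np.ones(k)
        for _ in range(12):  # per-item step halving guard
            a_new = np.maximum(a + step * delta[:, 0], 1e-2)
            xi_new = xi.copy()
            xi_new[:, 1:] = np.where(valid[:, 1:], xi[:, 1:] + step[:, None] * delta[:, 1:], xi[:, 1:])
            q_new = _expected_q(R, _log_prob_table(a_new, xi_new, NODES))
            bad = q_new < q_old - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        a, xi = a_new, xi_new
    return a, xi


def _init_params(codes: np.ndarray, n_cats: np.ndarray):
    """Start values: unit discriminations, intercepts from category frequencies."""
    n, k = codes.shape
    a = np.ones(k)
    xi = np.full((k, 5), _NEG)
    xi[:, 0] = 0.0
    for j in range(k):
        freq = np.bincount(codes[:, j], minlength=5).astype(float)
        m = n_cats[j]
        logf = np.log(np.maximum(freq[:m], 0.5)) - np.log(max(freq[0], 0.5))
        xi[j, 1:m] = logf[1:]
    return a, xi


def _fit_em(codes, n_cats, background=None, max_iter=EM_MAX_ITER, tol=EM_TOL):
    """Shared EM loop for the plain GPCM and the latent-regression GPCM.

    With ``background`` (an n x p matrix), each person's prior is
    N(mu + beta'c_i, sigma2); after every M-step the latent metric is
    renormalized so the marginal of theta keeps mean 0 and variance 1 (the
    same identification as the N(0,1) prior of the plain fit).
    """
    n, k = codes.shape
    a, xi = _init_params(codes, n_cats)
    oh = _onehot(codes)
    latent = None
    if background is not None:
        B = np.asarray(background, dtype=float)
        if B.ndim == 1:
            B = B[:, None]
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), B])) < B.shape[1] + 1:
            raise ValueError("background matrix is rank deficient")
        mu, beta, sigma2 = 0.0, np.zeros(B.shape[1]), 1.0
        design = np.column_stack([np.ones(n), B])
        gram_inv = np.linalg.inv(design.T @ design)
    log_w0 = np.log(_prior_weights())

    history = []
    converged = False
    for _ in range(max_iter):
        logp = _log_prob_table(a, xi, NODES)
        ll_nodes = oh @ logp.transpose(1, 0, 2).reshape(N_NODES, k * 5).T  # (n, Q)
        if background is None:
            log_prior = log_w0[None, :]
        else:
            m_i = mu + B @ beta
            lp = -0.5 * (NODES[None, :] - m_i[:, None]) ** 2 / sigma2
            log_prior = lp - logsumexp(lp, axis=1, keepdims=True)
        joint = ll_nodes + log_prior
        ll_i = logsumexp(joint, axis=1)
        history.append(float(ll_i.sum()))
        W = np.exp(joint - ll_i[:, None])

        R = (W.T @ oh).reshape(N_NODES, k, 5).transpose(1, 0, 2)
        a_new, xi_new = _mstep_items(R, a.copy(), xi.copy(), n_cats)

        if background is None:
            change = max(
                np.abs(a_new - a).max(),
                np.abs(np.where(xi > _NEG / 2, xi_new - xi, 0.0)).max(),
            )
            a, xi = a_new, xi_new
        else:
            theta_bar = W @ NODES
            theta_var = W @ NODES**2 - theta_bar**2
            coefs = gram_inv @ (design.T @ theta_bar)
            fitted = design @ coefs
            sigma2_new = float(np.mean(theta_var + (theta_bar - fitted) ** 2))
            mu_new, beta_new = float(coefs[0]), coefs[1:]
            # renormalize the latent metric: marginal theta stays N(0, 1)
            t = float(fitted.mean())
            s = float(np.sqrt(fitted.var() + sigma2_new))
            a_scaled = a_new * s
            xi_scaled = xi_new + np.arange(5.0)[None, :] * a_new[:, None] * t
            xi_scaled[xi_new < _NEG / 2] = _NEG
            xi_scaled[:, 0] = 0.0
            mu_scaled = (mu_new - t) / s
            beta_scaled = beta_new / s
            sigma2_scaled = sigma2_new / s**2
            change = max(
                np.abs(a_scaled - a).max(),
                np.abs(np.where(xi > _NEG / 2, xi_scaled - xi, 0.0)).max(),
                abs(mu_scaled - mu),
                np.abs(beta_scaled - beta).max(),
                abs(sigma2_scaled - sigma2),
            )
            a, xi = a_scaled, xi_scaled
            mu, beta, sigma2 = mu_scaled, beta_scaled, sigma2_scaled
        if change < tol:
            converged = True
            break

    if background is not None:
        latent = (mu, beta, sigma2)
    return a, xi, float(history[-1]), np.asarray(history), converged, latent


def _steps_from_xi(a: np.ndarray, xi: np.ndarray, n_cats: np.ndarray) -> np.ndarray:
    steps = np.full((a.shape[0], 4), np.nan)
    for j in range(a.shape[0]):
        m = n_cats[j]
        steps[j, : m - 1] = (xi[j, : m - 1] - xi[j, 1:m]) / a[j]
    return steps


def fit_gpcm(items: np.ndarray, max_iter: int = EM_MAX_ITER, tol: float = EM_TOL) -> GPCMParams:
    """Fit the GPCM by marginal ML (EM over quadrature) with a N(0,1) prior.

    Deterministic given the data.  Categories unobserved in the sample are
    collapsed into their lower neighbor and the fit is flagged via
    ``collapsed``; non-convergence after the iteration cap is flagged via
    ``converged``.
    """
    codes, n_cats, cat_maps, collapsed = _recode_items(items)
    a, xi, loglik, history, converged, _ = _fit_em(codes, n_cats, None, max_iter, tol)
    return GPCMParams(
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


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _log_normalizer(params: GPCMParams, theta: np.ndarray) -> np.ndarray:
    """G(theta) = sum_j log Z_j(theta) for arbitrary theta values."""
    scores = np.arange(5.0)
    logits = (
        params.xi[:, None, :]
        + params.discriminations[:, None, None] * scores[None, None, :] * theta[None, :, None]
    )
    return logsumexp(logits, axis=-1).sum(axis=0)


def _golden_max(fun, lo: np.ndarray, hi: np.ndarray, tol: float = 1e-5) -> np.ndarray:
    """Vectorized golden-section maximization on per-element brackets.

    Classic four-point scheme: one new function evaluation per iteration.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    invphi2 = invphi**2
    a, b = lo.copy(), hi.copy()
    h = b - a
    c = a + invphi2 * h
    d = a + invphi * h
    fc, fd = fun(c), fun(d)
    span = float(np.max(h)) if h.size else 0.0
    n_iter = max(int(np.ceil(np.log(tol / max(span, tol)) / np.log(invphi))), 1)
    for _ in range(n_iter):
        left = fc >= fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        h = b - a
        c = a + invphi2 * h
        d = a + invphi * h
        x = np.where(left, c, d)
        fx = fun(x)
        fc, fd = np.where(left, fx, fd), np.where(left, fc, fx)
    return 0.5 * (a + b)


def _suff_stats(params: GPCMParams, items: np.ndarray):
    codes = params.recode(items)
    T = codes @ params.discriminations
    uniq, inverse = np.unique(T, return_inverse=True)
    return uniq, inverse


def _objective_parts(params: GPCMParams, theta: np.ndarray, need_info: bool):
    """G(theta) = sum_j log Z_j and (optionally) test information, one fused pass."""
    scores = np.arange(5.0)
    logits = (
        params.xi[:, None, :]
        + params.discriminations[:, None, None] * scores[None, None, :] * theta[None, :, None]
    )
    mx = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - mx)
    z = e.sum(axis=-1)
    G = (np.log(z) + mx[..., 0]).sum(axis=0)
    if not need_info:
        return G, None
    p = e / z[..., None]
    sbar = p @ scores
    svar = p @ scores**2 - sbar**2
    info = (params.discriminations[:, None] ** 2 * svar).sum(axis=0)
    return G, info


def _maximize_scores(params: GPCMParams, items: np.ndarray, mode: str) -> np.ndarray:
    """argmax over theta of T*theta - G(theta) + penalty(theta), per person.

    Grid scan at 0.1 resolution on [-6, 6] followed by golden-section
    refinement of the best node's bracket.  The penalty is half the log test
    information for the WLE and the log normal prior for the posterior mode.
    """
    uniq, inverse = _suff_stats(params, items)

    def objective(theta):
        G, info = _objective_parts(params, theta, need_info=(mode == "wle"))
        if mode == "wle":
            return -G + 0.5 * np.log(np.maximum(info, 1e-300))
        return -G - 0.5 * (theta - params.latent_mean) ** 2 / params.latent_var

    grid = np.linspace(*THETA_BOUNDS, 121)
    base = objective(grid)
    best = grid[np.argmax(uniq[:, None] * grid[None, :] + base[None, :], axis=1)]
    lo = np.clip(best - 0.1, *THETA_BOUNDS)
    hi = np.clip(best + 0.1, *THETA_BOUNDS)
    refined = _golden_max(lambda th: uniq * th + objective(th), lo, hi)
    return refined[inverse]


def test_information(params: GPCMParams, theta) -> np.ndarray:
    """Fisher test information sum_j a_j^2 Var(s_j | theta) of the GPCM."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    return _objective_parts(params, theta, need_info=True)[1]


def wle(params: GPCMParams, items: np.ndarray) -> ScoreVector:
    """Warm's weighted likelihood estimate: argmax log L + 0.5 log I(theta).

    The information weight keeps the maximizer finite for every response
    pattern, including all-lowest and all-highest.
    """
    return ScoreVector(method="WLE", values=_maximize_scores(params, items, "wle"),
                       standardized=False)


def eap(params: GPCMParams, items: np.ndarray) -> ScoreVector:
    """Expected a posteriori: posterior mean of theta over the quadrature grid."""
    uniq, inverse = _suff_stats(params, items)
    log_post = (
        uniq[:, None] * NODES[None, :]
        - _log_normalizer(params, NODES)[None, :]
        + np.log(params.weights)[None, :]
    )
    post = softmax(log_post, axis=1)
    return ScoreVector(method="EAP", values=(post @ NODES)[inverse], standardized=False)


def ebm(params: GPCMParams, items: np.ndarray) -> ScoreVector:
    """Empirical Bayes modal (MAP) score: posterior mode under the normal prior."""
    return ScoreVector(method="EBM", values=_maximize_scores(params, items, "ebm"),
                       standardized=False)
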