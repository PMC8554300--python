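"""Deterministic micro-datasets with brute-force oracle values.

Each fixture is self-contained: a tiny response matrix, parameters fixed in
code, and expected values recomputed at build time by oracles that are
independent of the estimation/optimization paths they check (dense grid
search for the IRT scores, explicit normal-equation solves for OLS).  The
grid oracles use a 1e-4 theta resolution on [-6, 6], an order of magnitude
finer than any assertion tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORACLE_GRID = np.arange(-6.0, 6.0 + 1e-12, 1e-4)


@dataclass
class Fixture:
    name: str
    items: np.ndarray
    known_params: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def _oracle_log_like(a, b, theta, responses):
    """Direct GPCM log-likelihood of one response pattern on a theta grid.

    Written independently of the package's log-linear machinery: explicit
    cumulative sums of a(theta - b_t) per item, normalized by brute force.
    """
    total = np.zeros_like(theta)
    for a_j, b_j, x_j in zip(a, b, responses):
        steps = a_j * (theta[:, None] - np.asarray(b_j)[None, :])
        cum = np.concatenate([np.zeros((theta.size, 1)), np.cumsum(steps, axis=1)], axis=1)
        cum -= cum.max(axis=1, keepdims=True)
        logz = np.log(np.exp(cum).sum(axis=1))
        total += cum[:, x_j] - logz
    return total


def _oracle_information(a, b, theta):
    info = np.zeros_like(theta)
    for a_j, b_j in zip(a, b):
        steps = a_j * (theta[:, None] - np.asarray(b_j)[None, :])
        cum = np.concatenate([np.zeros((theta.size, 1)), np.cumsum(steps, axis=1)], axis=1)
        cum -= cum.max(axis=1, keepdims=True)
        p = np.exp(cum)
        p /= p.sum(axis=1, keepdims=True)
        s = np.arange(p.shape[1])
        sbar = p @ s
        info += a_j**2 * (p @ s**2 - sbar**2)
    return info


def toy_gpcm() -> Fixture:
    """Three 5-category items with fixed parameters and grid-oracle scores.

    Discriminations (1.0, 1.5, 0.8); symmetric steps (-1.5, -0.5, 0.5, 1.5)
    for every item.  Expected WLE / EAP / EBM values for each pattern are
    recomputed here by dense grid search / quadrature over ORACLE_GRID.
    """
    a = np.array([1.0, 1.5, 0.8])
    b = [np.array([-1.5, -0.5, 0.5, 1.5])] * 3
    patterns = np.array(
        [
            [3, 3, 3],
            [1, 1, 1],
            [5, 5, 5],
            [2, 3, 4],
            [1, 3, 5],
            [4, 4, 2],
            [5, 1, 3],
            [2, 2, 2],
        ]
    )
    theta = ORACLE_GRID
    log_prior = -0.5 * theta**2
    expected = {"wle": [], "eap": [], "ebm": []}
    for row in patterns:
        ll = _oracle_log_like(a, b, theta, row - 1)
        info = _oracle_information(a, b, theta)
        expected["wle"].append(theta[np.argmax(ll + 0.5 * np.log(info))])
        post = np.exp(ll + log_prior - (ll + log_prior).max())
        expected["eap"].append(float((theta * post).sum() / post.sum()))
        expected["ebm"].append(theta[np.argmax(ll + log_prior)])
    return Fixture(
        name="toy_gpcm",
        items=patterns,
        known_params={"a": a, "b": np.vstack(b)},
        expected={k: np.asarray(v) for k, v in expected.items()},
    )


def toy_regression() -> Fixture:
    """Five observations with hand-solvable normal equations.

    The exact-fit outcome y = 2 + 0.5*x1 - x2 has zero residuals; the noisy
    outcome's coefficients come from an explicit 3x3 normal-equation solve
    performed here, independent of the package's OLS routine.
    """
    x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    x2 = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
    y_exact = 2.0 + 0.5 * x1 - x2
    y_noisy = y_exact + np.array([0.1, -0.2, 0.05, 0.15, -0.1])
    X = np.column_stack([np.ones(5), x1, x2])
    coef_noisy = np.linalg.solve(X.T @ X, X.T @ y_noisy)
    return Fixture(
        name="toy_regression",
        items=np.column_stack([x1, x2]).astype(int),
        known_params={"design": X, "y_exact": y_exact, "y_noisy": y_noisy},
        expected={"coef_exact": np.array([2.0, 0.5, -1.0]), "coef_noisy": coef_noisy},
    )
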