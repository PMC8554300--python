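"""Population model and data generator for one simulation replication.

The generating model: a standard-normal latent skill theta, measured by k
congeneric continuous indicators X*_j = lambda_j * theta + eps_j with unit
total variance, which are then cut at (-1.5, -0.5, 0.5, 1.5) into five
ordinal categories forming a symmetric bell-shaped histogram.  A covariate C
correlates 0.30 with theta.  Two outcomes are generated from (theta, C):
Y1 with the skill the stronger predictor (beta=0.35 > gamma=0.30) and Y2
with the skill the weaker one (beta=0.20 < gamma=0.30).  Outcome residual
variances are set so Var(Y1) = Var(Y2) = 1 exactly, which makes the
generating coefficients equal to their population-standardized versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scorebias.design_grid import DesignCondition

PHI = 0.30
THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)
#: (beta, gamma) of the analyzed outcome: skill-stronger uses Y1, skill-weaker Y2.
STRUCTURAL_COEFS = {"stronger": (0.35, 0.30), "weaker": (0.20, 0.30)}


@dataclass(frozen=True)
class PopulationParams:
    """Generating parameters of one design condition's population."""

    lambdas: np.ndarray
    phi: float = PHI
    beta1: float = 0.35
    gamma1: float = 0.30
    beta2: float = 0.20
    gamma2: float = 0.30
    thresholds: tuple = THRESHOLDS

    def __post_init__(self) -> None:
        if not (self.beta1 > self.gamma1 and self.beta2 < self.gamma2):
            raise ValueError("need beta1 > gamma1 (stronger) and beta2 < gamma2 (weaker)")
        t = np.asarray(self.thresholds)
        if not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")

    @staticmethod
    def _resid(beta: float, gamma: float) -> float:
        resid = 1.0 - beta**2 - gamma**2 - 2.0 * beta * gamma * PHI
        if resid <= 0:
            raise ValueError("structural coefficients imply non-positive outcome residual")
        return resid

    @property
    def sigma2_y1(self) -> float:
        return self._resid(self.beta1, self.gamma1)

    @property
    def sigma2_y2(self) -> float:
        return self._resid(self.beta2, self.gamma2)

    def analyzed_coefs(self, rsro: str) -> tuple[float, float]:
        """(beta, gamma) of the outcome analyzed under this rsro level."""
        if rsro == "stronger":
            return self.beta1, self.gamma1
        if rsro == "weaker":
            return self.beta2, self.gamma2
        raise ValueError(f"unknown rsro {rsro!r}")


@dataclass(frozen=True)
class SimulatedSample:
    """One replication's data: true skill, ordinal items, covariate, outcomes."""

    theta: np.ndarray
    items: np.ndarray  # n x k integers in 1..5
    covariate: np.ndarray
    y1: np.ndarray
    y2: np.ndarray

    def __post_init__(self) -> None:
        n = self.theta.shape[0]
        if self.items.shape[0] != n or any(
            v.shape[0] != n for v in (self.covariate, self.y1, self.y2)
        ):
            raise ValueError("all sample components must share the person dimension")
        if self.items.min() < 1 or self.items.max() > 5:
            raise ValueError("item responses must lie in 1..5")

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    @property
    def k(self) -> int:
        return self.items.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"theta": self.theta})
        for j in range(self.k):
            df[f"item_{j + 1}"] = self.items[:, j]
        df["covariate"] = self.covariate
        df["y1"] = self.y1
        df["y2"] = self.y2
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimulatedSample":
        item_cols = [c for c in df.columns if c.startswith("item_")]
        return cls(
            theta=df["theta"].to_numpy(float),
            items=df[item_cols].to_numpy(int),
            covariate=df["covariate"].to_numpy(float),
            y1=df["y1"].to_numpy(float),
            y2=df["y2"].to_numpy(float),
        )


def population_params(cond: DesignCondition) -> PopulationParams:
    """Generating population parameters for one design condition."""
    return PopulationParams(lambdas=cond.lambdas)


def population_covariance(cond: DesignCondition) -> pd.DataFrame:
    """Exact model-implied covariance of the pre-categorization variables.

    Rows/columns: X*_1..X*_k (continuous indicators), C, Y1, Y2, theta.
    All variances are 1 by construction, so this is also the correlation
    matrix.  Used as the oracle against sample moments and for SEM recovery
    tests.
    """
    p = population_params(cond)
    lam = p.lambdas
    k = lam.shape[0]
    names = [f"x{j + 1}" for j in range(k)] + ["c", "y1", "y2", "theta"]
    m = k + 4
    cov = np.zeros((m, m))
    ic, iy1, iy2, ith = k, k + 1, k + 2, k + 3

    # indicators: X*_j = lambda_j theta + eps_j, Var = 1
    cov[:k, :k] = np.outer(lam, lam)
    np.fill_diagonal(cov[:k, :k], 1.0)
    cov[:k, ith] = cov[ith, :k] = lam
    cov[:k, ic] = cov[ic, :k] = lam * p.phi
    # path-traced indicator-outcome covariances
    cy1_th = p.beta1 + p.gamma1 * p.phi  # cov(theta, Y1)
    cy2_th = p.beta2 + p.gamma2 * p.phi
    cy1_c = p.gamma1 + p.beta1 * p.phi  # cov(C, Y1)
    cy2_c = p.gamma2 + p.beta2 * p.phi
    cov[:k, iy1] = cov[iy1, :k] = lam * cy1_th
    cov[:k, iy2] = cov[iy2, :k] = lam * cy2_th
    cov[ic, ic] = cov[ith, ith] = 1.0
    cov[ic, ith] = cov[ith, ic] = p.phi
    cov[iy1, iy1] = cov[iy2, iy2] = 1.0
    cov[ith, iy1] = cov[iy1, ith] = cy1_th
    cov[ith, iy2] = cov[iy2, ith] = cy2_th
    cov[ic, iy1] = cov[iy1, ic] = cy1_c
    cov[ic, iy2] = cov[iy2, ic] = cy2_c
    # cov(Y1, Y2) via shared predictors
    cov[iy1, iy2] = cov[iy2, iy1] = (
        p.beta1 * p.beta2
        + p.gamma1 * p.gamma2
        + p.phi * (p.beta1 * p.gamma2 + p.beta2 * p.gamma1)
    )
    return pd.DataFrame(cov, index=names, columns=names)


def categorize(values: np.ndarray, thresholds=THRESHOLDS) -> np.ndarray:
    """Cut continuous values into ordinal categories 1..len(thresholds)+1.

    A value lands in category 1 + (number of thresholds strictly below it);
    monotone non-decreasing in the input.
    """
    t = np.asarray(thresholds, dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be strictly increasing")
    return 1 + np.searchsorted(t, np.asarray(values, dtype=float), side="left")


def generate_sample(cond: DesignCondition, seed: int, n: int | None = None) -> SimulatedSample:
    """Draw one replication's sample from the condition's population.

    Uses a counter-based (Philox) generator keyed by ``seed`` so identical
    (condition, seed) pairs give bit-identical samples.  ``n`` overrides the
    condition's sample size (used by large-n convergence checks).
    """
    theta, c, xstar, y1, y2 = _draw_continuous(cond, seed, n)
    return SimulatedSample(theta=theta, items=categorize(xstar), covariate=c, y1=y1, y2=y2)


def generate_continuous(cond: DesignCondition, seed: int, n: int | None = None):
    """Continuous-indicator twin of :func:`generate_sample`.

    Returns (theta, covariate, xstar, y1, y2) with the identical random
    stream, so the only difference from the ordinal sample is the missing
    categorization step.
    """
    return _draw_continuous(cond, seed, n)


def _draw_continuous(cond: DesignCondition, seed: int, n: int | None):
    p = population_params(cond)
    lam = p.lambdas
    n = cond.sample_size if n is None else int(n)
    rng = np.random.Generator(np.random.Philox(int(seed)))

    z = rng.standard_normal((n, 2))
    theta = z[:, 0]
    c = p.phi * theta + np.sqrt(1.0 - p.phi**2) * z[:, 1]

    eps = rng.standard_normal((n, lam.shape[0])) * np.sqrt(1.0 - lam**2)
    xstar = theta[:, None] * lam[None, :] + eps

    e1 = rng.standard_normal(n) * np.sqrt(p.sigma2_y1)
    e2 = rng.standard_normal(n) * np.sqrt(p.sigma2_y2)
    y1 = p.beta1 * theta + p.gamma1 * c + e1
    y2 = p.beta2 * theta + p.gamma2 * c + e2
    return theta, c, xstar, y1, y2
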