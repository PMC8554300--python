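"""Replication engine: run design conditions, regress the outcome on each
skill proxy plus the covariate, and summarize percent bias per method.

Per replication the engine generates a sample, computes the five test
scores, enters each into OLS alongside the covariate, pools ten
plausible-value regressions by Rubin's rules, fits the structural equation
model, and records the percent bias of the skill and covariate coefficients
against the generating values.  Seeds follow the variance-reduction scheme
seed(condition, rep) = base_seed*10^6 + condition_id*10^4 + rep, fed through
a counter-based (Philox) generator so conditions are independent streams and
every run is exactly reproducible.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from scorebias.ctt_scores import fit_cfa, rfs, sms
from scorebias.datagen import generate_sample, population_params
from scorebias.design_grid import DesignCondition, build_design
from scorebias.irt_scores import eap, ebm, fit_gpcm, wle
from scorebias.pv_engine import draw_pv, fit_latent_regression, pool_rubin
from scorebias.sem_engine import fit_sem

ALL_METHODS = ("SMS", "EBM", "RFS", "WLE", "EAP", "PV", "SEM")
#: columns of the pooled score/outcome correlation matrix
CORR_VARS = ("SMS", "EBM", "RFS", "WLE", "EAP", "Y1", "Y2")
#: methods for which the standardized-coefficient variant is also recorded
STD_METHODS = ("EBM", "RFS", "WLE", "EAP")


@dataclass
class OLSFit:
    """Least-squares coefficients and conventional standard errors."""

    coef: np.ndarray
    se: np.ndarray


@dataclass
class RegressionFit:
    """Skill and covariate coefficients from one proxy regression."""

    method: str
    skill_coef: float
    covariate_coef: float
    skill_se: float
    covariate_se: float
    standardized: bool = False


@dataclass
class BiasSummary:
    """Mean percent bias of one coefficient for one method in one condition."""

    condition_id: int
    method: str
    coefficient: str  # "skill" or "covariate"
    mean_pct_bias: float
    sd_pct_bias: float
    n_reps: int
    n_flagged: int


@dataclass
class RunConfig:
    """Configuration of a study run (JSON-serializable)."""

    n_reps: int = 100
    methods: tuple = ALL_METHODS
    base_seed: int = 1
    n_pv: int = 10
    conditions: tuple | None = None  # condition_ids; None = all 36
    output_dir: str | None = None
    standardized_variants: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("need at least one replication")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if raw.get("conditions") is not None:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def to_json(self) -> str:
        d = asdict(self)
        d["methods"] = list(self.methods)
        if self.conditions is not None:
            d["conditions"] = list(self.conditions)
        return json.dumps(d, indent=2)

    def replication_seed(self, condition_id: int, rep: int) -> int:
        return self.base_seed * 10**6 + condition_id * 10**4 + rep


def ols(outcome: np.ndarray, predictors: np.ndarray) -> OLSFit:
    """OLS of the outcome on a design matrix that already includes the intercept."""
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    n, p = X.shape
    gram = X.T @ X
    if np.linalg.matrix_rank(gram) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    gram_inv = np.linalg.inv(gram)
    coef = gram_inv @ (X.T @ y)
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(sigma2 * np.diag(gram_inv))
    return OLSFit(coef=coef, se=se)


def percent_bias(estimate: float, truth: float) -> float:
    """100 * (estimate - truth) / truth; negative = attenuation."""
    if truth == 0:
        raise ValueError("percent bias is undefined for a zero true value")
    return 100.0 * (estimate - truth) / truth


def sms_bias_closed_form(reliability: float, phi: float) -> float:
    """Classical errors-in-variables percent bias of the skill coefficient.

    For a standardized proxy S with corr(S, theta) = sqrt(reliability) and
    corr(S, C) = sqrt(reliability)*phi, the population regression of the
    outcome on (S, C) gives a skill coefficient of
    beta * sqrt(rho) * (1 - phi^2) / (1 - rho phi^2); the implied percent
    bias is independent of (beta, gamma).
    """
    rho = reliability
    return 100.0 * (np.sqrt(rho) * (1.0 - phi**2) / (1.0 - rho * phi**2) - 1.0)


def standardized_fit(
    fit: RegressionFit,
    score_sd: float,
    outcome_sd: float,
    covariate_sd: float | None = None,
) -> RegressionFit:
    """Rescale a fit to standardized coefficients (coef * predictor sd / outcome sd)."""
    if score_sd <= 0 or outcome_sd <= 0:
        raise ValueError("standard deviations must be positive")
    c_sd = covariate_sd if covariate_sd is not None else outcome_sd
    r_skill = score_sd / outcome_sd
    r_cov = c_sd / outcome_sd
    return RegressionFit(
        method=fit.method,
        skill_coef=fit.skill_coef * r_skill,
        covariate_coef=fit.covariate_coef * r_cov,
        skill_se=fit.skill_se * r_skill,
        covariate_se=fit.covariate_se * r_cov,
        standardized=True,
    )


def _proxy_fit(method: str, outcome, score, covariate) -> RegressionFit:
    n = outcome.shape[0]
    X = np.column_stack([np.ones(n), score, covariate])
    f = ols(outcome, X)
    return RegressionFit(
        method=method,
        skill_coef=float(f.coef[1]),
        covariate_coef=float(f.coef[2]),
        skill_se=float(f.se[1]),
        covariate_se=float(f.se[2]),
    )


def run_condition(cond: DesignCondition, config: RunConfig):
    """Run all replications of one condition.

    Returns (summaries, corr, flags): a list of :class:`BiasSummary` (one per
    method and coefficient, plus ``*_STD`` standardized-skill variants), the
    mean score/outcome correlation matrix over replications, and a dict of
    per-method flag counts.  Replications where a method errors out are
    excluded from that method's average and counted; non-converged but usable
    fits are included and counted as flagged.  The run aborts if more than
    10% of replications fail outright.
    """
    pop = population_params(cond)
    beta_true, gamma_true = pop.analyzed_coefs(cond.rsro)
    methods = [m for m in ALL_METHODS if m in config.methods]
    want_irt = any(m in methods for m in ("WLE", "EAP", "EBM"))
    want_corr = all(m in methods for m in ("SMS", "EBM", "RFS", "WLE", "EAP"))

    bias = {m: {"skill": [], "covariate": []} for m in methods}
    flags = {m: 0 for m in methods}
    errors = {m: 0 for m in methods}
    if config.standardized_variants:
        for m in STD_METHODS:
            if m in methods:
                bias[m + "_STD"] = {"skill": [], "covariate": []}
    corr_accum = np.zeros((len(CORR_VARS), len(CORR_VARS)))
    corr_n = 0
    hard_failures = 0

    for rep in range(1, config.n_reps + 1):
        seed = config.replication_seed(cond.condition_id, rep)
        sample = generate_sample(cond, seed)
        outcome = sample.y1 if cond.rsro == "stronger" else sample.y2
        C = sample.covariate
        out_sd = float(np.std(outcome, ddof=1))
        c_sd = float(np.std(C, ddof=1))
        scores = {}

        if "SMS" in methods:
            try:
                scores["SMS"] = sms(sample.items).values
            except ValueError:
                errors["SMS"] += 1
        if "RFS" in methods:
            try:
                cfa = fit_cfa(sample.items)
                if not cfa.converged:
                    flags["RFS"] += 1
                scores["RFS"] = rfs(cfa, sample.items).values
            except (ValueError, np.linalg.LinAlgError):
                errors["RFS"] += 1
        if want_irt:
            try:
                gp = fit_gpcm(sample.items)
                if not gp.converged or gp.collapsed:
                    for m in ("WLE", "EAP", "EBM"):
                        if m in methods:
                            flags[m] += 1
                for m, scorer in (("WLE", wle), ("EAP", eap), ("EBM", ebm)):
                    if m in methods:
                        scores[m] = scorer(gp, sample.items).values
            except (ValueError, np.linalg.LinAlgError):
                hard_failures += 1
                for m in ("WLE", "EAP", "EBM"):
                    if m in methods:
                        errors[m] += 1

        for m, vals in scores.items():
            fit = _proxy_fit(m, outcome, vals, C)
            bias[m]["skill"].append(percent_bias(fit.skill_coef, beta_true))
            bias[m]["covariate"].append(percent_bias(fit.covariate_coef, gamma_true))
            if config.standardized_variants and m in STD_METHODS:
                sfit = standardized_fit(fit, float(np.std(vals, ddof=1)), out_sd, c_sd)
                bias[m + "_STD"]["skill"].append(percent_bias(sfit.skill_coef, beta_true))
                bias[m + "_STD"]["covariate"].append(
                    percent_bias(sfit.covariate_coef, gamma_true)
                )

        if "PV" in methods:
            try:
                background = np.column_stack([C, sample.y1, sample.y2])
                lrm = fit_latent_regression(
                    sample.items, background, background_names=["c", "y1", "y2"]
                )
                if not lrm.item_params.converged:
                    flags["PV"] += 1
                pv_seed = (seed * 7919 + 13) % (2**31 - 1)
                pvs = draw_pv(lrm, sample.items, background, m=config.n_pv, seed=pv_seed)
                pv_fits = []
                for col in range(pvs.m):
                    f = _proxy_fit("PV", outcome, pvs.draws[:, col], C)
                    pv_fits.append(
                        (
                            np.array([f.skill_coef, f.covariate_coef]),
                            np.array([f.skill_se**2, f.covariate_se**2]),
                        )
                    )
                pooled = pool_rubin(pv_fits)
                bias["PV"]["skill"].append(percent_bias(pooled.coef[0], beta_true))
                bias["PV"]["covariate"].append(percent_bias(pooled.coef[1], gamma_true))
            except (ValueError, np.linalg.LinAlgError):
                hard_failures += 1
                errors["PV"] += 1

        if "SEM" in methods:
            try:
                sem = fit_sem(sample.items, C, outcome)
                if not sem.converged:
                    flags["SEM"] += 1
                bias["SEM"]["skill"].append(percent_bias(sem.beta_hat, beta_true))
                bias["SEM"]["covariate"].append(percent_bias(sem.gamma_hat, gamma_true))
            except (ValueError, np.linalg.LinAlgError):
                hard_failures += 1
                errors["SEM"] += 1

        if want_corr and all(m in scores for m in ("SMS", "EBM", "RFS", "WLE", "EAP")):
            block = np.column_stack(
                [scores[m] for m in ("SMS", "EBM", "RFS", "WLE", "EAP")]
                + [sample.y1, sample.y2]
            )
            corr_accum += np.corrcoef(block, rowvar=False)
            corr_n += 1

        if hard_failures > 0.1 * config.n_reps:
            raise RuntimeError(
                f"condition {cond.condition_id}: more than 10% of replications failed"
            )

    summaries = []
    for m, by_coef in bias.items():
        base = m.removesuffix("_STD")
        for coef_name, vals in by_coef.items():
            arr = np.asarray(vals)
            summaries.append(
                BiasSummary(
                    condition_id=cond.condition_id,
                    method=m,
                    coefficient=coef_name,
                    mean_pct_bias=float(arr.mean()) if arr.size else float("nan"),
                    sd_pct_bias=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                    n_reps=int(arr.size),
                    n_flagged=flags.get(base, 0) + errors.get(base, 0),
                )
            )
    corr = pd.DataFrame(
        corr_accum / corr_n if corr_n else np.full_like(corr_accum, np.nan),
        index=CORR_VARS,
        columns=CORR_VARS,
    )
    return summaries, corr, {"flagged": flags, "errors": errors}


def summaries_frame(summaries: Iterable[BiasSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def run_study(config: RunConfig, conditions: Sequence[DesignCondition] | None = None):
    """Run the configured subset of the design; returns (summaries_df, pooled_corr).

    When ``config.output_dir`` is set, writes summaries.csv, the pivoted bias
    tables, correlations.csv, and a run log with the config hash and flag
    counts.
    """
    grid = conditions if conditions is not None else build_design()
    if config.conditions is not None:
        wanted = set(config.conditions)
        grid = [c for c in grid if c.condition_id in wanted]
    all_summaries: list[BiasSummary] = []
    corr_sum = None
    corr_count = 0
    flag_log = {}
    for cond in grid:
        summaries, corr, flags = run_condition(cond, config)
        all_summaries.extend(summaries)
        if np.isfinite(corr.to_numpy()).all():
            corr_sum = corr if corr_sum is None else corr_sum + corr
            corr_count += 1
        flag_log[cond.condition_id] = flags
    df = summaries_frame(all_summaries)
    pooled_corr = corr_sum / corr_count if corr_count else None
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "summaries.csv", index=False)
        for coef in ("skill", "covariate"):
            make_tables(df, coef).to_csv(out / f"bias_{coef}.csv")
        if pooled_corr is not None:
            pooled_corr.to_csv(out / "correlations.csv")
        log = {
            "config": json.loads(config.to_json()),
            "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
            "flags": flag_log,
            "numpy_version": np.__version__,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return df, pooled_corr


def make_tables(summaries: pd.DataFrame, coefficient: str = "skill") -> pd.DataFrame:
    """Pivot per-condition mean percent bias into the wide report layout.

    Rows follow the canonical condition order (rsro x sample size x loadings
    x items); columns are the methods in report order.  Methods missing from
    the run appear as explicit gaps (NaN columns).
    """
    meta = {c.condition_id: c for c in build_design()}
    sub = summaries[summaries["coefficient"] == coefficient]
    wide = sub.pivot_table(index="condition_id", columns="method", values="mean_pct_bias")
    for m in ALL_METHODS:
        if m not in wide.columns:
            wide[m] = np.nan
    extra = [c for c in wide.columns if c not in ALL_METHODS]
    wide = wide[list(ALL_METHODS) + sorted(extra)]
    info = pd.DataFrame(
        {
            "condition_id": wide.index,
            "rsro": [meta[i].rsro for i in wide.index],
            "sample_size": [meta[i].sample_size for i in wide.index],
            "loadings": [meta[i].loading_profile for i in wide.index],
            "n_items": [meta[i].n_items for i in wide.index],
        }
    ).set_index("condition_id")
    return info.join(wide).sort_index()
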