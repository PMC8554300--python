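"""One-call reproduction of the study's headline quantities at desk scale.

Runs the full 36-condition design with every method at a configurable
replication count and condenses the summaries into the handful of numbers
the study reports: per-method maxima of absolute mean percent bias across
conditions, and the benchmark cells of the bias tables (the 4-item
low-loading and high-loading small-sample conditions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scorebias.design_grid import N_ITEMS_LEVELS, PROFILES, build_design, loading_set, omega
from scorebias.study_runner import RunConfig, run_study

#: benchmark cells, addressed by design factors rather than raw ids
CELL_LOW4_SMALL_STRONGER = dict(rsro="stronger", sample_size=300,
                                loading_profile="low", n_items=4)
CELL_HIGH4_SMALL_STRONGER = dict(rsro="stronger", sample_size=300,
                                 loading_profile="high", n_items=4)


def condition_id(**factors) -> int:
    """Resolve a design cell to its stable condition id."""
    for c in build_design():
        if all(getattr(c, key) == val for key, val in factors.items()):
            return c.condition_id
    raise KeyError(f"no condition matches {factors}")


def run_full_sweep(base_seed: int = 1, n_reps: int = 100, n_pv: int = 10):
    """All 36 conditions x all methods; returns (summaries_df, pooled_corr)."""
    cfg = RunConfig(n_reps=n_reps, base_seed=base_seed, n_pv=n_pv)
    return run_study(cfg)


def omega_calibration() -> pd.DataFrame:
    """Implied McDonald's omega of the nine (profile x item count) scales."""
    rows = [
        {"profile": p, "n_items": k, "omega": omega(loading_set(p, k))}
        for p in PROFILES
        for k in N_ITEMS_LEVELS
    ]
    return pd.DataFrame(rows)


def _cell_mean(df: pd.DataFrame, cid: int, method: str, coefficient: str) -> float:
    sel = df[
        (df["condition_id"] == cid)
        & (df["method"] == method)
        & (df["coefficient"] == coefficient)
    ]
    return float(sel["mean_pct_bias"].iloc[0])


def _max_abs(df: pd.DataFrame, methods, coefficient: str) -> float:
    sel = df[(df["method"].isin(methods)) & (df["coefficient"] == coefficient)]
    return float(sel["mean_pct_bias"].abs().max())


def headline_results(summaries: pd.DataFrame) -> dict:
    """Condense a full-sweep summary frame into the study's headline numbers.

    Maxima are over the 36 conditions (and, for the point-score entry, over
    the EBM/RFS/EAP methods); cell entries are signed mean percent biases.
    """
    cid_low4 = condition_id(**CELL_LOW4_SMALL_STRONGER)
    cid_high4 = condition_id(**CELL_HIGH4_SMALL_STRONGER)
    return {
        "sem_skill_max_abs": _max_abs(summaries, ["SEM"], "skill"),
        "pv_skill_max_abs": _max_abs(summaries, ["PV"], "skill"),
        "pv_covariate_max_abs": _max_abs(summaries, ["PV"], "covariate"),
        "point_score_skill_max_abs": _max_abs(summaries, ["EBM", "RFS", "EAP"], "skill"),
        "wle_skill_max_abs": _max_abs(summaries, ["WLE"], "skill"),
        "sms_skill_low4_small_stronger": _cell_mean(summaries, cid_low4, "SMS", "skill"),
        "wle_skill_low4_small_stronger": _cell_mean(summaries, cid_low4, "WLE", "skill"),
        "sms_skill_high4_small_stronger": _cell_mean(summaries, cid_high4, "SMS", "skill"),
        "sms_covariate_low4_small_stronger": _cell_mean(
            summaries, cid_low4, "SMS", "covariate"
        ),
    }
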