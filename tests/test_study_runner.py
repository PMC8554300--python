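import json

import numpy as np
import pytest

from scorebias.datagen import generate_continuous
from scorebias.design_grid import omega
from scorebias.fixtures import toy_regression
from scorebias.study_runner import (
    RegressionFit,
    RunConfig,
    make_tables,
    ols,
    percent_bias,
    run_condition,
    run_study,
    sms_bias_closed_form,
    standardized_fit,
    summaries_frame,
)

from conftest import condition


class TestOls:
    def test_exact_interpolation(self):
        fx = toy_regression()
        fit = ols(fx.known_params["y_exact"], fx.known_params["design"])
        assert np.allclose(fit.coef, fx.expected["coef_exact"], atol=1e-12)

    def test_hand_solved_normal_equations(self):
        fx = toy_regression()
        fit = ols(fx.known_params["y_noisy"], fx.known_params["design"])
        assert np.allclose(fit.coef, fx.expected["coef_noisy"], atol=1e-12)

    def test_row_permutation_invariance(self):
        fx = toy_regression()
        X, y = fx.known_params["design"], fx.known_params["y_noisy"]
        perm = np.array([4, 2, 0, 3, 1])
        a, b = ols(y, X), ols(y[perm], X[perm])
        assert np.allclose(a.coef, b.coef)
        assert np.allclose(a.se, b.se)

    def test_orthogonal_predictors_match_simple_slopes(self):
        rng = np.random.default_rng(0)
        n = 400
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x1 -= x1.mean()
        x2 -= x2.mean() + x1 * (x1 @ x2) / (x1 @ x1)  # orthogonalize
        y = 0.5 * x1 - 0.2 * x2 + rng.standard_normal(n)
        multi = ols(y, np.column_stack([np.ones(n), x1, x2]))
        s1 = ols(y, np.column_stack([np.ones(n), x1]))
        s2 = ols(y, np.column_stack([np.ones(n), x2]))
        assert multi.coef[1] == pytest.approx(s1.coef[1], abs=1e-10)
        assert multi.coef[2] == pytest.approx(s2.coef[1], abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(60), rng.standard_normal((60, 2))])
        y = X @ [1.0, 0.4, -0.3] + rng.standard_normal(60)
        ours = ols(y, X)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(ours.coef, ref.params)
        assert np.allclose(ours.se, ref.bse)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError):
            ols(np.arange(10.0), X)


class TestPercentBias:
    @pytest.mark.parametrize(
        ("est", "truth", "expected"),
        [(0.35, 0.35, 0.0), (0.9, 1.0, -10.0), (0.315, 0.35, -10.0)],
    )
    def test_arithmetic(self, est, truth, expected):
        assert percent_bias(est, truth) == pytest.approx(expected)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            percent_bias(0.1, 0.0)


class TestStandardizedFit:
    def _fit(self):
        return RegressionFit("WLE", skill_coef=0.3, covariate_coef=0.32,
                             skill_se=0.05, covariate_se=0.05)

    def test_unit_sds_are_identity(self):
        out = standardized_fit(self._fit(), 1.0, 1.0, 1.0)
        assert out.skill_coef == pytest.approx(0.3)
        assert out.covariate_coef == pytest.approx(0.32)
        assert out.standardized

    def test_rescaling(self):
        out = standardized_fit(self._fit(), 2.0, 0.5, 1.0)
        assert out.skill_coef == pytest.approx(0.3 * 4)
        assert out.covariate_coef == pytest.approx(0.32 * 2)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            standardized_fit(self._fit(), 0.0, 1.0)


class TestSeedScheme:
    def test_seed_formula(self):
        cfg = RunConfig(base_seed=3)
        assert cfg.replication_seed(7, 12) == 3 * 10**6 + 7 * 10**4 + 12

    def test_config_json_roundtrip(self, tmp_path):
        cfg = RunConfig(n_reps=5, methods=("SMS", "SEM"), base_seed=9, conditions=(1, 7))
        path = tmp_path / "cfg.json"
        path.write_text(cfg.to_json())
        assert RunConfig.from_json(path) == cfg

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(methods=("SMS", "XYZ"))


class TestClosedFormOracle:
    def test_continuous_sms_matches_errors_in_variables_formula(self):
        """With categorization disabled, the SMS skill-coefficient bias
        matches the classical attenuation closed form within 1.5 pts.

        n = 1e5 keeps the sampling SE of the estimated bias near 0.7 points,
        so the 1.5-point band is a two-sigma check.
        """
        for profile in ("low", "high"):
            cond = condition("stronger", 300, profile, 4)
            theta, c, xstar, y1, y2 = generate_continuous(cond, seed=47, n=100_000)
            means = xstar.mean(axis=1)
            score = (means - means.mean()) / means.std(ddof=1)
            fit = ols(y1, np.column_stack([np.ones(theta.size), score, c]))
            observed = percent_bias(fit.coef[1], 0.35)
            expected = sms_bias_closed_form(omega(cond.lambdas), 0.30)
            assert observed == pytest.approx(expected, abs=1.5)


@pytest.fixture(scope="module")
def small_run():
    cond = condition("stronger", 300, "low", 4)
    cfg = RunConfig(n_reps=8, base_seed=4)
    return run_condition(cond, cfg)


@pytest.fixture(scope="module")
def mini_study(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(n_reps=2, methods=("SMS", "SEM"), base_seed=8,
                    conditions=(1, 7, 19), output_dir=str(out),
                    standardized_variants=False)
    df, corr = run_study(cfg)
    return cfg, df, out


class TestRunCondition:
    def test_summary_layout(self, small_run):
        summaries, corr, flags = small_run
        df = summaries_frame(summaries)
        methods = set(df["method"])
        assert {"SMS", "EBM", "RFS", "WLE", "EAP", "PV", "SEM"} <= methods
        assert {"WLE_STD", "EAP_STD"} <= methods
        assert set(df["coefficient"]) == {"skill", "covariate"}
        assert (df["n_reps"] == 8).all()

    def test_attenuation_and_inflation_signs(self, small_run):
        """Fallible scores attenuate the skill and inflate the covariate."""
        df = summaries_frame(small_run[0])
        sms_skill = df.query("method=='SMS' and coefficient=='skill'").mean_pct_bias.iloc[0]
        sms_cov = df.query("method=='SMS' and coefficient=='covariate'").mean_pct_bias.iloc[0]
        wle_skill = df.query("method=='WLE' and coefficient=='skill'").mean_pct_bias.iloc[0]
        assert sms_skill < -20
        assert sms_cov > 10
        assert wle_skill < sms_skill  # WLE is the worst performer here

    def test_correlation_matrix_near_unity_scores(self, small_run):
        corr = small_run[1]
        score_block = corr.loc[["SMS", "EBM", "RFS", "WLE", "EAP"],
                               ["SMS", "EBM", "RFS", "WLE", "EAP"]].to_numpy()
        assert score_block[np.triu_indices(5, 1)].min() > 0.95

    def test_method_subset_runs(self):
        cond = condition("weaker", 300, "high", 4)
        cfg = RunConfig(n_reps=2, methods=("SMS", "SEM"), base_seed=6,
                        standardized_variants=False)
        summaries, corr, flags = run_condition(cond, cfg)
        df = summaries_frame(summaries)
        assert set(df["method"]) == {"SMS", "SEM"}
        assert corr.isna().all().all()  # needs all five scores


class TestRunStudyAndTables:
    def test_outputs_written(self, mini_study):
        cfg, df, out = mini_study
        assert (out / "summaries.csv").exists()
        assert (out / "bias_skill.csv").exists()
        log = json.loads((out / "run_log.json").read_text())
        assert log["config"]["base_seed"] == 8
        assert "config_sha256" in log

    def test_tables_layout(self, mini_study):
        cfg, df, out = mini_study
        table = make_tables(df, "skill")
        assert list(table.index) == [1, 7, 19]
        cols = list(table.columns)
        assert cols[:4] == ["rsro", "sample_size", "loadings", "n_items"]
        assert cols[4:11] == ["SMS", "EBM", "RFS", "WLE", "EAP", "PV", "SEM"]
        assert table["SMS"].notna().all()
        assert table["WLE"].isna().all()  # explicit gap for methods not run

    def test_rerun_reproducibility(self, mini_study, tmp_path):
        """Identical config (different output dir) gives identical summaries."""
        cfg, df, _ = mini_study
        from dataclasses import replace

        df2, _ = run_study(replace(cfg, output_dir=str(tmp_path)))
        assert np.allclose(
            df.sort_values(["condition_id", "method", "coefficient"]).mean_pct_bias.to_numpy(),
            df2.sort_values(["condition_id", "method", "coefficient"]).mean_pct_bias.to_numpy(),
        )


def test_cli_grid_smoke(tmp_path):
    from click.testing import CliRunner

    from scorebias.cli import main

    runner = CliRunner()
    result = runner.invoke(main, ["grid"])
    assert result.exit_code == 0
    assert "condition_id" in result.output
    dest = tmp_path / "grid.csv"
    result = runner.invoke(main, ["grid", "--out", str(dest)])
    assert result.exit_code == 0 and dest.exists()
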