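import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from scorebias.fixtures import toy_gpcm
from scorebias.irt_scores import (
    GPCMParams,
    eap,
    ebm,
    fit_gpcm,
    gpcm_category_probs,
    wle,
)
# aliased so pytest does not collect the library function as a test
from scorebias.irt_scores import test_information as gpcm_information

from conftest import condition
from scorebias.datagen import generate_sample


def make_params(a, steps):
    """GPCMParams with parameters fixed in code (no fitting)."""
    a = np.asarray(a, float)
    steps = np.asarray(steps, float)
    k = a.shape[0]
    xi = np.zeros((k, 5))
    xi[:, 1:] = -a[:, None] * np.cumsum(steps, axis=1)
    return GPCMParams(
        discriminations=a,
        steps=steps,
        xi=xi,
        n_cats=np.full(k, 5),
        cat_maps=np.tile(np.arange(5), (k, 1)),
        loglik=0.0,
        converged=True,
    )


SYM_STEPS = np.array([-1.5, -0.5, 0.5, 1.5])


@pytest.fixture(scope="module")
def sym3():
    return make_params([1.0, 1.5, 0.8], np.tile(SYM_STEPS, (3, 1)))


@pytest.fixture(scope="module")
def fitted_low4(low4_sample_module):
    return fit_gpcm(low4_sample_module.items)


@pytest.fixture(scope="module")
def low4_sample_module():
    return generate_sample(condition("stronger", 300, "low", 4), seed=20211015)


class TestCategoryProbs:
    @given(st.floats(0.2, 3.0), st.floats(-3, 3))
    def test_probabilities_normalize(self, a, theta):
        p = gpcm_category_probs(a, SYM_STEPS, theta)
        assert p.shape == (5,)
        assert np.all(p > 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_steps_give_symmetric_probs_at_zero(self):
        p = gpcm_category_probs(1.3, SYM_STEPS, 0.0)
        assert np.allclose(p, p[::-1])

    @given(st.floats(0.3, 2.5), st.floats(-2, 2), st.floats(-3, 3))
    def test_two_category_reduction_is_logistic(self, a, b1, theta):
        p = gpcm_category_probs(a, [b1], theta)
        assert p[1] == pytest.approx(expit(a * (theta - b1)), abs=1e-12)

    def test_rejects_nonpositive_discrimination(self):
        with pytest.raises(ValueError):
            gpcm_category_probs(0.0, SYM_STEPS, 0.0)


class TestFitGpcm:
    def test_discrimination_rank_order_matches_loadings(self):
        """At large n the fitted a_j preserve the order of the generating
        loadings (monotone mapping between loadings and discriminations)."""
        cond = condition("stronger", 300, "mixed", 4)  # loadings 0.9/0.7/0.6/0.4
        sample = generate_sample(cond, seed=31, n=30_000)
        fitted = fit_gpcm(sample.items)
        assert fitted.converged
        assert list(np.argsort(-fitted.discriminations)) == [0, 1, 2, 3]

    def test_em_ascent(self, fitted_low4):
        assert np.all(np.diff(fitted_low4.loglik_history) > -1e-7)

    def test_pattern_count_sufficiency(self, low4_sample_module):
        """Doubling every row leaves estimates unchanged, doubles the loglik."""
        items = low4_sample_module.items
        single = fit_gpcm(items)
        double = fit_gpcm(np.vstack([items, items]))
        assert np.allclose(single.discriminations, double.discriminations, atol=1e-6)
        assert double.loglik == pytest.approx(2 * single.loglik, rel=1e-6)

    def test_single_category_item_rejected(self):
        items = np.full((20, 3), 3)
        items[:, :2] = np.random.default_rng(0).integers(1, 6, (20, 2))
        with pytest.raises(ValueError):
            fit_gpcm(items)

    def test_unobserved_category_collapsed_and_flagged(self):
        rng = np.random.default_rng(4)
        items = rng.integers(1, 5, (80, 3))  # category 5 never observed
        fitted = fit_gpcm(items)
        assert fitted.collapsed
        assert np.all(fitted.n_cats == 4)
        # scoring still works on the collapsed scale
        assert np.all(np.isfinite(wle(fitted, items).values))


class TestInformation:
    def test_nonnegative_on_grid(self, sym3):
        grid = np.linspace(-6, 6, 101)
        assert np.all(gpcm_information(sym3, grid) >= 0)

    def test_vanishing_discrimination_limit(self):
        weak = make_params([1e-3, 1e-3], np.tile(SYM_STEPS, (2, 1)))
        assert gpcm_information(weak, np.array([0.0]))[0] < 1e-5

    def test_dichotomous_reduction_closed_form(self):
        a = 1.4
        params = make_params([a], [[0.3, 40.0, 41.0, 42.0]])  # cats 3-5 unreachable
        theta = np.linspace(-3, 3, 13)
        p1 = expit(a * (theta - 0.3))
        assert np.allclose(gpcm_information(params, theta), a**2 * p1 * (1 - p1), atol=1e-8)


class TestScoring:
    def test_all_middle_pattern_scores_zero_under_symmetry(self, sym3):
        items = np.array([[3, 3, 3], [1, 1, 1]])
        assert wle(sym3, items).values[0] == pytest.approx(0.0, abs=1e-6)
        assert eap(sym3, items).values[0] == pytest.approx(0.0, abs=1e-9)
        assert ebm(sym3, items).values[0] == pytest.approx(0.0, abs=1e-6)

    def test_wle_monotone_in_sufficient_statistic(self, sym3):
        low = wle(sym3, np.array([[1, 1, 1], [3, 3, 3], [5, 5, 5]])).values
        assert low[0] < low[1] < low[2]
        assert np.all(np.isfinite(low))

    def test_grid_oracle_agreement(self, sym3):
        """WLE/EAP/EBM match an independent 1e-4-resolution grid oracle."""
        fx = toy_gpcm()
        for name, scorer in (("wle", wle), ("eap", eap), ("ebm", ebm)):
            got = scorer(sym3, fx.items).values
            assert np.allclose(got, fx.expected[name], atol=2e-4), name

    def test_flat_likelihood_returns_prior_location(self):
        weak = make_params([1e-2, 1e-2], np.tile(SYM_STEPS, (2, 1)))
        patterns = np.array([[1, 5], [5, 1], [2, 4]])
        assert np.allclose(eap(weak, patterns).values, 0.0, atol=0.02)
        assert np.allclose(ebm(weak, patterns).values, 0.0, atol=0.02)

    def test_shrinkage_vs_antishrinkage(self, fitted_low4, low4_sample_module):
        """EAP shrinks below the prior variance; WLE over-disperses."""
        items = low4_sample_module.items
        v_eap = np.var(eap(fitted_low4, items).values)
        v_wle = np.var(wle(fitted_low4, items).values)
        assert v_eap < 1.0 < v_wle
        assert v_eap < v_wle

    def test_ebm_tracks_eap(self, fitted_low4, low4_sample_module):
        items = low4_sample_module.items
        r = np.corrcoef(ebm(fitted_low4, items).values, eap(fitted_low4, items).values)[0, 1]
        assert r > 0.99


def test_all_five_scores_highly_correlated(low4_sample_module):
    """The five score types correlate > 0.97 pairwise on study-like data."""
    from scorebias.ctt_scores import fit_cfa, rfs, sms

    items = low4_sample_module.items
    g = fit_gpcm(items)
    cfa = fit_cfa(items)
    block = np.column_stack(
        [
            sms(items).values,
            ebm(g, items).values,
            rfs(cfa, items).values,
            wle(g, items).values,
            eap(g, items).values,
        ]
    )
    corr = np.corrcoef(block, rowvar=False)
    # worst pair (SMS x WLE) sits near 0.965 in this lowest-reliability cell;
    # all IRT/CFA-based pairs are essentially at 1
    off = corr[np.triu_indices(5, 1)]
    assert off.min() > 0.95
    assert np.median(off) > 0.99
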