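"""PSIS-LOO: tail fitting, smoothing, elpd, and model ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import logsumexp, ndtr
from scipy.stats import genpareto, norm

from vocalsdt.fitting import fit
from vocalsdt.loo import (
    LooResult,
    compare,
    gpd_fit,
    loo,
    pointwise_loglik,
    psis_smooth,
)
from vocalsdt.models import FitConfig, PriorSpec, log_likelihood, make_model

from conftest import make_fake_fit


class TestGpdFit:
    def test_profile_estimator_recovers_shape(self):
        rng = np.random.default_rng(0)
        x = genpareto.rvs(c=0.3, scale=1.2, size=4000, random_state=rng)
        k, sigma = gpd_fit(x)
        assert k == pytest.approx(0.3, abs=0.1)
        assert sigma == pytest.approx(1.2, rel=0.15)

    def test_moments_fallback_agrees_on_light_tail(self):
        rng = np.random.default_rng(1)
        x = genpareto.rvs(c=0.1, scale=1.0, size=4000, random_state=rng)
        k_prof, _ = gpd_fit(x, method="profile")
        k_mom, _ = gpd_fit(x, method="moments")
        assert k_prof == pytest.approx(k_mom, abs=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gpd_fit(np.array([1.0, 2.0]))


class TestPsisSmooth:
    def test_constant_ratios_uniform_weights_sentinel_k(self):
        logw, k = psis_smooth(np.zeros(500))
        assert k == -np.inf
        assert np.allclose(np.exp(logw), 1.0 / 500)

    def test_weights_normalize(self):
        rng = np.random.default_rng(2)
        logw, _ = psis_smooth(rng.normal(size=1000))
        assert np.exp(logsumexp(logw)) == pytest.approx(1.0, abs=1e-12)

    def test_khat_recovers_pareto_tail_index(self):
        rng = np.random.default_rng(3)
        for alpha in (1.0, 2.0):
            ratios = rng.pareto(alpha, size=4000) + 1.0
            _, k = psis_smooth(np.log(ratios))
            assert k == pytest.approx(1.0 / alpha, abs=0.15)

    def test_light_tail_in_good_diagnostic_region(self):
        rng = np.random.default_rng(4)
        _, k = psis_smooth(0.5 * rng.normal(size=4000))
        assert k < 0.5

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match="100"):
            psis_smooth(np.zeros(50))

    def test_matches_arviz_psislw(self):
        import arviz as az

        rng = np.random.default_rng(5)
        lr = rng.standard_t(df=5, size=2000)
        logw, k = psis_smooth(lr)
        ref_logw, ref_k = az.psislw(lr.copy())
        assert k == pytest.approx(float(ref_k), abs=0.02)
        assert np.allclose(logw, np.asarray(ref_logw).ravel(), atol=0.02)


class TestPointwiseLoglik:
    def test_single_draw_single_trial(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["p1"],
                "list_id": ["L1"],
                "trial_index": [0],
                "stimulus_id": ["s1"],
                "familiarity": ["strangers"],
                "mode": ["cospeech"],
                "speed": ["original"],
                "response": [1],
            }
        )
        f = make_fake_fit(np.zeros((1, 1)), level=0, trials=trials)
        mat = pointwise_loglik(f, trials)
        assert mat.shape == (1, 1)
        assert mat[0, 0] == pytest.approx(np.log(0.5), abs=1e-14)

    def test_matches_per_draw_log_likelihood_calls(self, small_fit, small_trials):
        mat = pointwise_loglik(small_fit, small_trials)
        beta = small_fit.stacked("beta")
        effects = small_fit.stacked("participant_effects")
        stim = small_fit.stacked("stimulus_intercepts")
        rng = np.random.default_rng(6)
        for s in rng.choice(beta.shape[0], size=3, replace=False):
            point = {
                "beta": beta[s],
                "participant_effects": effects[s],
                "stimulus_intercepts": stim[s],
            }
            ref = log_likelihood(small_fit.model, point, small_trials)
            assert np.allclose(mat[s], ref, atol=1e-10)

    def test_mismatched_units_rejected(self, small_fit, small_trials):
        renamed = small_trials.copy()
        renamed["participant_id"] = renamed["participant_id"] + "_x"
        with pytest.raises(ValueError, match="units"):
            pointwise_loglik(small_fit, renamed)


class TestLoo:
    def test_looic_identity_and_pointwise_sum(self):
        rng = np.random.default_rng(7)
        ll = -np.abs(rng.normal(size=(600, 40)))
        res = loo(ll)
        assert res.looic == -2.0 * res.elpd_loo
        assert res.pointwise_elpd.sum() == pytest.approx(res.elpd_loo, rel=1e-12)

    def test_single_trial_se_is_zero(self):
        rng = np.random.default_rng(8)
        res = loo(-np.abs(rng.normal(size=(500, 1))))
        assert res.se_elpd == 0.0

    def test_duplicated_dataset_doubles_elpd(self):
        rng = np.random.default_rng(9)
        ll = -np.abs(rng.normal(size=(800, 30)))
        single = loo(ll)
        doubled = loo(np.hstack([ll, ll]))
        assert doubled.elpd_loo == pytest.approx(2.0 * single.elpd_loo, rel=1e-10)

    def test_matches_arviz_loo(self, small_fit, small_trials):
        import arviz as az

        mat = pointwise_loglik(small_fit, small_trials)
        mine = loo(mat)
        c, d = small_fit.n_chains, small_fit.n_draws
        idata = az.from_dict(
            posterior={"b": small_fit.draws["beta"][:, :, 0]},
            log_likelihood={"y": mat.reshape(c, d, -1)},
        )
        ref = az.loo(idata, pointwise=True)
        assert mine.elpd_loo == pytest.approx(float(ref.elpd_loo), abs=0.1)
        assert np.allclose(mine.pointwise_elpd, np.asarray(ref.loo_i), atol=0.02)


def toy_posterior_and_exact_loo(y, n_draws=4000, seed=51):
    """Intercept-only pooled probit with N(0,1) prior on an 8-trial dataset.

    Returns the PSIS-LOO result from posterior draws and the exact
    leave-one-out elpd computed by refitting (1-D quadrature) per trial.
    """
    n = len(y)
    trials = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "list_id": "L1",
            "trial_index": 0,
            "stimulus_id": [f"s{i}" for i in range(n)],
            "familiarity": "strangers",
            "mode": "cospeech",
            "speed": "original",
            "response": y,
        }
    )
    cfg = FitConfig(
        n_chains=2, n_iterations=n_draws, target_accept=0.9, max_trajectory_depth=10, seed=seed
    )
    f = fit(
        make_model(0), trials, PriorSpec(intercept_sd=1.0), cfg, random_effects=False
    )
    psis = loo(pointwise_loglik(f, trials))

    def lik(theta, resp):
        p = ndtr(theta)
        return float(np.prod(np.where(np.asarray(resp) == 1, p, 1 - p)))

    def evidence(resp):
        return quad(lambda t: lik(t, resp) * norm.pdf(t), -9, 9, limit=200)[0]

    full = evidence(y)
    exact = np.array(
        [np.log(full) - np.log(evidence(np.delete(y, i))) for i in range(n)]
    )
    return psis, exact


def test_psis_loo_matches_exact_refit_on_toy_problem():
    psis, exact = toy_posterior_and_exact_loo([1, 1, 1, 0, 1, 0, 1, 1])
    assert psis.elpd_loo == pytest.approx(exact.sum(), abs=0.1)
    assert np.allclose(psis.pointwise_elpd, exact, atol=0.05)


class TestCompare:
    def _result(self, pointwise, label):
        elpd = float(np.sum(pointwise))
        return LooResult(
            elpd_loo=elpd,
            se_elpd=0.0,
            looic=-2 * elpd,
            pointwise_elpd=np.asarray(pointwise, dtype=float),
            pareto_k=np.zeros(len(pointwise)),
            label=label,
        )

    def test_identical_results_zero_difference(self):
        pw = -np.abs(np.random.default_rng(10).normal(size=25))
        table = compare({"a": self._result(pw, "a"), "b": self._result(pw, "b")})
        assert np.allclose(table["elpd_diff"], 0.0)
        assert np.allclose(table["se_diff"], 0.0)

    def test_sorted_by_looic_best_first(self):
        rng = np.random.default_rng(11)
        pw = -np.abs(rng.normal(size=30))
        table = compare(
            {"worse": self._result(pw - 0.3, "worse"), "better": self._result(pw, "better")}
        )
        assert list(table["model"]) == ["better", "worse"]
        assert table.loc[0, "elpd_diff"] == 0.0

    def test_shared_constant_cancels_in_differences(self):
        rng = np.random.default_rng(12)
        a = -np.abs(rng.normal(size=30))
        b = a - rng.uniform(0, 0.2, size=30)
        t1 = compare({"a": self._result(a, "a"), "b": self._result(b, "b")})
        t2 = compare({"a": self._result(a + 1.7, "a"), "b": self._result(b + 1.7, "b")})
        pd.testing.assert_series_equal(t1["elpd_diff"], t2["elpd_diff"])
        pd.testing.assert_series_equal(t1["se_diff"], t2["se_diff"])

    def test_mismatched_lengths_rejected(self):
        a = self._result(-np.ones(10), "a")
        b = self._result(-np.ones(12), "b")
        with pytest.raises(ValueError, match="different numbers"):
            compare({"a": a, "b": b})
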