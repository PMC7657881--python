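"""ROC construction and AUC identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from vocalsdt.roc import (
    ROCCurve,
    ScoredTrials,
    SingleClassError,
    auc_posterior,
    auc_rank,
    predict_probabilities,
    roc_points,
)

from conftest import make_fake_fit


def _scored(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n = len(scores)
    return ScoredTrials(scores, labels, np.array(["cospeech"] * n), np.array(["original"] * n))


def brute_force_auc(scores, labels):
    """Exhaustive pair enumeration with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAucRank:
    def test_perfect_scores(self):
        assert auc_rank(_scored([0, 0, 1, 1], [0, 0, 1, 1])) == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = _scored(rng.random(20000), rng.random(20000) < 0.5)
        assert auc_rank(s) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError, match="stranger"):
            auc_rank(_scored([0.2, 0.8], [1, 1]))
        with pytest.raises(SingleClassError, match="friend"):
            auc_rank(_scored([0.2, 0.8], [0, 0]))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=2, max_size=12),
        data=st.data(),
    )
    def test_matches_exhaustive_pairs_on_small_instances(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if all(labels) or not any(labels):
            return
        s = _scored(scores, labels)
        assert auc_rank(s) == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(500)
        labels = rng.random(500) < ndtr(2 * (scores - 0.5))
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        s = _scored(scores, labels)
        assert auc_rank(s) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.floats(0.1, 3), scale=st.floats(0.1, 3))
    def test_invariant_to_increasing_transforms(self, shift, scale):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = np.arange(60) % 3 == 0
        base = auc_rank(_scored(scores, labels))
        transformed = ndtr(scale * scores + shift - 2)
        assert auc_rank(
            ScoredTrials(transformed, labels, np.array(["x"] * 60), np.array(["y"] * 60))
        ) == pytest.approx(base, abs=1e-12)

    def test_population_auc_equals_phi_d_over_sqrt2(self):
        """Equal-variance SDT: latent evidence separation d gives Phi(d/sqrt(2))."""
        rng = np.random.default_rng(3)
        d = 0.7
        n = 200000
        labels = rng.random(n) < 0.5
        evidence = rng.normal(0, 1, size=n) + d * labels
        s = _scored(ndtr(evidence), labels)
        expected = ndtr(d / np.sqrt(2))
        assert auc_rank(s) == pytest.approx(expected, abs=3.0 / np.sqrt(n))


class TestRocPoints:
    def test_perfect_separation_passes_through_corner(self):
        curve = roc_points(_scored([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]))
        assert any((f == 0.0) and (t == 1.0) for f, t in zip(curve.fpr, curve.tpr))
        assert curve.auc == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_constant_scores(self):
        curve = roc_points(_scored([0.5] * 10, [0, 1] * 5), thresholds=np.array([0.25, 0.75]))
        pts = set(zip(curve.fpr, curve.tpr))
        assert pts == {(0.0, 0.0), (1.0, 1.0)}

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(4)
        curve = roc_points(_scored(rng.random(200), rng.random(200) < 0.4))
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    def test_trapezoid_area_matches_rank_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.random(300)
        labels = rng.random(300) < scores
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        s = _scored(scores, labels)
        curve = roc_points(s)  # default 1001-point grid
        assert curve.auc == pytest.approx(auc_rank(s), abs=1.0 / 1000)
        # exhaustive observed-score thresholds: exact agreement
        exhaustive = roc_points(s, thresholds=np.unique(scores))
        assert exhaustive.auc == pytest.approx(auc_rank(s), abs=1e-12)


class TestPredictions:
    def test_zero_parameter_fit_scores_half(self, small_trials):
        f = make_fake_fit(np.zeros((50, 8)), level=4, trials=small_trials)
        scored = predict_probabilities(f, small_trials)
        assert np.allclose(scored.scores, 0.5)

    def test_posterior_mean_equals_average_of_per_draw(self, small_fit, small_trials):
        mean_scored = predict_probabilities(small_fit, small_trials)
        per_draw, _, _, _ = predict_probabilities(small_fit, small_trials, mode="per_draw")
        assert np.allclose(mean_scored.scores, per_draw.mean(axis=0), atol=1e-12)
        assert per_draw.min() >= 0.0 and per_draw.max() <= 1.0

    def test_new_units_need_marginalization(self, small_fit, small_trials):
        other = small_trials.copy()
        other["participant_id"] = other["participant_id"] + "_new"
        with pytest.raises(ValueError, match="marginalize"):
            predict_probabilities(small_fit, other)
        scored = predict_probabilities(small_fit, other, marginalize=True)
        assert np.isfinite(scored.scores).all()

    def test_auc_posterior_interval_and_range(self, small_fit, small_trials):
        s = auc_posterior(small_fit, small_trials, mode="colaughter")
        assert 0.0 <= s.ci_low <= s.mean <= s.ci_high <= 1.0

    def test_constant_draws_zero_width_auc_interval(self, small_trials):
        beta = np.tile(np.array([0.0, 0.8, 0.2, 0.0, 0.0, 0.3, 0.0, 0.0]), (150, 1))
        f = make_fake_fit(beta, level=4, trials=small_trials)
        s = auc_posterior(f, small_trials)
        assert s.ci_high - s.ci_low == pytest.approx(0.0, abs=1e-12)
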