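"""MAP Bayes classifier with the adaptive prior buffer."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import gaitclass as gc
from gaitclass.map_classifier import BUFFER_SIZE, update_priors

CLASSES = ["stair_climbing", "stair_descending", "walking"]


def _toy_model(seed=0, d=3.0):
    rng = np.random.default_rng(seed)
    means = {"stair_climbing": [-d, 0], "stair_descending": [d, 0], "walking": [0, d]}
    S, labels = [], []
    for c, m in means.items():
        S.append(rng.normal(m, 1.0, (60, 2)))
        labels += [c] * 60
    return gc.fit_map(np.vstack(S), np.asarray(labels)), means


class TestFit:
    def test_moments_match_hand_computation(self):
        Sa = np.array([[0.0, 0], [2, 0], [0, 2], [2, 2]])
        Sb = np.array([[10.0, 10], [12, 10], [11, 12]])
        S = np.vstack([Sa, Sb])
        labels = np.array(["a"] * 4 + ["b"] * 3)
        model = gc.fit_map(S, labels)
        assert np.allclose(model.conditionals["a"].mean, [1, 1])
        assert np.allclose(model.conditionals["a"].cov,
                           np.cov(Sa, rowvar=False, ddof=1))
        assert np.allclose(model.conditionals["b"].mean, Sb.mean(0))

    def test_initial_priors_uniform_and_buffer_balanced(self):
        model, _ = _toy_model()
        assert np.allclose(model.priors, 1 / 3)
        assert len(model.buffer) == BUFFER_SIZE == 240
        assert all(model.buffer.count(c) == 80 for c in CLASSES)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            gc.fit_map(np.zeros((10, 2)), np.array(["a"] * 10))

    def test_tiny_class_rejected(self):
        S = np.random.default_rng(0).normal(size=(10, 2))
        labels = np.array(["a"] * 8 + ["b"] * 2)
        with pytest.raises(ValueError, match="need >= 3"):
            gc.fit_map(S, labels)


class TestPosterior:
    def test_equidistant_point_splits_posterior(self):
        S = np.array([[-2.0, 0]] * 5 + [[2.0, 0]] * 5)
        S = S + np.array([[0, 0.1], [0, -0.1]] * 5)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        model = gc.fit_map(S, labels)
        post = gc.posterior(model, [0.0, 0.0])
        assert post[0] == pytest.approx(post[1], abs=1e-9)

    def test_matches_closed_form_density_oracle(self):
        model, means = _toy_model()
        rng = np.random.default_rng(5)
        for s in rng.normal(0, 3, (20, 2)):
            num = np.array([
                multivariate_normal.pdf(s, model.conditionals[c].mean,
                                        model.conditionals[c].cov) * p
                for c, p in zip(model.classes, model.priors)])
            assert np.allclose(gc.posterior(model, s), num / num.sum(), atol=1e-10)

    def test_normalization_over_many_random_points(self):
        model, _ = _toy_model()
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 50, (10000, 2))
        sums = [gc.posterior(model, s).sum() for s in pts[:200]]
        assert np.allclose(sums, 1.0, atol=1e-12)
        # extreme points exercise the log-space path
        assert gc.posterior(model, [1e4, 1e4]).sum() == pytest.approx(1.0)

    def test_non_finite_point_rejected(self):
        model, _ = _toy_model()
        with pytest.raises(ValueError, match="finite"):
            gc.posterior(model, [np.nan, 0.0])


class TestClassify:
    def test_equal_priors_equal_cov_is_nearest_mahalanobis(self):
        rng = np.random.default_rng(7)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        means = {"a": np.array([-2.0, 0]), "b": np.array([2.0, 0]),
                 "c": np.array([0.0, 3.0])}
        S, labels = [], []
        for c, m in means.items():
            S.append(rng.multivariate_normal(m, cov, 200))
            labels += [c] * 200
        model = gc.fit_map(np.vstack(S), np.asarray(labels))
        # force exactly shared covariance and equal priors
        for c in model.classes:
            model.conditionals[c] = gc.GaussianClassConditional(
                c, model.conditionals[c].mean, cov)
        icov = np.linalg.inv(cov)
        for s in rng.normal(0, 3, (200, 2)):
            label, _ = gc.classify_map(model, s)
            d2 = {c: (s - model.conditionals[c].mean) @ icov
                  @ (s - model.conditionals[c].mean) for c in model.classes}
            assert label == min(d2, key=d2.get)

    def test_skewed_priors_flip_borderline_decision(self):
        model, _ = _toy_model()
        s = np.array([0.0, 0.05])       # nearly equidistant from all classes
        base, _ = gc.classify_map(model, s)
        model.priors = np.where(np.array(model.classes) == base, 0.01, 0.98 / 2)
        model.priors = model.priors / model.priors.sum()
        flipped, _ = gc.classify_map(model, s)
        assert flipped != base

    def test_repeated_classification_without_update_is_stable(self):
        model, _ = _toy_model()
        s = [0.1, 0.2]
        out = [gc.classify_map(model, s, update=False) for _ in range(5)]
        assert all(o[0] == out[0][0] for o in out)
        assert all(np.array_equal(o[1], out[0][1]) for o in out)


class TestPriorBuffer:
    def test_fifo_eviction_counts(self):
        model, _ = _toy_model()
        # interleaved init: the globally oldest entry is a stair_climbing slot
        priors = update_priors(model, "walking")
        counts = {c: model.buffer.count(c) for c in model.classes}
        assert counts == {"stair_climbing": 79, "stair_descending": 80,
                          "walking": 81}
        assert np.allclose(priors, np.array([79, 80, 81]) / 240)

    def test_saturation_hits_floor(self):
        model, _ = _toy_model()
        for _ in range(240):
            update_priors(model, "walking")
        eps = model.prior_floor
        w = model.priors[model.classes.index("walking")]
        assert w >= 1 - 2 * eps
        others = [p for c, p in zip(model.classes, model.priors) if c != "walking"]
        assert np.allclose(others, eps)

    def test_update_can_change_next_decision(self):
        model, _ = _toy_model()
        s = np.array([0.0, 0.05])
        before, _ = gc.classify_map(model, s)
        # drive the buffer toward a different class
        target = next(c for c in model.classes if c != before)
        for _ in range(400):
            update_priors(model, target)
        after, _ = gc.classify_map(model, s)
        assert after == target != before

    def test_long_run_frequencies_tracked(self):
        model, _ = _toy_model()
        freqs = {"stair_climbing": 0.5, "stair_descending": 0.3, "walking": 0.2}
        rng = np.random.default_rng(8)
        stream = rng.choice(list(freqs), p=list(freqs.values()), size=2500)
        for lab in stream:
            update_priors(model, lab)
        for c, f in freqs.items():
            assert model.prior_of(c) == pytest.approx(f, abs=0.05)

    def test_unknown_label_rejected(self):
        model, _ = _toy_model()
        with pytest.raises(ValueError, match="unknown label"):
            update_priors(model, "jogging")

    def test_per_class_mode_keeps_counts(self):
        rng = np.random.default_rng(9)
        S = np.vstack([rng.normal([-3, 0], 1, (30, 2)),
                       rng.normal([3, 0], 1, (30, 2))])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        model = gc.fit_map(S, labels, buffer_mode="per_class")
        before = {c: model.buffer.count(c) for c in model.classes}
        update_priors(model, "a")
        after = {c: model.buffer.count(c) for c in model.classes}
        assert before == after


class TestRecovery:
    def test_fit_recovers_known_gaussians(self):
        rng = np.random.default_rng(10)
        mean_a, cov_a = np.array([1.0, -2.0]), np.array([[2.0, 0.5], [0.5, 1.0]])
        mean_b, cov_b = np.array([-3.0, 4.0]), np.array([[1.0, -0.3], [-0.3, 2.0]])
        n = 5000
        S = np.vstack([rng.multivariate_normal(mean_a, cov_a, n),
                       rng.multivariate_normal(mean_b, cov_b, n)])
        labels = np.array(["a"] * n + ["b"] * n)
        model = gc.fit_map(S, labels)
        for mean, cov, c in [(mean_a, cov_a, "a"), (mean_b, cov_b, "b")]:
            se = np.sqrt(np.diag(cov) / n)
            assert np.all(np.abs(model.conditionals[c].mean - mean) < 3 * se)
            rel = np.linalg.norm(model.conditionals[c].cov - cov) / np.linalg.norm(cov)
            assert rel < 0.10

    def test_json_round_trip(self):
        model, _ = _toy_model()
        obj = model.to_json()
        back = gc.MAPModel.from_json(obj)
        s = [0.5, -0.5]
        assert np.allclose(gc.posterior(back, s), gc.posterior(model, s))
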