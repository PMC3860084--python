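"""MDM-style soft-margin SVM solver and one-vs-one voting."""

import numpy as np
import pytest
from scipy.optimize import minimize

import gaitclass as gc
from gaitclass.svm_classifier import (BinarySVM, dual_objective,
                                      train_binary_svm, _compute_b)


def qp_oracle(X, y, C):
    """Generic convex QP solver on the identical dual (independent oracle)."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)
    res = minimize(lambda a: 0.5 * a @ Q @ a - a.sum(),
                   np.full(n, min(C, 1.0) * 0.5),
                   jac=lambda a: Q @ a - 1.0,
                   bounds=[(0.0, C)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                 "jac": lambda a: y}],
                   method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
    return res.x


class TestBinarySVM:
    def test_two_point_problem_analytic_solution(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        y = np.array([-1.0, 1.0])
        m = train_binary_svm(X, y, C=5.0)
        # hard-margin optimum: alpha = (0.5, 0.5), w = (1, 0), b = 0
        assert np.allclose(m.alphas, 0.5, atol=1e-8)
        assert np.allclose(m.w, [1.0, 0.0], atol=1e-8)
        assert m.b == pytest.approx(0.0, abs=1e-8)

    def test_coordinate_scaling_rescales_w_inversely(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        y = np.array([-1.0, 1.0])
        m1 = train_binary_svm(X, y, C=5.0)
        m2 = train_binary_svm(4.0 * X, y, C=5.0)
        assert np.allclose(m2.w, m1.w / 4.0, atol=1e-8)

    def test_separable_data_zero_training_error_and_kkt(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal([-4, 0], 0.5, (20, 2)),
                       rng.normal([4, 0], 0.5, (20, 2))])
        y = np.concatenate([-np.ones(20), np.ones(20)])
        m = train_binary_svm(X, y, C=50.0, tol=1e-8)
        assert m.converged
        margins = y * (X @ m.w + m.b)
        assert np.all(margins > 0)               # zero training error
        # complementary slackness: unbounded SVs sit on the margin
        on = (m.alphas > 1e-6) & (m.alphas < 50.0 - 1e-6)
        assert np.allclose(margins[on], 1.0, atol=1e-4)

    def test_dual_constraints_hold(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 2))
        y = np.sign(X[:, 0] + 0.3 * rng.standard_normal(40))
        y[y == 0] = 1.0
        m = train_binary_svm(X, y, C=5.0)
        assert np.all(m.alphas >= -1e-12)
        assert np.all(m.alphas <= 5.0 + 1e-12)
        assert abs(m.alphas @ y) < 1e-8
        assert np.allclose(m.w, X.T @ (m.alphas * y), atol=1e-8)
        assert m.gap <= 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_qp_oracle_on_overlapping_classes(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        X = np.vstack([rng.normal([-1, 0], 1.0, (n // 2, 2)),
                       rng.normal([1, 0], 1.0, (n // 2, 2))])
        y = np.concatenate([-np.ones(n // 2), np.ones(n // 2)])
        m = train_binary_svm(X, y, C=5.0, tol=1e-6)
        a_qp = qp_oracle(X, y, 5.0)
        assert dual_objective(X, y, m.alphas) == pytest.approx(
            dual_objective(X, y, a_qp), abs=1e-6)
        g = np.linspace(-3, 3, 12)
        G = np.array(np.meshgrid(g, g)).reshape(2, -1).T
        w_qp = X.T @ (a_qp * y)
        b_qp = _compute_b(y, a_qp, X @ w_qp, 5.0)
        assert np.array_equal(np.sign(G @ m.w + m.b), np.sign(G @ w_qp + b_qp))

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError, match="both"):
            train_binary_svm(np.zeros((4, 2)), np.ones(4))

    def test_non_positive_C_rejected(self):
        with pytest.raises(ValueError, match="C must be positive"):
            train_binary_svm(np.zeros((4, 2)),
                             np.array([1.0, -1, 1, -1]), C=0.0)


@pytest.fixture(scope="module")
def separable_model():
    rng = np.random.default_rng(3)
    means = {"stair_climbing": [-5, 0], "stair_descending": [5, 0],
             "walking": [0, 6]}
    X, labels = [], []
    for c, m in means.items():
        X.append(rng.normal(m, 0.8, (40, 2)))
        labels += [c] * 40
    return gc.train_ovo(np.vstack(X), np.asarray(labels), C=5.0), means


class TestOneVsOne:
    def test_machine_count_is_k_choose_2(self, separable_model):
        model, _ = separable_model
        assert len(model.machines) == 3

    def test_interior_point_gets_two_votes(self, separable_model):
        model, means = separable_model
        for c, m in means.items():
            label, votes = gc.classify_ovo(model, m)
            assert label == c
            assert votes[c] == 2

    def test_cyclic_tie_is_deterministic(self):
        # hand-built machines voting a -> b -> c -> a: exercise tie-break
        ma = BinarySVM("a", "b", np.zeros(0), np.array([1.0, 0]), 0.0, 5.0, 0.0)
        mb = BinarySVM("b", "c", np.zeros(0), np.array([0.0, 1.0]), 0.0, 5.0, 0.0)
        mc = BinarySVM("c", "a", np.zeros(0), np.array([-1.0, -1.0]), 0.5, 5.0, 0.0)
        model = gc.OvOSVMModel(classes=["a", "b", "c"], machines=[ma, mb, mc])
        s = np.array([0.4, 0.1])
        label, votes = gc.classify_ovo(model, s)
        assert sorted(votes.values()) == [1, 1, 1]
        assert label == gc.classify_ovo(model, s)[0]
        # strongest summed |decision| among the tied labels wins
        strength = {c: 0.0 for c in model.classes}
        for m in model.machines:
            d = abs(float(s @ m.w + m.b))
            strength[m.pos_label] += d
            strength[m.neg_label] += d
        assert label == max(strength, key=strength.get)

    def test_batch_agrees_with_single_calls(self, separable_model):
        model, _ = separable_model
        rng = np.random.default_rng(4)
        S = rng.normal(0, 4, (25, 2))
        batch = gc.classify_ovo_batch(model, S)
        singles = [gc.classify_ovo(model, s)[0] for s in S]
        assert batch == singles

    def test_json_round_trip(self, separable_model, tmp_path):
        model, _ = separable_model
        path = tmp_path / "svm.json"
        model.to_json(path)
        back = gc.OvOSVMModel.from_json(str(path))
        rng = np.random.default_rng(5)
        S = rng.normal(0, 4, (20, 2))
        assert gc.classify_ovo_batch(back, S) == gc.classify_ovo_batch(model, S)
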