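"""Linear soft-margin SVM trained by pairwise coefficient transfer
(Mitchell-Demyanov-Malozemov style), one-vs-one with max-wins voting.

The binary machine solves the standard soft-margin dual

    max  sum(alpha) - 1/2 sum_ij alpha_i alpha_j y_i y_j <x_i, x_j>
    s.t. 0 <= alpha_i <= C,   sum_i alpha_i y_i = 0,

with C = 5 by default and no kernel: the upstream surrogate network is
the nonlinear map, so the machines operate on the 2-D coordinates.

Each iteration selects the maximal-KKT-violating pair of coefficients
and transfers mass between them with the closed-form step, clipped to
the box — the two-coordinate update that the MDM nearest-point method
applies to its hull coefficients.  When the selected pair shares a label
the step is a pure within-class transfer; cross-class pairs let total
mass grow from the deterministic all-zero start.  Iteration stops when
the duality gap (hinge-loss primal minus dual objective) drops to
``tol``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

logger = logging.getLogger("gaitclass")

__all__ = [
    "BinarySVM",
    "OvOSVMModel",
    "train_binary_svm",
    "train_ovo",
    "classify_ovo",
    "classify_ovo_batch",
    "decision_function",
]


@dataclass
class BinarySVM:
    """One trained binary machine of the one-vs-one ensemble."""

    pos_label: object
    neg_label: object
    alphas: np.ndarray
    w: np.ndarray
    b: float
    C: float
    gap: float
    converged: bool = True
    n_iter: int = 0

    def decision(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.w + self.b


def _index_sets(y, alphas, C, eps):
    """KKT index sets: I_up can receive mass upward, I_low downward."""
    I_up = ((y > 0) & (alphas < C - eps)) | ((y < 0) & (alphas > eps))
    I_low = ((y > 0) & (alphas > eps)) | ((y < 0) & (alphas < C - eps))
    return I_up, I_low


def _compute_b(y, alphas, f, C):
    """Bias from unbounded support vectors, else KKT-interval midpoint.

    KKT with bias: alpha_i < C implies y_i(f_i + b) >= 1 and alpha_i > 0
    implies y_i(f_i + b) <= 1, which makes (y - f) over I_up the lower
    bounds on b and over I_low the upper bounds.
    """
    eps = 1e-8 * max(C, 1.0)
    unbounded = (alphas > eps) & (alphas < C - eps)
    if unbounded.any():
        return float(np.mean(y[unbounded] - f[unbounded]))
    I_up, I_low = _index_sets(y, alphas, C, eps)
    v = y - f
    lo = np.max(v[I_up]) if I_up.any() else -np.inf
    hi = np.min(v[I_low]) if I_low.any() else np.inf
    if np.isinf(lo) and np.isinf(hi):
        return 0.0
    if np.isinf(lo):
        return float(hi)
    if np.isinf(hi):
        return float(lo)
    return float((lo + hi) / 2.0)


def _duality_gap(X, y, alphas, w, b, C):
    margins = y * (X @ w + b)
    primal = 0.5 * w @ w + C * np.sum(np.maximum(0.0, 1.0 - margins))
    dual = alphas.sum() - 0.5 * w @ w
    return float(primal - dual)


def dual_objective(X, y, alphas) -> float:
    """Soft-margin dual objective at ``alphas`` (to maximize)."""
    w = np.asarray(X, dtype=float).T @ (alphas * y)
    return float(alphas.sum() - 0.5 * w @ w)


def train_binary_svm(X: np.ndarray, y: np.ndarray, C: float = 5.0,
                     tol: float = 1e-6, max_iter: int = 200000) -> BinarySVM:
    """Solve the soft-margin dual for a two-class problem.

    ``y`` must be +/-1 with both classes present.  Starts
    deterministically from alpha = 0 and iterates maximal-violating-pair
    transfers until the duality gap is at most ``tol`` (or ``max_iter``
    is hit, in which case the model carries ``converged=False``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, d) with one label per row")
    uniq = set(np.unique(y).tolist())
    if not uniq.issubset({-1.0, 1.0}) or len(uniq) < 2:
        raise ValueError("y must contain both +1 and -1 labels")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    n = y.size
    K = X @ X.T
    K_diag = np.diag(K).copy()
    alphas = np.zeros(n)
    f = np.zeros(n)             # f_i = <w, x_i>
    eps_a = 1e-12
    it = 0
    check_every = max(16, n // 2)
    for it in range(1, max_iter + 1):
        # optimality measure: max over I_up of (y - f) vs min over I_low
        v = y - f
        I_up, I_low = _index_sets(y, alphas, C, eps_a)
        if not I_up.any() or not I_low.any():
            break
        i = int(np.argmax(np.where(I_up, v, -np.inf)))
        j = int(np.argmin(np.where(I_low, v, np.inf)))
        violation = v[i] - v[j]
        if violation < 1e-14:
            break
        eta = max(K_diag[i] + K_diag[j] - 2.0 * K[i, j], 1e-12)
        # move along u: alpha_i += y_i t, alpha_j -= y_j t (keeps sum alpha*y)
        t = violation / eta
        t_max_i = (C - alphas[i]) if y[i] > 0 else alphas[i]
        t_max_j = alphas[j] if y[j] > 0 else (C - alphas[j])
        t = min(t, t_max_i, t_max_j)
        if t <= 0:
            break
        alphas[i] += y[i] * t
        alphas[j] -= y[j] * t
        f += t * (K[i] - K[j])
        if it % check_every == 0 or violation < 1e-10:
            w = X.T @ (alphas * y)
            b = _compute_b(y, alphas, f, C)
            if _duality_gap(X, y, alphas, w, b, C) <= tol:
                break
    w = X.T @ (alphas * y)
    b = _compute_b(y, alphas, f, C)
    gap = _duality_gap(X, y, alphas, w, b, C)
    converged = gap <= tol
    if not converged:
        logger.warning("binary SVM stopped after %d iterations with duality gap "
                       "%.3g > tol %.3g", it, gap, tol)
    return BinarySVM(None, None, alphas, w, float(b), C, gap, converged, it)


@dataclass
class OvOSVMModel:
    """One-vs-one ensemble: one binary machine per unordered class pair.

    Prediction is max-wins voting; vote ties go to the tied label with
    the largest sum of absolute decision values over its machines, then
    to fixed (sorted) label order.
    """

    classes: list
    machines: list          # of BinarySVM, pair order = combinations(classes, 2)
    tie_rule: str = "sum-abs-decision, then label order"

    def to_json(self, path=None):
        obj = {
            "kind": "svm",
            "classes": list(self.classes),
            "machines": [
                {"pos": m.pos_label, "neg": m.neg_label, "w": m.w.tolist(),
                 "b": m.b, "C": m.C, "gap": m.gap, "converged": m.converged}
                for m in self.machines
            ],
        }
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, src) -> "OvOSVMModel":
        obj = src if isinstance(src, dict) else json.load(open(src))
        machines = [
            BinarySVM(m["pos"], m["neg"], np.zeros(0), np.asarray(m["w"]),
                      m["b"], m["C"], m["gap"], m["converged"])
            for m in obj["machines"]
        ]
        return cls(classes=list(obj["classes"]), machines=machines)


def train_ovo(X: np.ndarray, labels, C: float = 5.0, tol: float = 1e-6,
              max_iter: int = 200000) -> OvOSVMModel:
    """Train k(k-1)/2 binary machines, one per unordered class pair."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes, got {classes}")
    machines = []
    for a, bcl in combinations(classes, 2):
        sel = (labels == a) | (labels == bcl)
        Xp = X[sel]
        yp = np.where(labels[sel] == a, 1.0, -1.0)
        m = train_binary_svm(Xp, yp, C=C, tol=tol, max_iter=max_iter)
        m.pos_label, m.neg_label = a, bcl
        machines.append(m)
    return OvOSVMModel(classes=classes, machines=machines)


def decision_function(model: OvOSVMModel, s) -> dict:
    """Per-pair signed decision values for a single point."""
    s = np.asarray(s, dtype=float).ravel()
    return {(m.pos_label, m.neg_label): float(s @ m.w + m.b) for m in model.machines}


def classify_ovo(model: OvOSVMModel, s):
    """Max-wins vote over all pairwise machines for one 2-D point.

    Returns ``(label, votes)`` where ``votes`` maps each class to its
    vote count.  A decision value of exactly zero votes for the pair's
    positive (first-in-sorted-order) label.
    """
    s = np.asarray(s, dtype=float).ravel()
    votes = {c: 0 for c in model.classes}
    strength = {c: 0.0 for c in model.classes}
    for m in model.machines:
        d = float(s @ m.w + m.b)
        winner = m.pos_label if d >= 0 else m.neg_label
        votes[winner] += 1
        strength[m.pos_label] += abs(d)
        strength[m.neg_label] += abs(d)
    best = max(votes.values())
    tied = [c for c in model.classes if votes[c] == best]
    if len(tied) > 1:
        top = max(strength[c] for c in tied)
        tied = [c for c in tied if strength[c] == top]
    return tied[0], votes


def classify_ovo_batch(model: OvOSVMModel, S) -> list:
    """Predicted label for each row of ``S``."""
    return [classify_ovo(model, s)[0] for s in np.atleast_2d(np.asarray(S, dtype=float))]
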