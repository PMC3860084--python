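"""Sammon nonlinear mapping of the 16-D feature space to 2-D, and a
feed-forward surrogate network that mimics it.

Sammon's mapping minimizes the stress

    E = (1 / sum_{i<j} d*_ij) * sum_{i<j} (d*_ij - d_ij)^2 / d*_ij,

where d* are pairwise Euclidean distances in the (standardized) input
space and d the distances in the 2-D embedding.  The classic
diagonal-Newton update with "magic factor" 0.35 is used, with
step-halving whenever a step would increase the stress, so the accepted
stress sequence is non-increasing.

Because the mapping is iterative and has no closed-form out-of-sample
extension, a multilayer perceptron (16 inputs, one hidden layer of 40
tanh units, 2 linear outputs) is trained to reproduce it from a 15%
random subset of the mapped points, using Levenberg-Marquardt on the
full weight vector.  Training stops when the normalized mean square
error — MSE divided by the variance of the target coordinates — falls
below 0.1%; at that error the surrogate's per-dimension correlation
with the true Sammon coordinates exceeds 0.98.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("gaitclass")

__all__ = [
    "SammonEmbedding",
    "SurrogateModel",
    "sammon_map",
    "sammon_stress",
    "train_surrogate",
    "predict_surrogate",
]


# --------------------------------------------------------------------------
# Sammon mapping
# --------------------------------------------------------------------------

def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd, mu, sd


@dataclass
class SammonEmbedding:
    """Result of a Sammon mapping run."""

    Y: np.ndarray           # (n, 2) embedded coordinates
    stress: float           # final stress
    n_iter: int
    stress_history: np.ndarray = field(default=None, repr=False)


def sammon_stress(X_or_D, Y: np.ndarray, *, standardized: bool = False) -> float:
    """Brute-force Sammon stress of embedding ``Y`` for inputs ``X``.

    ``X_or_D`` may be the raw feature matrix (standardized internally
    unless ``standardized=True``) or a precomputed condensed/square
    distance matrix.  Zero input-space distances are excluded from the
    sum, matching :func:`sammon_map`.
    """
    X_or_D = np.asarray(X_or_D, dtype=float)
    if X_or_D.ndim == 2 and X_or_D.shape[0] == X_or_D.shape[1] and np.allclose(
            X_or_D, X_or_D.T) and np.allclose(np.diag(X_or_D), 0):
        dstar = squareform(X_or_D, checks=False)
    elif X_or_D.ndim == 1:
        dstar = X_or_D
    else:
        Xs = X_or_D if standardized else _standardize(X_or_D)[0]
        dstar = pdist(Xs)
    d = pdist(np.asarray(Y, dtype=float))
    keep = dstar > 0
    dstar, d = dstar[keep], d[keep]
    c = dstar.sum()
    return float(((dstar - d) ** 2 / dstar).sum() / c)


def _pca_init(Xs: np.ndarray) -> np.ndarray:
    Xc = Xs - Xs.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ Vt[:2].T


def sammon_map(X: np.ndarray, max_iter: int = 500, tol: float = 1e-9,
               seed: int | None = None, init: str = "pca", magic: float = 0.35,
               standardize: bool = True) -> SammonEmbedding:
    """Embed an (n, p) feature matrix in 2-D by Sammon stress minimization.

    Features are z-scored before distance computation by default (the 16
    gait features have heterogeneous units).  ``init`` is ``"pca"`` (the
    first two principal components, deterministic) or ``"random"``
    (seeded Gaussian).  ``tol`` is the relative stress decrease at which
    iteration stops.  Coincident input points (zero pairwise distance)
    are dropped from the stress sum with a log notice.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError(f"need an (n >= 3, p) matrix, got shape {X.shape}")
    n = X.shape[0]
    Xs = _standardize(X)[0] if standardize else X

    Dstar = squareform(pdist(Xs))
    off = ~np.eye(n, dtype=bool)
    zero_pairs = (Dstar <= 0) & off
    if zero_pairs.any():
        logger.info("dropping %d coincident input pairs from the stress sum",
                    int(zero_pairs.sum()) // 2)
    include = off & ~zero_pairs
    c = Dstar[include].sum() / 2.0  # each pair counted once

    if init == "pca":
        Y = _pca_init(Xs)
    elif init == "random":
        rng = np.random.default_rng(seed)
        Y = rng.standard_normal((n, 2))
    else:
        raise ValueError(f"init must be 'pca' or 'random', got {init!r}")

    inv_dstar = np.zeros_like(Dstar)
    inv_dstar[include] = 1.0 / Dstar[include]

    def stress_of(Yc):
        D = squareform(pdist(Yc))
        diff = Dstar - D
        return float((diff[include] ** 2 * inv_dstar[include]).sum() / 2.0 / c)

    cur = stress_of(Y)
    history = [cur]
    it = 0
    for it in range(1, max_iter + 1):
        D = squareform(pdist(Y))
        D_safe = np.where(D > 1e-12, D, 1e-12)
        B = Dstar - D
        A = inv_dstar / D_safe          # 1/(d* d), zero on excluded pairs
        W = B * A
        grad = np.empty_like(Y)
        hess = np.empty_like(Y)
        for k in range(2):
            dk = Y[:, k][:, None] - Y[:, k][None, :]
            grad[:, k] = (-2.0 / c) * (W * dk).sum(axis=1)
            hess[:, k] = (-2.0 / c) * (
                A * (B - (dk ** 2 / D_safe) * (1.0 + B / D_safe))
            ).sum(axis=1)
        denom = np.abs(hess)
        denom = np.where(denom > 1e-12, denom, 1e-12)
        step = magic * grad / denom
        accepted = False
        for _ in range(30):
            Y_try = Y - step
            s_try = stress_of(Y_try)
            if s_try <= cur:
                accepted = True
                break
            step = step / 2.0
        if not accepted:
            break
        rel = (cur - s_try) / max(cur, 1e-300)
        Y, cur = Y_try, s_try
        history.append(cur)
        if rel < tol:
            break

    return SammonEmbedding(Y=Y, stress=cur, n_iter=it,
                           stress_history=np.asarray(history))


# --------------------------------------------------------------------------
# MLP surrogate, Levenberg-Marquardt training
# --------------------------------------------------------------------------

@dataclass
class SurrogateModel:
    """16-40-2 MLP mimicking the Sammon mapping.

    Inputs are z-scored with the stored means/scales; hidden activation
    is tanh, output is linear.  ``mse`` is the achieved training MSE as a
    fraction of target variance; ``converged`` records whether the
    stopping criterion was met.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    W1: np.ndarray          # (hidden, n_in)
    b1: np.ndarray
    W2: np.ndarray          # (n_out, hidden)
    b2: np.ndarray
    mse: float
    converged: bool
    method: str = "levenberg-marquardt"
    train_idx: np.ndarray = field(default=None, repr=False)

    @property
    def hidden_width(self) -> int:
        return self.W1.shape[0]

    def to_json(self, path=None):
        obj = {
            "kind": "surrogate",
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "shapes": {"W1": list(self.W1.shape), "W2": list(self.W2.shape)},
            "mse": self.mse, "converged": self.converged, "method": self.method,
        }
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, src) -> "SurrogateModel":
        if isinstance(src, dict):
            obj = src
        else:
            with open(src) as fh:
                obj = json.load(fh)
        return cls(
            x_mean=np.asarray(obj["x_mean"]), x_scale=np.asarray(obj["x_scale"]),
            W1=np.asarray(obj["W1"]), b1=np.asarray(obj["b1"]),
            W2=np.asarray(obj["W2"]), b2=np.asarray(obj["b2"]),
            mse=obj["mse"], converged=obj["converged"], method=obj["method"],
        )


def _forward(model_or_params, Xs):
    if isinstance(model_or_params, SurrogateModel):
        W1, b1, W2, b2 = model_or_params.W1, model_or_params.b1, \
            model_or_params.W2, model_or_params.b2
    else:
        W1, b1, W2, b2 = model_or_params
    H = np.tanh(Xs @ W1.T + b1)
    return H @ W2.T + b2, H


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(theta, n_in, hid, n_out):
    i = 0
    W1 = theta[i:i + hid * n_in].reshape(hid, n_in); i += hid * n_in
    b1 = theta[i:i + hid]; i += hid
    W2 = theta[i:i + n_out * hid].reshape(n_out, hid); i += n_out * hid
    b2 = theta[i:i + n_out]
    return W1, b1, W2, b2


def _jacobian(theta, Xs, n_out):
    """Jacobian of the stacked residual vector w.r.t. the weight vector."""
    n, n_in = Xs.shape
    hid = (theta.size - n_out) // (n_in + 1 + n_out)
    W1, b1, W2, b2 = _unpack(theta, n_in, hid, n_out)
    Z = Xs @ W1.T + b1
    H = np.tanh(Z)
    dH = 1.0 - H ** 2                       # (n, hid)
    n_par = theta.size
    J = np.zeros((n * n_out, n_par))
    for k in range(n_out):
        rows = slice(k * n, (k + 1) * n)
        G = W2[k] * dH                      # (n, hid)
        J[rows, :hid * n_in] = (G[:, :, None] * Xs[:, None, :]).reshape(n, hid * n_in)
        J[rows, hid * n_in:hid * (n_in + 1)] = G
        J[rows, hid * (n_in + 1) + k * hid:hid * (n_in + 1) + (k + 1) * hid] = H
        J[rows, -n_out + k] = 1.0
    return J


def train_surrogate(X: np.ndarray, Y: np.ndarray, subset_frac: float = 0.15,
                    mse_target: float = 0.001, seed: int | None = None,
                    hidden: int = 40, max_epochs: int = 400) -> SurrogateModel:
    """Train the MLP surrogate on a random subset of Sammon pairs.

    A seeded random ``subset_frac`` of the (feature, embedding) pairs is
    drawn, inputs are z-scored, and the 16-40-2 network is fitted by
    Levenberg-Marquardt.  Training stops once MSE / var(targets) drops
    below ``mse_target`` (0.1% by default); otherwise the best weights
    are returned with ``converged=False`` and a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[0] < 100:
        raise ValueError(f"need at least 100 pairs to train, got {X.shape[0]}")
    n_sub = max(10, int(round(subset_frac * X.shape[0])))
    rng = np.random.default_rng(seed)
    idx = rng.choice(X.shape[0], size=n_sub, replace=False)
    Xt, T = X[idx], Y[idx]
    Xs, mu, sd = _standardize(Xt)
    n_in, n_out = Xs.shape[1], T.shape[1]

    var_T = float(np.mean((T - T.mean(axis=0)) ** 2))
    if var_T < 1e-300:
        # constant targets: the zero-hidden network with output bias = mean
        W1 = rng.standard_normal((hidden, n_in)) * 0.1
        model = SurrogateModel(mu, sd, W1, np.zeros(hidden),
                               np.zeros((n_out, hidden)), T.mean(axis=0).copy(),
                               mse=0.0, converged=True, train_idx=idx)
        return model

    W1 = rng.standard_normal((hidden, n_in)) / np.sqrt(n_in)
    b1 = np.zeros(hidden)
    W2 = rng.standard_normal((n_out, hidden)) / np.sqrt(hidden)
    b2 = T.mean(axis=0).copy()
    theta = _pack(W1, b1, W2, b2)

    def residual(th):
        P, _ = _forward(_unpack(th, n_in, hidden, n_out), Xs)
        return (P - T).T.ravel()            # stacked by output dim

    r = residual(theta)
    sse = float(r @ r)
    lam = 1e-2
    nmse = sse / (r.size * var_T)
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        if nmse < mse_target:
            break
        J = _jacobian(theta, Xs, n_out)
        JtJ = J.T @ J
        Jtr = J.T @ r
        improved = False
        for _ in range(30):
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(theta.size), -Jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            r_try = residual(theta + delta)
            sse_try = float(r_try @ r_try)
            if sse_try < sse:
                theta = theta + delta
                r, sse = r_try, sse_try
                lam = max(lam / 5.0, 1e-12)
                improved = True
                break
            lam *= 5.0
        nmse = sse / (r.size * var_T)
        if not improved:
            break

    converged = bool(nmse < mse_target)
    if not converged:
        logger.warning("surrogate training stopped at normalized MSE %.3g "
                       "(target %.3g) after %d epochs", nmse, mse_target, epoch)
    W1, b1, W2, b2 = _unpack(theta, n_in, hidden, n_out)
    return SurrogateModel(mu, sd, W1, b1, W2, b2, mse=float(nmse),
                          converged=converged, train_idx=idx)


def predict_surrogate(model: SurrogateModel, x) -> np.ndarray:
    """Deterministic feed-forward prediction; accepts a vector or batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if not np.isfinite(X).all():
        raise ValueError("surrogate input contains non-finite values")
    if X.shape[1] != model.x_mean.size:
        raise ValueError(f"expected {model.x_mean.size} features, got {X.shape[1]}")
    Xs = (X - model.x_mean) / model.x_scale
    P, _ = _forward(model, Xs)
    return P[0] if single else P
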