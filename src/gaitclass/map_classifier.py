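"""Maximum-a-posteriori Bayes classifier on the 2-D mapped features.

Class-conditional densities are bivariate Gaussians with moments
estimated from the training set.  Priors start uniform and then adapt at
run time: the last 240 predicted activity identifiers are kept in a FIFO
buffer whose class frequencies, floored at epsilon = 1/480 and
renormalized, are the current priors.  The floor prevents an absorbing
state in which a class whose prior has decayed to zero can never be
predicted again.

The buffer is updated with the *predicted* label — the deployment
scenario has no ground truth available — and by default the oldest entry
overall is evicted (a plain FIFO of the last 240 predictions, which makes
the priors track recent class frequencies).  An alternative per-class
mode that refreshes the oldest entry of the predicted class, leaving the
class counts unchanged, is available via ``buffer_mode``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger("gaitclass")

__all__ = [
    "GaussianClassConditional",
    "MAPModel",
    "fit_map",
    "posterior",
    "classify_map",
    "update_priors",
]

BUFFER_SIZE = 240


@dataclass
class GaussianClassConditional:
    """Bivariate Gaussian density p(s | activity)."""

    label: str
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() <= 0:
            raise ValueError("covariance must be positive definite")
        self._cov_inv = np.linalg.inv(self.cov)
        self._log_norm = -0.5 * (self.mean.size * np.log(2 * np.pi)
                                 + np.log(np.linalg.det(self.cov)))

    def log_pdf(self, s: np.ndarray) -> float:
        d = np.asarray(s, dtype=float).ravel() - self.mean
        return float(self._log_norm - 0.5 * d @ self._cov_inv @ d)


@dataclass
class MAPModel:
    """Fitted MAP classifier state."""

    classes: list
    conditionals: dict                       # label -> GaussianClassConditional
    priors: np.ndarray                       # aligned with classes
    buffer: list                             # FIFO of predicted labels
    prior_floor: float = 1.0 / (2 * BUFFER_SIZE)
    buffer_mode: str = "fifo"                # or "per_class"
    _stamps: list = field(default_factory=list, repr=False)
    _clock: int = field(default=0, repr=False)

    def prior_of(self, label) -> float:
        return float(self.priors[self.classes.index(label)])

    def to_json(self, path=None):
        obj = {
            "kind": "map",
            "classes": list(self.classes),
            "means": {c: self.conditionals[c].mean.tolist() for c in self.classes},
            "covs": {c: self.conditionals[c].cov.tolist() for c in self.classes},
            "priors": self.priors.tolist(),
            "buffer": list(self.buffer),
            "prior_floor": self.prior_floor,
            "buffer_mode": self.buffer_mode,
        }
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, src) -> "MAPModel":
        obj = src if isinstance(src, dict) else json.load(open(src))
        conds = {c: GaussianClassConditional(c, obj["means"][c], obj["covs"][c])
                 for c in obj["classes"]}
        model = cls(classes=list(obj["classes"]), conditionals=conds,
                    priors=np.asarray(obj["priors"]), buffer=list(obj["buffer"]),
                    prior_floor=obj["prior_floor"], buffer_mode=obj["buffer_mode"])
        model._stamps = list(range(len(model.buffer)))
        model._clock = len(model.buffer)
        return model


def fit_map(S: np.ndarray, labels, buffer_size: int = BUFFER_SIZE,
            prior_floor: float | None = None, buffer_mode: str = "fifo") -> MAPModel:
    """Fit per-class Gaussian moments and initialize uniform priors.

    The prior buffer starts with equal per-class counts (``buffer_size``
    divided evenly, interleaved) so that the initial count-based priors
    are the hypothesized uniform ones.
    """
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    if S.ndim != 2:
        raise ValueError("S must be an (n, d) matrix")
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes, got {classes}")
    conds = {}
    for c in classes:
        Sc = S[labels == c]
        if Sc.shape[0] < 3:
            raise ValueError(f"class {c!r} has {Sc.shape[0]} samples, need >= 3")
        mean = Sc.mean(axis=0)
        cov = np.cov(Sc, rowvar=False, ddof=1)
        ev_min = np.linalg.eigvalsh(cov).min()
        if ev_min < 1e-10 * np.trace(cov) or ev_min <= 0:
            ridge = 1e-6 * np.trace(cov) if np.trace(cov) > 0 else 1e-6
            cov = cov + ridge * np.eye(cov.shape[0])
            logger.info("regularized near-singular covariance of class %r "
                        "(ridge %.3g)", c, ridge)
        conds[c] = GaussianClassConditional(c, mean, cov)
    k = len(classes)
    base, rem = divmod(buffer_size, k)
    buffer = [classes[i % k] for i in range(base * k)]
    buffer += classes[:rem]
    priors = np.full(k, 1.0 / k)
    if prior_floor is None:
        prior_floor = 1.0 / (2 * buffer_size)
    model = MAPModel(classes=classes, conditionals=conds, priors=priors,
                     buffer=buffer, prior_floor=prior_floor, buffer_mode=buffer_mode)
    model._stamps = list(range(len(buffer)))
    model._clock = len(buffer)
    return model


def _log_joint(model: MAPModel, s) -> np.ndarray:
    lp = np.array([model.conditionals[c].log_pdf(s) for c in model.classes])
    return lp + np.log(model.priors)


def posterior(model: MAPModel, s) -> np.ndarray:
    """Per-class posterior P(activity | s), aligned with ``model.classes``.

    Computed in log space; if every class-conditional density underflows
    the posteriors are still well defined from the log densities.
    """
    s = np.asarray(s, dtype=float).ravel()
    if not np.isfinite(s).all():
        raise ValueError("input point contains non-finite values")
    lj = _log_joint(model, s)
    if np.all(lj == -np.inf):
        logger.warning("all class densities underflow at %s; uniform posterior", s)
        return np.full(len(model.classes), 1.0 / len(model.classes))
    return np.exp(lj - logsumexp(lj))


def classify_map(model: MAPModel, s, update: bool = False):
    """MAP decision: argmax of the posterior, ties to the first class in
    sorted label order.  With ``update=True`` the predicted label is
    pushed into the prior buffer and the priors recomputed, so the next
    call sees the adapted priors."""
    post = posterior(model, s)
    label = model.classes[int(np.argmax(post))]
    if update:
        update_priors(model, label)
    return label, post


def update_priors(model: MAPModel, new_label) -> np.ndarray:
    """Push a classified activity into the buffer and recompute priors.

    FIFO mode evicts the globally oldest entry.  Counts are divided by
    the buffer length, floored at ``prior_floor`` and the remaining mass
    shared proportionally among the unfloored classes.
    """
    if new_label not in model.classes:
        raise ValueError(f"unknown label {new_label!r}; classes are {model.classes}")
    if model.buffer_mode == "fifo":
        oldest = int(np.argmin(model._stamps))
        model.buffer[oldest] = new_label
        model._stamps[oldest] = model._clock
    elif model.buffer_mode == "per_class":
        own = [i for i, lab in enumerate(model.buffer) if lab == new_label]
        if own:
            oldest = min(own, key=lambda i: model._stamps[i])
        else:  # class absent from buffer: fall back to global eviction
            oldest = int(np.argmin(model._stamps))
        model.buffer[oldest] = new_label
        model._stamps[oldest] = model._clock
    else:
        raise ValueError(f"unknown buffer_mode {model.buffer_mode!r}")
    model._clock += 1

    n = len(model.buffer)
    counts = np.array([model.buffer.count(c) for c in model.classes], dtype=float)
    priors = counts / n
    eps = model.prior_floor
    low = priors < eps
    if low.any():
        priors[low] = eps
        rest = ~low
        mass = 1.0 - low.sum() * eps
        priors[rest] = priors[rest] / priors[rest].sum() * mass
    model.priors = priors
    return priors
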