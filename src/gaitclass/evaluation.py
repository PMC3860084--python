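"""Classification performance indicators: per-class rates, row-normalized
confusion matrix, and normalized mutual information (NMI).

NMI here is mutual information between the actual and predicted label
distributions divided by the geometric mean of the two marginal
entropies (the Strehl-Ghosh convention, natural logs); it is 1 for
perfect agreement, 0 for independence, and 0 by convention when either
marginal entropy vanishes.  This normalization, applied to the published
row-percentage confusion tables with actual-class marginals taken from
the dataset composition, reproduces both reported NMI values, which is
how the convention was pinned down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("gaitclass")

__all__ = [
    "ConfusionResult",
    "confusion",
    "nmi_from_joint",
    "joint_from_rowpct",
    "stratified_split",
]


@dataclass
class ConfusionResult:
    """Confusion counts with derived rates and NMI.

    ``counts[i][j]`` is the number of epochs with actual class ``i``
    predicted as class ``j``; ``row_pct`` normalizes each row to 100.
    """

    classes: list
    counts: np.ndarray
    row_pct: np.ndarray
    per_class_rate: np.ndarray
    overall_rate: float
    nmi: float


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi_from_joint(joint: np.ndarray) -> float:
    """NMI of a joint (actual, predicted) probability matrix.

    Entries must be non-negative; a total within 1% of 1 is renormalized.
    Returns 0 when either marginal entropy is 0.
    """
    J = np.asarray(joint, dtype=float)
    if (J < 0).any():
        raise ValueError("joint matrix has negative entries")
    tot = J.sum()
    if tot <= 0:
        raise ValueError("joint matrix sums to zero")
    if abs(tot - 1.0) > 0.01:
        raise ValueError(f"joint matrix sums to {tot:.4f}, more than 1% from 1")
    J = J / tot
    pa = J.sum(axis=1)
    pp = J.sum(axis=0)
    ha, hp = _entropy(pa), _entropy(pp)
    if ha <= 0 or hp <= 0:
        return 0.0
    outer = np.outer(pa, pp)
    nz = J > 0
    mi = float((J[nz] * np.log(J[nz] / outer[nz])).sum())
    return mi / np.sqrt(ha * hp)


def joint_from_rowpct(row_pct: np.ndarray, actual_marginals: np.ndarray) -> np.ndarray:
    """Joint distribution from a row-percentage table and actual marginals.

    ``joint[i, j] = marginal[i] * row_pct[i, j] / 100``.  Bridges printed
    row-normalized confusion tables to :func:`nmi_from_joint`.
    """
    R = np.asarray(row_pct, dtype=float)
    m = np.asarray(actual_marginals, dtype=float).ravel()
    if R.ndim != 2 or R.shape[0] != m.size:
        raise ValueError(f"shape mismatch: row_pct {R.shape} vs {m.size} marginals")
    rows = R.sum(axis=1)
    if np.any(np.abs(rows - 100.0) > 0.2):
        raise ValueError(f"row sums {rows} deviate from 100 by more than 0.2")
    if abs(m.sum() - 1.0) > 1e-9:
        raise ValueError(f"marginals sum to {m.sum()}, expected 1")
    return m[:, None] * R / 100.0


def confusion(true_labels, pred_labels, classes=None) -> ConfusionResult:
    """Confusion matrix, per-class and overall rates, and NMI."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.size == 0:
        raise ValueError("empty label sequences")
    if t.size != p.size:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([t, p])).tolist())
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=int)
    for a, b in zip(t, p):
        counts[index[a], index[b]] += 1
    row_tot = counts.sum(axis=1)
    row_pct = np.divide(counts * 100.0, row_tot[:, None],
                        out=np.zeros((k, k)), where=row_tot[:, None] > 0)
    per_class = np.diag(row_pct)
    overall = 100.0 * np.trace(counts) / counts.sum()
    nmi = nmi_from_joint(counts / counts.sum())
    return ConfusionResult(classes, counts, row_pct, per_class, float(overall), nmi)


def stratified_split(labels, train_frac: float = 0.15, seed: int | None = None):
    """Seeded stratified train/test index split (per-class proportions kept).

    Defaults to a 15/85 train/test split, mirroring the fraction of the
    dataset the surrogate network is trained on.
    """
    labels = np.asarray(labels)
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in sorted(np.unique(labels).tolist()):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_tr = max(1, int(round(train_frac * idx.size)))
        train_idx.append(idx[:n_tr])
        test_idx.append(idx[n_tr:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))
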