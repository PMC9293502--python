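"""Cluster-validity scoring of fuzzy partitions.

Two classical indices for an n x c membership matrix U:

* partition coefficient  Vpc = (1/n) sum_k sum_i u_ik^2, in [1/c, 1]
  (larger = crisper = better);
* partition entropy      Vpe = -(1/n) sum_k sum_i u_ik log2 u_ik,
  in [0, log2 c] (smaller = better), with 0*log2(0) := 0.

A hard partition attains exactly (Vpc, Vpe) = (1, 0).

Also provides Dice overlap after optimal (Hungarian) label matching, the
segmentation-agreement metric used when comparing engines against a ground
truth whose label numbering is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import InvalidInputError, MembershipMatrix


def _as_membership_array(membership) -> np.ndarray:
    u = membership.values if isinstance(membership, MembershipMatrix) else np.asarray(membership, float)
    if u.ndim != 2 or u.size == 0:
        raise InvalidInputError("membership matrix must be non-empty n x c")
    return u


def partition_coefficient(membership) -> float:
    """Bezdek partition coefficient Vpc of a fuzzy partition."""
    u = _as_membership_array(membership)
    return float(np.sum(u * u) / u.shape[0])


def partition_entropy(membership) -> float:
    """Partition entropy Vpe (log base 2) of a fuzzy partition."""
    u = _as_membership_array(membership)
    pos = u > 0
    h = np.zeros_like(u)
    h[pos] = u[pos] * np.log2(u[pos])
    return float(-np.sum(h) / u.shape[0])


@dataclass
class ValidityReport:
    """Vpc/Vpe pair with the partition dimensions they were computed on."""

    v_pc: float
    v_pe: float
    n: int
    c: int

    @classmethod
    def from_membership(cls, membership) -> "ValidityReport":
        u = _as_membership_array(membership)
        return cls(
            v_pc=partition_coefficient(u),
            v_pe=partition_entropy(u),
            n=u.shape[0],
            c=u.shape[1],
        )


# ---------------------------------------------------------------------------
# Segmentation agreement
# ---------------------------------------------------------------------------

def match_labels(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Optimal assignment of predicted to true labels (max total overlap).

    Pixels labeled -1 (outside mask) in either grid are ignored.  Returns
    a dict mapping predicted label -> true label.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InvalidInputError("label grids must share a shape")
    valid = (pred >= 0) & (truth >= 0)
    p, t = pred[valid], truth[valid]
    p_labels = np.unique(p)
    t_labels = np.unique(t)
    conf = np.zeros((p_labels.size, t_labels.size))
    for i, pl in enumerate(p_labels):
        sel = p == pl
        for j, tl in enumerate(t_labels):
            conf[i, j] = np.sum(sel & (t == tl))
    rows, cols = linear_sum_assignment(-conf)
    return {int(p_labels[i]): int(t_labels[j]) for i, j in zip(rows, cols)}


def dice_scores(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Per-class Dice coefficients after optimal label matching.

    Returns a dict keyed by the true class label.
    """
    mapping = match_labels(pred, truth)
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    valid = (pred >= 0) & (truth >= 0)
    remapped = np.full_like(pred, -1)
    for pl, tl in mapping.items():
        remapped[valid & (pred == pl)] = tl
    out = {}
    for tl in np.unique(truth[valid]):
        a = remapped == tl
        b = valid & (truth == tl)
        denom = a.sum() + b.sum()
        out[int(tl)] = float(2.0 * np.sum(a & b) / denom) if denom else 1.0
    return out


def mean_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Unweighted mean of the per-class Dice scores."""
    scores = dice_scores(pred, truth)
    return float(np.mean(list(scores.values())))
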