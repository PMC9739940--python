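"""Training objectives: softmax cross-entropy, discriminative instance loss,
Chamfer distance and the four-stage progressive completion loss, plus the
earth mover's distance used for evaluation.

These are the numpy reference implementations used for evaluation and
testing; the training loop uses autodiff counterparts that share the same
formulas (see :mod:`mixseedling.nn`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

__all__ = [
    "InstanceLossParams",
    "semantic_loss",
    "instance_loss",
    "chamfer_distance",
    "completion_loss",
    "emd",
]


@dataclass(frozen=True)
class InstanceLossParams:
    """Margin of the discriminative pull loss, in normalized units."""

    delta_s: float = 0.1

    def __post_init__(self) -> None:
        if self.delta_s <= 0:
            raise ValueError("delta_s must be positive")


def semantic_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean softmax cross-entropy over labeled points.

    ``scores`` is ``(N, Ns)`` raw logits, ``labels`` integer classes; rows
    labeled with the -1 sentinel are excluded.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    valid = labels >= 0
    if not valid.any():
        raise ValueError("no labeled points to compute the loss on")
    s = scores[valid]
    y = labels[valid]
    if y.max() >= s.shape[1]:
        raise ValueError("label out of range of the score columns")
    m = s.max(axis=1, keepdims=True)
    log_probs = s - m - np.log(np.exp(s - m).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(len(y)), y].mean())


def instance_loss(
    embedding: np.ndarray,
    instance_labels: np.ndarray,
    params: InstanceLossParams = InstanceLossParams(),
) -> tuple[float, float, float]:
    """Discriminative instance loss ``L = Ls + Lreg``.

    ``Ls`` is the hinge-squared pull term drawing each point's embedding
    within ``delta_s`` of its instance center; ``Lreg`` keeps the centers near
    the origin:

    ``Ls = (1/I) sum_i (1/N_i) sum_j max(0, ||c_i - f_j|| - delta_s)^2``,
    ``Lreg = (1/I) sum_i ||c_i||``.

    Points labeled -1 are ignored; empty instances are skipped with a warning.
    Returns ``(total, Ls, Lreg)``.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(instance_labels, dtype=np.int64)
    ids = np.unique(labels[labels >= 0])
    if len(ids) == 0:
        raise ValueError("at least one instance is required")
    ls_terms, reg_terms = [], []
    for i in ids:
        f = embedding[labels == i]
        if len(f) == 0:  # pragma: no cover - unique() precludes this
            warnings.warn(f"instance {i} has no points; skipped", stacklevel=2)
            continue
        c = f.mean(axis=0)
        dist = np.linalg.norm(f - c, axis=1)
        hinge = np.maximum(0.0, dist - params.delta_s)
        ls_terms.append(float((hinge**2).mean()))
        reg_terms.append(float(np.linalg.norm(c)))
    ls = float(np.mean(ls_terms))
    lreg = float(np.mean(reg_terms))
    return ls + lreg, ls, lreg


def chamfer_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Symmetric mean nearest-neighbor distance (plain Euclidean norms):

    ``CD = 1/2 [ mean_x min_y ||x-y|| + mean_y min_x ||x-y|| ]``.
    """
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("chamfer distance of an empty set is undefined")
    d12, _ = cKDTree(s2).query(s1)
    d21, _ = cKDTree(s1).query(s2)
    return 0.5 * (float(d12.mean()) + float(d21.mean()))


def completion_loss(
    predictions: Sequence[np.ndarray], targets: Sequence[np.ndarray]
) -> float:
    """Sum of per-stage Chamfer distances of the progressive decoder.

    ``predictions`` are the four stage outputs Y1..Y4 at resolutions
    (N/8, N/4, N/2, N); ``targets`` the matching farthest-point-sampled
    ground-truth clouds.
    """
    if len(predictions) != len(targets):
        raise ValueError("predictions and targets must pair up stage by stage")
    for t, (y, g) in enumerate(zip(predictions, targets)):
        if len(y) != len(g):
            raise ValueError(f"stage {t}: prediction has {len(y)} points, target {len(g)}")
    return float(sum(chamfer_distance(y, g) for y, g in zip(predictions, targets)))


def emd(s1: np.ndarray, s2: np.ndarray, exact_limit: int = 512,
        sinkhorn_reg: float = 5e-3, sinkhorn_iters: int = 500) -> float:
    """Earth mover's distance: ``min over bijections phi`` of
    ``(1/|S1|) sum ||x - phi(x)||``.

    Solved exactly by the Hungarian algorithm for sets up to ``exact_limit``
    points; larger sets use entropy-regularized transport (Sinkhorn) rounded
    to a feasible assignment, an approximation accurate to roughly the
    regularization scale (documented tolerance ~1-2% on unit-scale clouds).
    Only defined when both sets have the same size.
    """
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    if len(s1) != len(s2):
        raise ValueError("EMD is only defined for equal-size sets")
    n = len(s1)
    cost = np.linalg.norm(s1[:, None, :] - s2[None, :, :], axis=2)
    if n <= exact_limit:
        row, col = linear_sum_assignment(cost)
        return float(cost[row, col].mean())
    # Sinkhorn on the cost, then round to a permutation greedily by the plan
    k = np.exp(-cost / (sinkhorn_reg * max(cost.max(), 1e-12)))
    u = np.ones(n)
    for _ in range(sinkhorn_iters):
        v = 1.0 / (k.T @ u)
        u = 1.0 / (k @ v)
    plan = u[:, None] * k * v[None, :]
    col = np.full(n, -1)
    taken = np.zeros(n, dtype=bool)
    for i in np.argsort(-plan.max(axis=1)):
        j_order = np.argsort(-plan[i])
        j = j_order[~taken[j_order]][0]
        col[i] = j
        taken[j] = True
    return float(cost[np.arange(n), col].mean())


def exhaustive_emd(s1: np.ndarray, s2: np.ndarray) -> float:
    """Brute-force EMD over all permutations; oracle for tiny sets (n <= 7)."""
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    n = len(s1)
    if n > 7:
        raise ValueError("exhaustive EMD is only feasible for n <= 7")
    best = np.inf
    for perm in permutations(range(n)):
        total = np.linalg.norm(s1 - s2[list(perm)], axis=1).mean()
        best = min(best, total)
    return float(best)
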