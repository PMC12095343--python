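"""Education-platform scoring: content push and user satisfaction.

Two weighted-sum scores used by the education information platform built on
top of the resource optimizer:

* **Content push score** — each content item ``i`` carries a vector of
  user-group affinities ``U_i``; a push strategy assigns a weight ``P_j``
  to each user group.  The item's score is ``C_i = sum_j U_ij * P_j`` and
  items are pushed in descending score order.

* **Satisfaction score** — service-quality ratings ``Q`` are combined with
  normalized importance weights ``W`` into ``S = sum_i Q_i * W_i``, a
  convex combination bounded by ``[min Q, max Q]``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["push_score", "rank_contents", "satisfaction_score"]


def push_score(affinity: np.ndarray, strategy: np.ndarray) -> float:
    """Score one content item: ``sum_j U_j * P_j``.

    Both vectors must be nonnegative and of equal length.
    """
    u = np.asarray(affinity, dtype=float)
    p = np.asarray(strategy, dtype=float)
    if u.shape != p.shape or u.ndim != 1:
        raise ValueError(f"affinity and strategy lengths differ: {u.shape} vs {p.shape}")
    if np.any(u < 0) or np.any(p < 0):
        raise ValueError("affinities and strategy weights must be nonnegative")
    return float(np.dot(u, p))


def rank_contents(affinity_matrix: np.ndarray, strategy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score every content row and rank them by descending score.

    Ties are broken by lowest row index.  Returns ``(scores, order)``.
    """
    u = np.atleast_2d(np.asarray(affinity_matrix, dtype=float))
    scores = np.array([push_score(row, strategy) for row in u])
    order = np.argsort(-scores, kind="stable")
    return scores, order


def satisfaction_score(quality: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean ``S = sum Q_i * W_i`` with ``W`` summing to one.

    Raises if the weights are not normalized: normalize explicitly upstream
    so the convex-combination bound ``min Q <= S <= max Q`` is guaranteed.
    """
    q = np.asarray(quality, dtype=float)
    w = np.asarray(weights, dtype=float)
    if q.shape != w.shape or q.ndim != 1:
        raise ValueError("quality and weights must be equal-length vectors")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1 within 1e-9")
    return float(np.dot(q, w))
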