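"""Good-point-set (low-discrepancy) population initialization.

A good point set places ``n`` points in the unit cube ``[0, 1)^d`` far more
evenly than uniform random sampling.  The classical construction picks one
irrational-derived generator per dimension,

    gamma_j = frac(2 * cos(2*pi*j / p)),   j = 1..d,

with ``p`` the smallest prime >= 2d + 3, and emits the fractional-part
lattice ``point_k = ({gamma_1 * k}, ..., {gamma_d * k})`` for ``k = 1..n``.
The construction is fully deterministic: the same ``(n, d)`` always yields
the same matrix, which is what makes it attractive as a reproducible
population initializer for swarm optimizers.

Uniformity is quantified here by a Monte-Carlo estimate of the star
discrepancy (exact computation is NP-hard in the dimension).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UnitPointSet",
    "generate_good_point_set",
    "map_to_bounds",
    "estimate_discrepancy",
]


@dataclass(frozen=True)
class UnitPointSet:
    """An ``n x d`` deterministic low-discrepancy point set in ``[0, 1)^d``.

    Attributes
    ----------
    points : ndarray, shape (n, d)
        Entries in ``[0, 1)``; rows pairwise distinct for ``n > 1``.
    generators : ndarray, shape (d,)
        The per-dimension generator values ``gamma_j``.
    """

    points: np.ndarray
    generators: np.ndarray

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


def _smallest_prime_at_least(m: int) -> int:
    def is_prime(k: int) -> bool:
        if k < 2:
            return False
        f = 2
        while f * f <= k:
            if k % f == 0:
                return False
            f += 1
        return True

    p = m
    while not is_prime(p):
        p += 1
    return p


def _good_point_generators(d: int) -> np.ndarray:
    """Generators ``gamma_j = frac(2 cos(2 pi j / p))``, p smallest prime >= 2d+3."""
    p = _smallest_prime_at_least(2 * d + 3)
    j = np.arange(1, d + 1, dtype=float)
    gamma = 2.0 * np.cos(2.0 * np.pi * j / p)
    return gamma - np.floor(gamma)


def generate_good_point_set(n: int, d: int) -> UnitPointSet:
    """Construct the classical good point set with ``n`` points in dimension ``d``.

    Parameters
    ----------
    n, d : int
        Point count and dimension, both >= 1.

    Returns
    -------
    UnitPointSet
        Deterministic: repeated calls with the same arguments return
        bit-identical matrices.
    """
    if n < 1 or d < 1:
        raise ValueError(f"n and d must be positive, got n={n}, d={d}")
    gamma = _good_point_generators(d)
    k = np.arange(1, n + 1, dtype=float)[:, None]
    pts = k * gamma[None, :]
    pts -= np.floor(pts)
    return UnitPointSet(points=pts, generators=gamma)


def map_to_bounds(pts: UnitPointSet | np.ndarray, lb, ub) -> np.ndarray:
    """Affinely map unit-cube points into the box ``[lb, ub)``.

    ``lb`` and ``ub`` are per-dimension bound vectors with ``ub > lb``
    elementwise.  Returns ``lb + points * (ub - lb)``.
    """
    points = pts.points if isinstance(pts, UnitPointSet) else np.asarray(pts, float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if np.any(ub <= lb):
        raise ValueError("every upper bound must strictly exceed its lower bound")
    return lb + points * (ub - lb)


def estimate_discrepancy(points: np.ndarray, n_probe: int = 4096, seed: int = 0) -> float:
    """Monte-Carlo estimate of the star discrepancy of a unit-cube point set.

    Draws ``n_probe`` random anchored boxes ``[0, a)`` and returns the largest
    absolute difference between the empirical fraction of points inside the
    box and the box volume.  A lower value means a more uniform point set.
    Deterministic for a fixed ``seed``; a lower bound on the true star
    discrepancy.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if np.any(points < 0.0) or np.any(points >= 1.0):
        raise ValueError("all points must lie in the half-open unit cube [0, 1)")
    if n_probe < 1:
        raise ValueError("n_probe must be >= 1")
    n, d = points.shape
    rng = np.random.default_rng(seed)
    worst = 0.0
    # Probe in chunks to bound memory at (chunk x n) comparisons.
    chunk = max(1, min(n_probe, 512))
    remaining = n_probe
    while remaining > 0:
        m = min(chunk, remaining)
        anchors = rng.random((m, d))
        inside = np.all(points[None, :, :] < anchors[:, None, :], axis=2)
        frac = inside.mean(axis=1)
        vol = np.prod(anchors, axis=1)
        worst = max(worst, float(np.max(np.abs(frac - vol))))
        remaining -= m
    return worst
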