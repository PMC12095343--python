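"""Standard closed-form benchmark objectives (sphere, Rastrigin, Rosenbrock)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["Objective", "make_test_objective", "TEST_OBJECTIVES"]


@dataclass
class Objective:
    """A scalar objective over a fixed-dimension search space.

    ``evaluator`` maps a length-``d`` position to a finite scalar.  ``sense``
    is ``"minimize"`` or ``"maximize"``; the optimizers minimize internally
    and negate maximization objectives at the boundary.  ``known_optimum``
    holds the optimal value for benchmark functions (always on the original,
    un-negated scale).
    """

    evaluator: Callable[[np.ndarray], float]
    sense: str = "minimize"
    known_optimum: Optional[float] = None
    name: str = field(default="objective")

    def __post_init__(self) -> None:
        if self.sense not in ("minimize", "maximize"):
            raise ValueError(f"sense must be 'minimize' or 'maximize', got {self.sense!r}")

    def __call__(self, x: np.ndarray) -> float:
        return float(self.evaluator(np.asarray(x, dtype=float)))


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _rastrigin(x: np.ndarray) -> float:
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


TEST_OBJECTIVES = {
    "sphere": _sphere,
    "rastrigin": _rastrigin,
    "rosenbrock": _rosenbrock,
}

#: canonical search box half-width per benchmark
DEFAULT_BOUNDS = {"sphere": 100.0, "rastrigin": 5.12, "rosenbrock": 5.0}


def make_test_objective(name: str, d: int) -> Objective:
    """Return a standard minimization benchmark with known optimum 0.

    ``sphere`` and ``rastrigin`` are minimized at the origin, ``rosenbrock``
    at the all-ones vector.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    try:
        fn = TEST_OBJECTIVES[name]
    except KeyError:
        raise ValueError(
            f"unknown objective {name!r}; choose from {sorted(TEST_OBJECTIVES)}"
        ) from None
    return Objective(evaluator=fn, sense="minimize", known_optimum=0.0, name=name)
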