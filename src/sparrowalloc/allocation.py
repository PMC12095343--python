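"""Constrained public-health education resource allocation.

A resource category (teaching materials R1, staff R2, facilities R3, IT
support R4) of fixed total size is split among ``n`` targets (regions,
institutions or projects).  A candidate allocation is a share vector ``x``
on the probability simplex, additionally subject to a concentration cap on
its second moment:

    maximize   f(x) = sum_a  w_a * g_a(x_a)
    subject to sum_a x_a = 1,   x_a >= 0,   sum_a x_a**2 <= delta_sq,

where ``w_a`` are target weights summing to one, ``g_a`` is the target's
effect function (how allocated share translates into educational effect;
linear ``E_a * x``, saturating ``E_a * (1 - exp(-kappa x))`` or power
``E_a * x**gamma``), and ``delta_sq`` in ``[1/n, 1]`` bounds how
concentrated the allocation may be — the uniform split has second moment
exactly ``1/n``, a one-hot allocation exactly ``1``.

The optimizers of :mod:`sparrowalloc.ssa` / :mod:`sparrowalloc.issa` treat
each flock member as a candidate allocation; infeasible positions are
repaired (box clamp, Euclidean simplex projection, affine shrink toward the
uniform vector onto the second-moment ball) before every evaluation.  An
exact KKT oracle for linear effects provides independent verification.

Balance of an allocation is reported as Jain's fairness index
``(sum x)**2 / (n * sum x**2)``, which on the simplex equals
``1 / (n * sum x**2)`` and is therefore bounded below by ``1/(n*delta_sq)``
whenever the concentration cap holds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InfeasibleProblemError
from .objectives import Objective
from .ssa import OptimizationResult, OptimizerConfig, SearchSpace, run_ssa

__all__ = [
    "AllocationProblem",
    "AllocationSolution",
    "allocation_objective",
    "project_to_simplex",
    "enforce_variance_cap",
    "repair",
    "jain_balance",
    "solve_allocation",
    "kkt_oracle_linear",
    "load_problem",
    "save_problem",
    "save_solution",
]

_SIMPLEX_TOL = 1e-9
_NONNEG_TOL = 1e-12

CATEGORIES = ("R1", "R2", "R3", "R4")
CATEGORY_NAMES = {
    "R1": "teaching materials",
    "R2": "teaching staff",
    "R3": "teaching facilities",
    "R4": "information technology",
}
#: materials and IT can be shared over the network; staff and facilities are
#: bound to a location
DEFAULT_SHAREABLE = {"R1": True, "R2": False, "R3": False, "R4": True}

_G_FAMILIES = ("linear", "saturating", "power")


@dataclass
class AllocationProblem:
    """One resource category's allocation problem over ``n`` targets."""

    efficiency: np.ndarray
    delta_sq: float
    weights: Optional[np.ndarray] = None
    g_family: Optional[Sequence[str]] = None
    g_param: Optional[Sequence[float]] = None
    lb: Optional[np.ndarray] = None
    ub: Optional[np.ndarray] = None
    category: str = "R1"
    shareable: Optional[bool] = None
    target_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        n = self.efficiency.size
        if n < 1:
            raise ConfigurationError("at least one target is required")
        if np.any(self.efficiency <= 0):
            raise ConfigurationError("efficiencies must be positive")
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != n or np.any(self.weights < 0):
            raise ConfigurationError("weights must be a nonnegative length-n vector")
        if abs(self.weights.sum() - 1.0) > _SIMPLEX_TOL:
            raise ConfigurationError("weights must sum to 1 within 1e-9")
        if self.g_family is None:
            self.g_family = ["linear"] * n
        self.g_family = list(self.g_family)
        for fam in self.g_family:
            if fam not in _G_FAMILIES:
                raise ConfigurationError(f"unknown effect family {fam!r}")
        if self.g_param is None:
            self.g_param = [float("nan")] * n
        self.g_param = [float(p) for p in self.g_param]
        self.lb = np.zeros(n) if self.lb is None else np.asarray(self.lb, dtype=float)
        self.ub = np.ones(n) if self.ub is None else np.asarray(self.ub, dtype=float)
        if np.any(self.lb < 0) or np.any(self.ub > 1) or np.any(self.lb > self.ub):
            raise ConfigurationError("bounds must satisfy 0 <= lb <= ub <= 1")
        if self.lb.sum() > 1.0 + _SIMPLEX_TOL or self.ub.sum() < 1.0 - _SIMPLEX_TOL:
            raise ConfigurationError("box bounds leave the simplex unreachable")
        if self.delta_sq < 1.0 / n - _SIMPLEX_TOL:
            raise InfeasibleProblemError(
                f"delta_sq={self.delta_sq} < 1/n={1.0 / n}: the uniform split has "
                "second moment 1/n, so the feasible set is empty"
            )
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"category must be one of {CATEGORIES}")
        if self.shareable is None:
            self.shareable = DEFAULT_SHAREABLE[self.category]
        if self.target_ids is None:
            self.target_ids = [f"A{a + 1}" for a in range(n)]
        self.target_ids = list(self.target_ids)

    @property
    def n(self) -> int:
        return self.efficiency.size

    def effects(self, x: np.ndarray) -> np.ndarray:
        """Per-target effect values ``g_a(x_a)``."""
        x = np.asarray(x, dtype=float)
        out = np.empty(self.n)
        for a in range(self.n):
            fam, e, p = self.g_family[a], self.efficiency[a], self.g_param[a]
            if fam == "linear":
                out[a] = e * x[a]
            elif fam == "saturating":
                out[a] = e * (1.0 - math.exp(-p * x[a]))
            else:  # power
                out[a] = e * x[a] ** p
        return out


@dataclass
class AllocationSolution:
    """A feasible allocation with its objective value and balance score."""

    x: np.ndarray
    objective_value: float
    balance: float
    feasible: dict = field(default_factory=dict)
    repaired: bool = False
    result: Optional[OptimizationResult] = None

    def to_dict(self) -> dict:
        return {
            "x": [float(v) for v in self.x],
            "objective_value": float(self.objective_value),
            "balance": float(self.balance),
            "feasible": {k: bool(v) for k, v in self.feasible.items()},
            "repaired": bool(self.repaired),
        }


def allocation_objective(x: np.ndarray, prob: AllocationProblem) -> float:
    """Weighted-effect objective ``sum_a w_a * g_a(x_a)``.

    With all-linear effects and uniform weights this is ``(1/n) * sum x_a *
    E_a``, i.e. the plain efficiency-weighted objective up to the constant
    ``1/n``.
    """
    x = np.asarray(x, dtype=float)
    if x.size != prob.n:
        raise ValueError(f"x has length {x.size}, expected {prob.n}")
    return float(np.dot(prob.weights, prob.effects(x)))


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto ``{x >= 0, sum x = 1}`` (sorted-threshold)."""
    v = np.asarray(v, dtype=float)
    n = v.size
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho_candidates = u + (1.0 - css) / np.arange(1, n + 1) > 0
    rho = int(np.nonzero(rho_candidates)[0][-1])
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


def enforce_variance_cap(x: np.ndarray, delta_sq: float) -> np.ndarray:
    """Shrink a simplex point toward uniform until ``sum x**2 <= delta_sq``.

    Returns ``u + t*(x - u)`` with ``u`` the uniform vector and
    ``t = sqrt((delta_sq - 1/n) / (sum x**2 - 1/n))``, which stays on the
    simplex, preserves the ranking of components, and meets the cap with
    equality when it was violated.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if delta_sq < 1.0 / n - _SIMPLEX_TOL:
        raise InfeasibleProblemError(f"delta_sq={delta_sq} < 1/n={1.0 / n}")
    s = float(np.dot(x, x))
    if s <= delta_sq:
        return x.copy()
    u = np.full(n, 1.0 / n)
    t = math.sqrt(max(delta_sq - 1.0 / n, 0.0) / (s - 1.0 / n))
    return u + t * (x - u)


def repair(v: np.ndarray, prob: AllocationProblem) -> tuple[np.ndarray, bool]:
    """Map an arbitrary vector to a feasible allocation.

    Composition: clamp to the box, project onto the simplex, shrink onto the
    second-moment ball.  Idempotent.  Returns ``(x, changed)`` where
    ``changed`` reports whether the input moved by more than 1e-9 in any
    coordinate.
    """
    v = np.asarray(v, dtype=float)
    x = np.clip(v, prob.lb, prob.ub)
    x = project_to_simplex(x)
    x = enforce_variance_cap(x, prob.delta_sq)
    return x, bool(np.max(np.abs(x - v)) > _SIMPLEX_TOL)


def feasibility_report(x: np.ndarray, prob: AllocationProblem) -> dict:
    x = np.asarray(x, dtype=float)
    return {
        "simplex": bool(abs(x.sum() - 1.0) <= _SIMPLEX_TOL),
        "nonneg": bool(np.all(x >= -_NONNEG_TOL)),
        "variance": bool(np.dot(x, x) <= prob.delta_sq + _SIMPLEX_TOL),
        "box": bool(np.all(x >= prob.lb - _SIMPLEX_TOL) and np.all(x <= prob.ub + _SIMPLEX_TOL)),
    }


def jain_balance(x: np.ndarray) -> float:
    """Jain fairness index ``(sum x)**2 / (n * sum x**2)`` in ``(0, 1]``.

    Equals 1 for the uniform allocation and ``1/n`` for one-hot.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or x.sum() <= 0:
        raise ValueError("jain_balance requires a nonnegative vector with positive sum")
    return float(x.sum() ** 2 / (x.size * np.dot(x, x)))


def kkt_oracle_linear(
    efficiency: np.ndarray, delta_sq: float
) -> tuple[np.ndarray, float]:
    """Exact maximizer of ``sum x_a E_a`` on the capped simplex.

    The KKT conditions give ``x_a proportional to max(0, E_a - lam)`` for a
    threshold ``lam``; the second moment of that family increases
    monotonically with ``lam``, so the active-cap solution is found by
    bisection.  When the cap is slack at a simplex vertex (``delta_sq >= 1``)
    the solution is one-hot on the best target.

    Returns ``(x_star, f_star)``.
    """
    e = np.asarray(efficiency, dtype=float)
    n = e.size
    if delta_sq < 1.0 / n - _SIMPLEX_TOL:
        raise InfeasibleProblemError(f"delta_sq={delta_sq} < 1/n={1.0 / n}")
    if delta_sq <= 1.0 / n + 1e-15:
        x = np.full(n, 1.0 / n)
        return x, float(np.dot(x, e))
    if delta_sq >= 1.0:
        x = np.zeros(n)
        x[int(np.argmax(e))] = 1.0
        return x, float(np.max(e))

    e_max = float(np.max(e))
    argmax_set = np.isclose(e, e_max, rtol=0, atol=0)
    m = int(argmax_set.sum())
    if delta_sq >= 1.0 / m:
        # cap slack at the uniform-over-argmax point, which attains max(E)
        x = np.where(argmax_set, 1.0 / m, 0.0)
        return x, e_max

    def x_of(lam: float) -> np.ndarray:
        w = np.maximum(e - lam, 0.0)
        return w / w.sum()

    lo = float(np.min(e)) - 1e6 * (e_max - float(np.min(e)) + 1.0)
    hi = e_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.dot(x_of(mid), x_of(mid))) < delta_sq:
            lo = mid
        else:
            hi = mid
    x = x_of(lo)
    return x, float(np.dot(x, e))


def solve_allocation(
    prob: AllocationProblem,
    cfg: OptimizerConfig,
    algorithm: str = "issa",
) -> AllocationSolution:
    """Optimize an allocation problem with the sparrow search optimizers.

    Each flock member is a candidate allocation; its position is repaired to
    feasibility before every fitness evaluation, so the returned solution
    always satisfies the simplex, nonnegativity and concentration
    constraints.
    """
    from .issa import run_issa  # local import avoids a cycle

    if algorithm not in ("ssa", "issa"):
        raise ConfigurationError(f"algorithm must be 'ssa' or 'issa', got {algorithm!r}")
    space = SearchSpace(d=prob.n, lb=prob.lb, ub=prob.ub)

    def fitness(v: np.ndarray) -> float:
        x, _ = repair(v, prob)
        return allocation_objective(x, prob)

    obj = Objective(evaluator=fitness, sense="maximize", name=f"allocation-{prob.category}")
    if algorithm == "issa":
        result = run_issa(obj, space, cfg)
    else:
        result = run_ssa(obj, space, cfg)
    x, changed = repair(result.best_position, prob)
    return AllocationSolution(
        x=x,
        objective_value=allocation_objective(x, prob),
        balance=jain_balance(x),
        feasible=feasibility_report(x, prob),
        repaired=changed,
        result=result,
    )


# ---------------------------------------------------------------------------
# CSV / JSON serialization
# ---------------------------------------------------------------------------

def save_problem(prob: AllocationProblem, csv_path, meta_path) -> None:
    """Write targets as CSV and problem-level metadata as JSON."""
    df = pd.DataFrame(
        {
            "target_id": prob.target_ids,
            "efficiency": prob.efficiency,
            "weight": prob.weights,
            "g_family": prob.g_family,
            "g_param": prob.g_param,
            "lb": prob.lb,
            "ub": prob.ub,
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "n": prob.n,
        "delta_sq": float(prob.delta_sq),
        "category": prob.category,
        "shareable": bool(prob.shareable),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def load_problem(csv_path, meta_path) -> AllocationProblem:
    """Read an allocation problem from the CSV + JSON pair of :func:`save_problem`."""
    df = pd.read_csv(csv_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    required = {"target_id", "efficiency", "weight", "g_family", "g_param", "lb", "ub"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"problem CSV missing columns: {sorted(missing)}")
    if len(df) != int(meta["n"]):
        raise ConfigurationError(
            f"CSV has {len(df)} rows but metadata declares n={meta['n']}"
        )
    return AllocationProblem(
        efficiency=df["efficiency"].to_numpy(),
        delta_sq=float(meta["delta_sq"]),
        weights=df["weight"].to_numpy(),
        g_family=list(df["g_family"]),
        g_param=list(df["g_param"]),
        lb=df["lb"].to_numpy(),
        ub=df["ub"].to_numpy(),
        category=meta.get("category", "R1"),
        shareable=meta.get("shareable"),
        target_ids=list(df["target_id"]),
    )


def save_solution(sol: AllocationSolution, prob: AllocationProblem, csv_path, json_path) -> None:
    """Write the share vector as CSV and the summary as JSON."""
    pd.DataFrame({"target_id": prob.target_ids, "share": sol.x}).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(sol.to_dict(), fh, indent=2)
        fh.write("\n")
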