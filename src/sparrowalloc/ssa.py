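"""Baseline sparrow search algorithm (SSA).

SSA is a population metaheuristic modeled on the foraging of a sparrow
flock.  Each candidate solution ("sparrow") holds a position in the search
box; every iteration the flock is partitioned by fitness into three
behavioral roles:

* **discoverers** (producers) — the best-ranked fraction, which either
  contract multiplicatively toward the origin of their coordinates (safe
  foraging) or take a normal-perturbation step (alarm raised);
* **followers** (scroungers) — the remainder, whose worst half migrates away
  from the worst position and whose best half is attracted to the current
  best position;
* **scouts** — a random subset that moves a random fraction of the way
  toward the global best, guarding against stagnation.

Positions are clamped to the box after every update.  The optimizer
minimizes internally; maximization objectives are negated at the boundary.
All randomness flows from a single seeded generator, so a fixed seed yields
a bit-identical trajectory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .exceptions import ConfigurationError, EvaluationError
from .objectives import Objective, make_test_objective  # noqa: F401  (re-export)

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "SparrowPopulation",
    "OptimizationResult",
    "random_init",
    "evaluate",
    "partition_roles",
    "discoverer_update",
    "follower_update",
    "scout_update",
    "run_ssa",
]

DISCOVERER, FOLLOWER, SCOUT = "discoverer", "follower", "scout"


@dataclass(frozen=True)
class SearchSpace:
    """A box-bounded continuous search space of dimension ``d``."""

    d: int
    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.broadcast_to(np.asarray(self.lb, float), (self.d,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, float), (self.d,)).copy()
        if self.d < 1:
            raise ConfigurationError("dimension must be >= 1")
        if np.any(ub <= lb):
            raise ConfigurationError("ub must strictly exceed lb in every dimension")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @classmethod
    def symmetric(cls, d: int, half_width: float) -> "SearchSpace":
        return cls(d=d, lb=-half_width * np.ones(d), ub=half_width * np.ones(d))

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lb, self.ub)


@dataclass
class OptimizerConfig:
    """All optimizer tunables.

    Parameters
    ----------
    pop_size : population size N (>= 4).
    max_iter : number of iterations T.
    discoverer_fraction : fraction PD of the flock ranked as discoverers.
    scout_fraction : fraction SD drawn as scouts from the non-discoverers.
    alarm_threshold : ST in (0,1); a uniform draw below ST selects the
        discoverers' contraction branch, above it the alarm (normal step).
    alpha : learning rate of the elite-guided pull toward the best position.
    beta : scale of the elite update's uniform perturbation, as a fraction
        of the per-dimension search range.
    elite_fraction : fraction q of the flock forming the elite ("best point")
        set in the improved algorithm.
    seed : seed for the run's random generator.
    """

    pop_size: int = 30
    max_iter: int = 100
    discoverer_fraction: float = 0.2
    scout_fraction: float = 0.1
    alarm_threshold: float = 0.8
    alpha: float = 0.5
    beta: float = 0.3
    elite_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ConfigurationError("pop_size must be >= 4")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        for name in ("discoverer_fraction", "scout_fraction", "alarm_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.discoverer_fraction + self.scout_fraction >= 1.0:
            raise ConfigurationError("discoverer_fraction + scout_fraction must be < 1")
        if not 0.0 < self.elite_fraction <= 1.0:
            raise ConfigurationError("elite_fraction must lie in (0, 1]")
        if self.alpha <= 0 or self.beta < 0:
            raise ConfigurationError("alpha must be positive and beta nonnegative")

    @property
    def n_discoverers(self) -> int:
        return math.ceil(self.discoverer_fraction * self.pop_size)

    @property
    def n_scouts(self) -> int:
        return math.ceil(self.scout_fraction * self.pop_size)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "OptimizerConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(mapping) - known - {"algorithm"}
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(**{k: v for k, v in mapping.items() if k in known})

    @classmethod
    def from_file(cls, path) -> "OptimizerConfig":
        """Load from YAML or JSON (YAML parses both)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)


@dataclass
class SparrowPopulation:
    """The flock state at one iteration.

    ``fitness`` is stored on the internal minimization scale.  ``best_*``
    track the best position *ever evaluated* during the run, not merely the
    best member of the current generation.
    """

    positions: np.ndarray
    fitness: np.ndarray = field(default=None)  # type: ignore[assignment]
    roles: np.ndarray = field(default=None)  # type: ignore[assignment]
    best_position: Optional[np.ndarray] = None
    best_fitness: float = math.inf
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.positions.shape[0]
        if self.fitness is None:
            self.fitness = np.full(n, np.nan)
        if self.roles is None:
            self.roles = np.full(n, FOLLOWER, dtype=object)

    @property
    def size(self) -> int:
        return self.positions.shape[0]


@dataclass
class OptimizationResult:
    """Outcome of a run: best point, per-iteration best-so-far, bookkeeping.

    ``history`` has one entry per iteration and is monotone (non-increasing
    for minimization, non-decreasing for maximization).  Values are reported
    on the objective's original scale.
    """

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    n_evaluations: int
    seed: int
    algorithm: str = "ssa"

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_position": [float(v) for v in self.best_position],
            "best_fitness": float(self.best_fitness),
            "history": [float(v) for v in self.history],
            "n_evaluations": int(self.n_evaluations),
            "seed": int(self.seed),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _internal_evaluator(obj: Objective):
    """Wrap an objective into a minimizing callable that rejects non-finite values."""
    sign = 1.0 if obj.sense == "minimize" else -1.0

    def f(x: np.ndarray) -> float:
        v = obj(x)
        if not np.isfinite(v):
            raise EvaluationError(f"objective returned non-finite value {v!r} at {x!r}")
        return sign * v

    return f


def random_init(space: SearchSpace, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Uniform random initial positions: ``rand * (ub - lb) + lb`` per entry."""
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return space.lb + rng.random((n, space.d)) * (space.ub - space.lb)


def evaluate(pop: SparrowPopulation, obj: Objective) -> SparrowPopulation:
    """Fill the fitness vector and refresh the best-so-far record in place."""
    f = _internal_evaluator(obj)
    pop.fitness = np.array([f(x) for x in pop.positions])
    pop.n_evaluations += pop.size
    i = int(np.argmin(pop.fitness))
    if pop.fitness[i] < pop.best_fitness:
        pop.best_fitness = float(pop.fitness[i])
        pop.best_position = pop.positions[i].copy()
    return pop


def _fitness_order(fitness: np.ndarray) -> np.ndarray:
    """Indices sorted best-first; ties broken by lowest index (stable sort)."""
    return np.argsort(fitness, kind="stable")


def partition_roles(
    pop: SparrowPopulation, cfg: OptimizerConfig, rng: np.random.Generator
) -> SparrowPopulation:
    """Assign discoverer/follower/scout roles by fitness rank.

    The best ``ceil(PD*N)`` individuals become discoverers; ``ceil(SD*N)``
    individuals drawn uniformly (seeded) from the rest become scouts.
    """
    n = pop.size
    nd, ns = cfg.n_discoverers, cfg.n_scouts
    if nd + ns >= n:
        raise ConfigurationError(
            f"role fractions leave no followers: {nd} discoverers + {ns} scouts >= N={n}"
        )
    order = _fitness_order(pop.fitness)
    roles = np.full(n, FOLLOWER, dtype=object)
    roles[order[:nd]] = DISCOVERER
    rest = order[nd:]
    scouts = rng.choice(rest, size=ns, replace=False)
    roles[scouts] = SCOUT
    pop.roles = roles
    return pop


def discoverer_update(
    pop: SparrowPopulation,
    cfg: OptimizerConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> SparrowPopulation:
    """Producer move: alarm-gated contraction or normal-perturbation step.

    For discoverer of rank ``r`` (1-based among discoverers): with
    probability ST the position contracts as ``X * exp(-r / (u * T))`` with
    ``u ~ U(0, 1]``; otherwise a shared standard-normal scalar Q is added to
    every coordinate.
    """
    order = _fitness_order(pop.fitness)
    disc = [i for i in order if pop.roles[i] == DISCOVERER]
    for rank, i in enumerate(disc, start=1):
        if rng.random() < cfg.alarm_threshold:
            u = 1.0 - rng.random()  # U on (0, 1]
            pop.positions[i] = pop.positions[i] * math.exp(-rank / (u * cfg.max_iter))
        else:
            pop.positions[i] = pop.positions[i] + rng.standard_normal()
    pop.positions[disc] = space.clamp(pop.positions[disc])
    return pop


def follower_update(
    pop: SparrowPopulation,
    cfg: OptimizerConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> SparrowPopulation:
    """Scrounger move.

    Followers in the worst half of the flock (by overall fitness rank r,
    1-based) migrate as ``Q * exp((X_worst - X) / r**2)``; the rest are
    attracted to the best position, landing at
    ``X_best + |X - X_best| * (+-1) / d`` with a fresh random sign per
    coordinate.
    """
    n = pop.size
    order = _fitness_order(pop.fitness)
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(1, n + 1)
    x_worst = pop.positions[order[-1]].copy()
    x_best = pop.best_position
    d = space.d
    for i in range(n):
        if pop.roles[i] != FOLLOWER:
            continue
        r = rank_of[i]
        if r > n / 2:
            q = rng.standard_normal()
            pop.positions[i] = q * np.exp((x_worst - pop.positions[i]) / r**2)
        else:
            signs = rng.choice([-1.0, 1.0], size=d)
            pop.positions[i] = x_best + np.abs(pop.positions[i] - x_best) * signs / d
        pop.positions[i] = space.clamp(pop.positions[i])
    return pop


def scout_update(
    pop: SparrowPopulation,
    cfg: OptimizerConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> SparrowPopulation:
    """Anti-stagnation move: each scout steps ``X + rand * (X_best - X)``.

    One uniform draw per scout, shared across dimensions, so the new
    position lies on the segment between the scout and the best position.
    """
    x_best = pop.best_position
    for i in range(pop.size):
        if pop.roles[i] != SCOUT:
            continue
        r = rng.random()
        pop.positions[i] = pop.positions[i] + r * (x_best - pop.positions[i])
        pop.positions[i] = space.clamp(pop.positions[i])
    return pop


def run_ssa(
    obj: Objective,
    space: SearchSpace,
    cfg: OptimizerConfig,
    init_positions: Optional[np.ndarray] = None,
) -> OptimizationResult:
    """Run the baseline sparrow search loop.

    Random initialization, then ``max_iter`` iterations of role partition and
    the three role updates, evaluating the flock once per iteration.  Total
    evaluations: ``N * (T + 1)``.
    """
    rng = np.random.default_rng(cfg.seed)
    if init_positions is None:
        positions = random_init(space, cfg.pop_size, rng)
    else:
        positions = space.clamp(np.array(init_positions, dtype=float, copy=True))
    pop = SparrowPopulation(positions=positions)
    evaluate(pop, obj)
    history = np.empty(cfg.max_iter)
    for t in range(cfg.max_iter):
        partition_roles(pop, cfg, rng)
        discoverer_update(pop, cfg, space, rng)
        follower_update(pop, cfg, space, rng)
        scout_update(pop, cfg, space, rng)
        evaluate(pop, obj)
        history[t] = pop.best_fitness
    sign = 1.0 if obj.sense == "minimize" else -1.0
    return OptimizationResult(
        best_position=pop.best_position.copy(),
        best_fitness=sign * pop.best_fitness,
        history=sign * history,
        n_evaluations=pop.n_evaluations,
        seed=cfg.seed,
        algorithm="ssa",
    )
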