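"""Improved sparrow search algorithm (ISSA).

Two changes over the baseline flock of :mod:`sparrowalloc.ssa`:

1. **Good-point-set initialization.**  Iteration-0 positions come from the
   deterministic low-discrepancy construction of
   :mod:`sparrowalloc.good_points` mapped into the search box, instead of
   uniform random sampling.  The initial flock is therefore identical for
   every seed; only the stochastic updates differ between runs.

2. **Elite-guided refresh.**  After the role updates of each iteration, the
   elite ("best point") set — the top ``q``-fraction of the flock — is
   re-selected, and every individual proposes a move

       X' = X + alpha * (P_best - X) + beta * (rand - 0.5) * (UB - LB),

   a pull toward the current best position ``P_best`` plus a zero-mean
   uniform perturbation scaled by the per-dimension range (fresh draw per
   dimension), clamped to the box.  The proposal is kept only when it
   improves the individual's fitness: positions with higher fitness are
   preserved, so the refresh adds guided exploration without eroding
   convergence.

Because the elite refresh evaluates one candidate per individual, a run
uses ``2N`` evaluations per iteration (plus ``N`` at initialization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError
from .good_points import generate_good_point_set, map_to_bounds
from .objectives import Objective
from .ssa import (
    OptimizationResult,
    OptimizerConfig,
    SearchSpace,
    SparrowPopulation,
    _fitness_order,
    _internal_evaluator,
    discoverer_update,
    evaluate,
    follower_update,
    partition_roles,
    random_init,
    scout_update,
)

__all__ = [
    "EliteSet",
    "select_elite",
    "elite_guided_update",
    "update_elite_set",
    "initial_population",
    "run_issa",
]


def initial_population(
    space: SearchSpace,
    cfg: OptimizerConfig,
    init: str = "gps",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Iteration-0 positions for a run.

    ``"gps"`` maps the deterministic good point set into the box — identical
    for every seed — while ``"random"`` draws uniform positions from ``rng``.
    """
    if init == "gps":
        unit = generate_good_point_set(cfg.pop_size, space.d)
        return map_to_bounds(unit, space.lb, space.ub)
    if init == "random":
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        return random_init(space, cfg.pop_size, rng)
    raise ConfigurationError(f"init must be 'gps' or 'random', got {init!r}")


@dataclass
class EliteSet:
    """The top ``ceil(q*N)`` individuals by fitness and their centroid."""

    members: np.ndarray  # (m, d) positions
    member_indices: np.ndarray  # indices into the population
    centroid: np.ndarray  # (d,)

    @property
    def size(self) -> int:
        return self.members.shape[0]


def select_elite(pop: SparrowPopulation, q: float) -> EliteSet:
    """Select the best ``ceil(q*N)`` individuals (ties: lowest index)."""
    m = int(np.ceil(q * pop.size))
    if m < 1:
        raise ConfigurationError(f"elite fraction {q} selects no members for N={pop.size}")
    order = _fitness_order(pop.fitness)
    idx = order[:m]
    members = pop.positions[idx].copy()
    return EliteSet(members=members, member_indices=idx, centroid=members.mean(axis=0))


def update_elite_set(elite: EliteSet, pop: SparrowPopulation, q: float) -> EliteSet:
    """Refresh the elite set from the freshly evaluated population.

    Selection (not interpolation) governs membership; the relaxation toward
    the elite region is realized by :func:`elite_guided_update` pulling
    individuals toward the best member.
    """
    return select_elite(pop, q)


def elite_guided_update(
    x: np.ndarray,
    p_best: np.ndarray,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
    space: SearchSpace,
) -> np.ndarray:
    """Propose ``x + alpha*(p_best - x) + beta*(rand - 0.5)*(ub - lb)``, clamped.

    ``rand`` is drawn fresh per dimension, so the perturbation is zero-mean
    in every coordinate.
    """
    noise = (rng.random(space.d) - 0.5) * (space.ub - space.lb)
    candidate = x + cfg.alpha * (p_best - x) + cfg.beta * noise
    return space.clamp(candidate)


def _elite_refresh_stage(
    pop: SparrowPopulation,
    obj_internal,
    cfg: OptimizerConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> EliteSet:
    """Re-select the elite, then greedily apply the guided move to everyone."""
    elite = select_elite(pop, cfg.elite_fraction)
    p_best = pop.best_position
    for i in range(pop.size):
        candidate = elite_guided_update(pop.positions[i], p_best, cfg, rng, space)
        f_new = obj_internal(candidate)
        pop.n_evaluations += 1
        if f_new < pop.fitness[i]:
            pop.positions[i] = candidate
            pop.fitness[i] = f_new
            if f_new < pop.best_fitness:
                pop.best_fitness = float(f_new)
                pop.best_position = candidate.copy()
    return elite


def run_issa(
    obj: Objective,
    space: SearchSpace,
    cfg: OptimizerConfig,
    init: str = "gps",
) -> OptimizationResult:
    """Run the improved sparrow search loop.

    ``init`` selects the initializer: ``"gps"`` (good point set, the
    default) or ``"random"`` (uniform, for ablation studies).  History and
    monotonicity contracts match :func:`sparrowalloc.ssa.run_ssa`.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = initial_population(space, cfg, init=init, rng=rng)
    pop = SparrowPopulation(positions=positions)
    evaluate(pop, obj)
    f_internal = _internal_evaluator(obj)
    history = np.empty(cfg.max_iter)
    for t in range(cfg.max_iter):
        partition_roles(pop, cfg, rng)
        discoverer_update(pop, cfg, space, rng)
        follower_update(pop, cfg, space, rng)
        scout_update(pop, cfg, space, rng)
        evaluate(pop, obj)
        _elite_refresh_stage(pop, f_internal, cfg, space, rng)
        history[t] = pop.best_fitness
    sign = 1.0 if obj.sense == "minimize" else -1.0
    return OptimizationResult(
        best_position=pop.best_position.copy(),
        best_fitness=sign * pop.best_fitness,
        history=sign * history,
        n_evaluations=pop.n_evaluations,
        seed=cfg.seed,
        algorithm="issa",
    )
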