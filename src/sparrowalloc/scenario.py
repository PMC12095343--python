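"""Synthetic allocation-scenario generator.

Emulates multi-region public-health education resource allocation over the
four resource categories — R1 teaching materials, R2 teaching staff, R3
teaching facilities, R4 information-technology support — with per-target
efficiencies, weights, effect functions and a concentration cap, so every
optimizer and model component is testable without external data.  Linear
scenarios come with machine-checkable exact optima from the KKT oracle.

Shareable categories (materials, IT) can serve any region over the network
and get a loose per-target upper bound (1.0 by default); location-bound
categories (staff, facilities) get a tighter one (0.5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .allocation import (
    CATEGORIES,
    DEFAULT_SHAREABLE,
    AllocationProblem,
    kkt_oracle_linear,
)
from .exceptions import ConfigurationError

__all__ = ["ScenarioSpec", "generate_scenario", "generate_with_known_optimum"]

#: per-target upper bound by shareability
UB_SHAREABLE = 1.0
UB_LOCATION_BOUND = 0.5


@dataclass
class ScenarioSpec:
    """Parameters of the synthetic scenario family.

    Efficiencies are log-uniform on ``efficiency_range`` (default [0.5, 2],
    a 4x spread between the least and most efficient target).  Weights are
    either exactly uniform or Dirichlet(``alpha_w``) draws.  The
    concentration cap ``delta_sq`` is drawn uniformly from
    ``delta_sq_range`` (default the full feasible interval ``[1/n, 1]``,
    spanning forced-uniform to unconstrained regimes).
    """

    n_regions: int = 5
    categories: Sequence[str] = CATEGORIES
    efficiency_range: tuple[float, float] = (0.5, 2.0)
    weight_law: str = "uniform"
    alpha_w: float = 5.0
    delta_sq_range: Optional[tuple[float, float]] = None
    g_family_mix: dict = field(default_factory=lambda: {"linear": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ConfigurationError("n_regions must be >= 2")
        for c in self.categories:
            if c not in CATEGORIES:
                raise ConfigurationError(f"unknown category {c!r}")
        if self.weight_law not in ("uniform", "dirichlet"):
            raise ConfigurationError("weight_law must be 'uniform' or 'dirichlet'")
        lo, hi = self.efficiency_range
        if not 0 < lo <= hi:
            raise ConfigurationError("efficiency_range must be positive and ordered")
        if self.delta_sq_range is not None:
            lo, hi = self.delta_sq_range
            if lo < 1.0 / self.n_regions or hi > 1.0 or lo > hi:
                raise ConfigurationError("delta_sq_range must lie within [1/n, 1]")
        if abs(sum(self.g_family_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("g_family_mix probabilities must sum to 1")


def _draw_g(rng: np.random.Generator, mix: dict, n: int) -> tuple[list, list]:
    fams = rng.choice(list(mix), size=n, p=list(mix.values()))
    families, params = [], []
    for fam in fams:
        families.append(str(fam))
        if fam == "saturating":
            params.append(float(rng.uniform(2.0, 8.0)))  # half-effect around x ~ 0.1-0.35
        elif fam == "power":
            params.append(float(rng.uniform(0.5, 0.9)))  # concave returns
        else:
            params.append(float("nan"))
    return families, params


def generate_scenario(spec: ScenarioSpec) -> dict[str, AllocationProblem]:
    """Draw one AllocationProblem per requested category, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    lo_d, hi_d = spec.delta_sq_range if spec.delta_sq_range else (1.0 / n, 1.0)
    problems: dict[str, AllocationProblem] = {}
    for cat in spec.categories:
        log_lo, log_hi = np.log(spec.efficiency_range)
        eff = np.exp(rng.uniform(log_lo, log_hi, size=n))
        if spec.weight_law == "uniform":
            w = np.full(n, 1.0 / n)
        else:
            w = rng.dirichlet(np.full(n, spec.alpha_w))
        fams, params = _draw_g(rng, spec.g_family_mix, n)
        delta_sq = float(rng.uniform(lo_d, hi_d))
        shareable = DEFAULT_SHAREABLE[cat]
        ub_val = UB_SHAREABLE if shareable else UB_LOCATION_BOUND
        problems[cat] = AllocationProblem(
            efficiency=eff,
            delta_sq=delta_sq,
            weights=w,
            g_family=fams,
            g_param=params,
            lb=np.zeros(n),
            ub=np.full(n, ub_val),
            category=cat,
            shareable=shareable,
        )
    return problems


def generate_with_known_optimum(
    n: int, seed: int
) -> tuple[AllocationProblem, np.ndarray, float]:
    """A linear-effect problem together with its exact optimum.

    Efficiencies are log-uniform on [0.5, 2], weights uniform, bounds [0, 1],
    and the cap uniform on [1/n, 1].  Returns ``(problem, x_star, f_star)``
    with ``f_star`` on the weighted-objective scale, computed by the KKT
    oracle — ideal for end-to-end recovery tests.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    rng = np.random.default_rng(seed)
    eff = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n))
    delta_sq = float(rng.uniform(1.0 / n, 1.0))
    prob = AllocationProblem(efficiency=eff, delta_sq=delta_sq, category="R1")
    c = prob.weights * prob.efficiency  # linear objective coefficients
    x_star, f_star = kkt_oracle_linear(c, delta_sq)
    return prob, x_star, f_star
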