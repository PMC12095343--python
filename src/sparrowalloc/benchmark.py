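"""Benchmark harness: convergence records, paired comparisons, ablations.

Runs the two optimizers over benchmark objectives for a list of seeds,
records per-iteration best-so-far curves, and aggregates paired per-seed
statistics (win/loss/tie sign counts and medians).  All aggregates are
recomputable from the raw records, and reports round-trip losslessly
through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .good_points import estimate_discrepancy, generate_good_point_set
from .issa import run_issa
from .objectives import DEFAULT_BOUNDS, make_test_objective
from .ssa import OptimizerConfig, SearchSpace, run_ssa

__all__ = ["BenchmarkReport", "run_benchmark", "ablate_initializer", "discrepancy_ablation"]


@dataclass
class BenchmarkReport:
    """Per-run records plus aggregates derived from them."""

    records: list = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)
    discrepancy_table: list = field(default_factory=list)

    def recompute_aggregates(self) -> dict:
        """(Re)derive medians, IQRs and paired sign counts from the records."""
        by_arm: dict[tuple[str, str], dict[int, float]] = {}
        for rec in self.records:
            key = (rec["objective"], rec["arm"])
            by_arm.setdefault(key, {})[rec["seed"]] = rec["final_fitness"]
        agg: dict = {"arms": {}, "paired": {}}
        for (objective, arm), by_seed in sorted(by_arm.items()):
            vals = np.array([by_seed[s] for s in sorted(by_seed)])
            agg["arms"][f"{objective}/{arm}"] = {
                "n_runs": int(vals.size),
                "median": float(np.median(vals)),
                "iqr": float(np.subtract(*np.percentile(vals, [75, 25]))),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        objectives = sorted({obj for obj, _ in by_arm})
        for objective in objectives:
            arms = sorted(arm for obj, arm in by_arm if obj == objective)
            for i, a in enumerate(arms):
                for b in arms[i + 1 :]:
                    seeds = sorted(set(by_arm[(objective, a)]) & set(by_arm[(objective, b)]))
                    fa = np.array([by_arm[(objective, a)][s] for s in seeds])
                    fb = np.array([by_arm[(objective, b)][s] for s in seeds])
                    agg["paired"][f"{objective}/{a}_vs_{b}"] = {
                        "n_pairs": len(seeds),
                        "wins_first": int(np.sum(fa < fb)),
                        "wins_second": int(np.sum(fb < fa)),
                        "ties": int(np.sum(fa == fb)),
                        "median_first": float(np.median(fa)),
                        "median_second": float(np.median(fb)),
                    }
        self.aggregates = agg
        return agg

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "aggregates": self.aggregates,
            "discrepancy_table": self.discrepancy_table,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "BenchmarkReport":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            records=data["records"],
            aggregates=data.get("aggregates", {}),
            discrepancy_table=data.get("discrepancy_table", []),
        )


def _record(arm: str, objective_name: str, seed: int, result) -> dict:
    return {
        "arm": arm,
        "algorithm": result.algorithm,
        "objective": objective_name,
        "seed": int(seed),
        "final_fitness": float(result.best_fitness),
        "n_evaluations": int(result.n_evaluations),
        "history": [float(v) for v in result.history],
    }


def run_benchmark(
    objective_names: Sequence[str],
    d: int,
    algorithms: Sequence[str],
    cfg: OptimizerConfig,
    seeds: Sequence[int],
) -> BenchmarkReport:
    """Full-factorial benchmark over objectives x algorithms x seeds."""
    if not objective_names or not seeds:
        raise ConfigurationError("need at least one objective and one seed")
    for alg in algorithms:
        if alg not in ("ssa", "issa"):
            raise ConfigurationError(f"unknown algorithm {alg!r}")
    report = BenchmarkReport()
    for name in objective_names:
        obj = make_test_objective(name, d)
        space = SearchSpace.symmetric(d, DEFAULT_BOUNDS[name])
        for alg in algorithms:
            for seed in seeds:
                run_cfg = replace(cfg, seed=int(seed))
                result = run_ssa(obj, space, run_cfg) if alg == "ssa" else run_issa(obj, space, run_cfg)
                report.records.append(_record(alg, name, seed, result))
    report.recompute_aggregates()
    return report


def ablate_initializer(
    objective_name: str,
    d: int,
    cfg: OptimizerConfig,
    seeds: Sequence[int],
) -> BenchmarkReport:
    """ISSA with good-point-set init vs ISSA with random init, same seeds."""
    if not seeds:
        raise ConfigurationError("need at least one seed")
    obj = make_test_objective(objective_name, d)
    space = SearchSpace.symmetric(d, DEFAULT_BOUNDS[objective_name])
    report = BenchmarkReport()
    for seed in seeds:
        run_cfg = replace(cfg, seed=int(seed))
        for arm, init in (("issa-gps", "gps"), ("issa-random", "random")):
            result = run_issa(obj, space, run_cfg, init=init)
            report.records.append(_record(arm, objective_name, seed, result))
    report.recompute_aggregates()
    return report


def discrepancy_ablation(
    n_points: int = 1000,
    dims: Sequence[int] = (2, 5),
    n_random_sets: int = 20,
    n_probe: int = 4096,
    seed: int = 0,
) -> list[dict]:
    """Estimated star discrepancy: good point set vs uniform-random sets.

    For each dimension, compares the deterministic good point set against
    ``n_random_sets`` random sets of equal size using the same probe seed,
    reporting the paired win count and mean random discrepancy.
    """
    rng = np.random.default_rng(seed)
    table = []
    for d in dims:
        probe_seed = int(rng.integers(2**31))
        gps = generate_good_point_set(n_points, d)
        d_gps = estimate_discrepancy(gps.points, n_probe=n_probe, seed=probe_seed)
        d_rand = []
        for _ in range(n_random_sets):
            pts = rng.random((n_points, d))
            d_rand.append(estimate_discrepancy(pts, n_probe=n_probe, seed=probe_seed))
        d_rand = np.array(d_rand)
        table.append(
            {
                "d": int(d),
                "n_points": int(n_points),
                "gps_discrepancy": float(d_gps),
                "random_mean_discrepancy": float(d_rand.mean()),
                "random_min_discrepancy": float(d_rand.min()),
                "wins": int(np.sum(d_gps < d_rand)),
                "n_random_sets": int(n_random_sets),
            }
        )
    return table
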