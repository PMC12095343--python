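"""Paired-seed comparison of baseline and improved sparrow search.

Compares the two optimizers where it matters for this package: on random
linear allocation problems with known exact optima.  Both algorithms solve
each problem from the same seed; the relative gap to the KKT oracle
measures solution quality (lower is better).
"""

import numpy as np

from sparrowalloc import OptimizerConfig, generate_with_known_optimum, solve_allocation

issa_gaps, ssa_gaps = [], []
for i in range(12):
    prob, _, f_star = generate_with_known_optimum(n=8, seed=300 + i)
    cfg = OptimizerConfig(pop_size=30, max_iter=150, seed=i)
    for algorithm, gaps in (("issa", issa_gaps), ("ssa", ssa_gaps)):
        sol = solve_allocation(prob, cfg, algorithm=algorithm)
        gaps.append((f_star - sol.objective_value) / f_star)

issa_gaps, ssa_gaps = np.array(issa_gaps), np.array(ssa_gaps)
print(f"ISSA median relative gap: {np.median(issa_gaps):.2e}")
print(f"SSA  median relative gap: {np.median(ssa_gaps):.2e}")
print(f"ISSA closer to the optimum in {np.sum(issa_gaps < ssa_gaps)} of 12 paired runs")
# The deterministic low-discrepancy start and the greedy elite-guided
# refresh give ISSA roughly an order of magnitude smaller optimality gaps
# here.  On easy multimodal benchmarks (e.g. Rastrigin) both algorithms
# reach the exact optimum and the comparison ties.
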