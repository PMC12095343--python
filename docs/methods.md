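# Methods

## The optimization problem

Public-health education resources of one category (teaching materials,
teaching staff, teaching facilities, or IT support) are divided among `n`
targets — regions, institutions, or projects.  A candidate allocation is a
share vector `x` on the probability simplex, and the model is

```
maximize   f(x) = Σ_a  w_a · g_a(x_a)
subject to Σ_a x_a = 1,    x_a ≥ 0,    Σ_a x_a² ≤ δ²,
```

with target weights `w` (nonnegative, summing to 1), per-target effect
functions `g_a`, and a concentration cap `δ²` on the second moment of the
shares.  Since `Σx² = 1/n` for the uniform split and `1` for a one-hot
split, any `δ² ∈ [1/n, 1]` interpolates between "force an even spread" and
"no concentration limit".  The cap is a second-moment bound as written, not
a central-moment variance; on the simplex the two orderings agree
(`Var(x) = (Σx² − 1/n)/n`), so the cap plays exactly the role of a variance
limit on the allocation pattern.

Effect functions come in three families, per target:

| family       | form                  | use case                              |
|--------------|-----------------------|---------------------------------------|
| `linear`     | `E·x`                 | effect proportional to share (default)|
| `saturating` | `E·(1 − e^(−κx))`     | diminishing returns, scale `1/κ`      |
| `power`      | `E·x^γ`, `γ ∈ (0,1)`  | concave returns                       |

`E_a > 0` is the target's efficiency — how well it converts resources into
educational effect.  With all-linear effects and uniform weights the
objective reduces (up to the constant `1/n`) to the plain
efficiency-weighted sum `Σ x_a E_a`.

Each resource category is optimized independently: materials and IT support
can be shared over a network while staff and facilities are bound to a
location, so pooling them into one parameter would misstate substitution
possibilities.  Shareability only affects scenario generation (per-target
upper bounds), not the mathematics.

## Balance metric

"Balance" of an allocation is reported as Jain's fairness index
`(Σx)² / (n·Σx²)`, which is 1 for the uniform split and `1/n` for one-hot.
On the simplex it equals `1/(n·Σx²)`, so the concentration cap directly
lower-bounds balance at `1/(n·δ²)` — the cap and the reported metric are
two views of the same second moment.

## Baseline sparrow search (SSA)

A population of `N` candidate positions is evolved for `T` iterations.
Each iteration, the flock is ranked by fitness and partitioned:

* the best `⌈PD·N⌉` are **discoverers**: with probability `ST` (alarm
  threshold) discoverer of rank `r` contracts multiplicatively,
  `X ← X·exp(−r/(u·T))`, `u ~ U(0,1]`; otherwise a shared standard-normal
  scalar is added to every coordinate;
* `⌈SD·N⌉` individuals drawn uniformly from the rest are **scouts**, each
  moving a uniform-random fraction of the way toward the best-so-far
  position (one draw per scout, shared across dimensions, so the move stays
  on the segment);
* the remainder are **followers**: the worst half (by overall rank `r`)
  migrates as `Q·exp((X_worst − X)/r²)` with `Q` standard normal, the best
  half is attracted to the best position, landing at
  `X_best ± |X − X_best|/d` per coordinate.

Positions are clamped to the search box after every update (clamping, not
reflection, so repaired positions stay in the stated range).  Fitness ties
break toward the lower index, the optimizer minimizes internally
(maximization objectives are negated at the boundary), and all randomness
flows from one seeded generator, making fixed-seed runs bit-identical.
The best-so-far record tracks every position ever evaluated, so the
per-iteration history is monotone by construction.

Default role fractions are `PD = 0.2`, `SD = 0.1`, `ST = 0.8` — the common
choices in the sparrow-search literature; all are configurable.

## The improvement layer (ISSA)

Two changes, both orthogonal to the role dynamics:

**Good-point-set initialization.**  Iteration-0 positions are the classical
good point set: generators `γ_j = frac(2·cos(2πj/p))` with `p` the smallest
prime `≥ 2d+3`, points `({γ_1 k}, …, {γ_d k})` for `k = 1…N`, affinely
mapped into the box.  The construction is deterministic — the initial flock
is identical for every seed — and covers the box more evenly than uniform
sampling.  Uniformity is quantified by a Monte-Carlo star-discrepancy
estimate (4096 anchored boxes by default; exact star discrepancy is NP-hard
in the dimension, and the Monte-Carlo value is a lower bound on it).  The
advantage is asymptotic in the point count: at `n = 1000` the good point
set beats 20 random sets in 20/20 paired comparisons for `d ∈ {2, 5}`, but
at small counts in higher dimension (e.g. `n = 100, d = 5`) the
fixed-generator lattice can lose to random sampling.  Population sizes of
practical interest here (`N ≥ 30`, `d ≤ 10`) sit in the favorable regime
for the *optimizer* use case, where what matters is avoiding the clustering
of a random draw.

**Elite-guided refresh.**  After the role updates of every iteration, the
elite set — the best `⌈q·N⌉` individuals — is re-selected and every
individual proposes

```
X' = X + α·(P_best − X) + β·(rand − 0.5)·(UB − LB)
```

with `P_best` the best-so-far position, `rand` fresh per dimension, and the
result clamped.  The proposal is accepted only if it improves the
individual's fitness.  Greedy acceptance is the deliberate design choice
here: position quality is preserved while the guided move adds exploration
pressure.  An unconditional replacement would re-inject uniform noise of
magnitude `~β·(UB − LB)` into every position every iteration, putting a
floor of order `(β·range)²` under the achievable objective on smooth
problems and destroying the multiplicative fine-convergence the discoverer
rule provides; with greedy acceptance the refresh can only help.  The cost
is one extra evaluation per individual per iteration (`2N` total), which
the evaluation counter reports faithfully.

Elite membership is governed by *selection* (re-ranking the freshly
evaluated flock), not by interpolating old members toward new ones; the
relaxation toward the elite region acts through the `α`-pull of the update
itself.  This keeps one mechanism responsible for one effect.

Defaults: `α = 0.5` (halfway pull), `β = 0.3` (perturbation up to ±15% of
the range per coordinate), `q = 0.2`.  Whether the update helps depends on
the landscape: on the allocation problems it reduces optimality gaps by
roughly an order of magnitude over the baseline, on narrow curved valleys
(Rosenbrock) the extra exploration does not pay, and on easy multimodal
benchmarks both variants reach the exact optimum.

## Constraint handling: repair before evaluation

Optimizer positions live in the box `[LB, UB]^n` and are repaired to
feasibility before every fitness evaluation:

1. clamp to the per-target box;
2. Euclidean projection onto the simplex (sorted-threshold algorithm,
   `O(n log n)`);
3. if `Σx² > δ²`, shrink affinely toward the uniform vector:
   `x ← u + t(x − u)` with `t = √((δ² − 1/n)/(Σx² − 1/n))`, which stays on
   the simplex, preserves the ranking of components, and meets the cap with
   equality.

Repair was chosen over penalty terms because the update rule already clamps
positions into "the effective allocation range"; repair extends that clamp
to the remaining two constraint families and guarantees every reported
solution is feasible to tolerance (`Σx = 1 ± 1e−9`, `x ≥ −1e−12`,
`Σx² ≤ δ² + 1e−9`).  The composition is idempotent.  Note the simplex
projection can push a coordinate past a tight per-target upper bound; the
feasibility report flags the box family separately, and in the generated
scenarios (bounds 0.5/1.0) this is rare and small.

## Exact oracle for linear effects

For linear effects the problem is `max c·x` on the capped simplex with
`c = w ⊙ E`.  KKT stationarity gives `x_a ∝ max(0, c_a − λ)` on the
support; the second moment of that family is monotone in `λ`, so the
active-cap solution is found by bisection (200 iterations, machine
precision).  Corner cases handled exactly: `δ² ≥ 1` gives the one-hot
vertex on `argmax c` (lowest index on ties), `δ² = 1/n` gives the uniform
vector, and a tied maximum with slack cap gives the uniform split over the
argmax set.  The oracle is cross-checked against dense grid search (step
`1e−3`) on three-target instances in the test suite; grid search can only
undershoot the true optimum, by at most a few times the step size.

## Synthetic scenarios

The generator emulates multi-region, four-category allocation problems:
efficiencies log-uniform on `[0.5, 2]` (a 4× spread — large enough that
concentration pressure is real, small enough that no target is worthless),
weights uniform or Dirichlet, `δ²` uniform over the full feasible interval
`[1/n, 1]` so instances span forced-uniform to unconstrained regimes, and
per-target upper bounds of 0.5 for location-bound categories (staff,
facilities) versus 1.0 for shareable ones (materials, IT).  Linear
instances are emitted together with their oracle optimum, giving every
end-to-end test a machine-checkable target.

What the generator does *not* emulate: real regional demand data,
correlations between categories, temporal dynamics, or indivisible
resources.  Passing tests therefore demonstrate the optimizer's correctness
and convergence on the stated problem class, not calibration to any real
allocation dataset.

## Platform scores

The content-push score is the inner product of a content item's user-group
affinities with the strategy weights; items are pushed in descending score
order with lowest-index tie-break.  Scores are linear in the strategy, so
positive rescaling never changes the ranking.  The satisfaction score is a
convex combination of service-quality ratings under normalized importance
weights, hence always bounded by the worst and best rating.  Weight
normalization is validated, not silently applied.

## Problem sizes and numerical choices

Test-suite and reproduction runs use populations of 10–30 for 25–500
iterations and allocation sizes `n ∈ {3, 5, 10}` — sizes at which the
solver's median relative gap to the exact oracle is below `1e−3` and a
full reproduction completes in a couple of minutes on one core.  Key
tolerances: simplex and variance feasibility `1e−9`, nonnegativity
`1e−12`, oracle bisection to machine precision, discrepancy probes 4096.
Degenerate inputs are rejected with specific errors: `δ² < 1/n` (empty
feasible set), nonpositive efficiencies, unnormalized weights, role
fractions that leave no followers, boxes with `ub ≤ lb`.

## Known limitations

* Single-period, divisible allocations only; no equity constraints beyond
  the concentration cap.
* The elite refresh doubles per-iteration evaluation cost; on objectives
  where it does not help, that cost buys nothing.
* The good-point-set advantage degrades at small point counts in higher
  dimensions (see above).
* Comparator metaheuristics (PSO, GWO, and hybrids) are out of scope; the
  benchmark harness compares the two implemented variants only.
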