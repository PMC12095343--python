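"""Allocation model: objective, constraints, repair, balance, oracle, solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sparrowalloc import (
    AllocationProblem,
    ConfigurationError,
    InfeasibleProblemError,
    OptimizerConfig,
    allocation_objective,
    enforce_variance_cap,
    jain_balance,
    kkt_oracle_linear,
    load_problem,
    project_to_simplex,
    repair,
    save_problem,
    solve_allocation,
)


def grid_oracle_n3(efficiency, delta_sq, step=1e-3):
    """Dense grid search over the capped 3-simplex; independent of the KKT path."""
    g = np.arange(0.0, 1.0 + step / 2, step)
    x1, x2 = np.meshgrid(g, g, indexing="ij")
    x3 = 1.0 - x1 - x2
    ok = (x3 >= -1e-12) & (x1**2 + x2**2 + x3**2 <= delta_sq + 1e-9)
    f = x1 * efficiency[0] + x2 * efficiency[1] + x3 * efficiency[2]
    f[~ok] = -np.inf
    return float(f.max())


class TestObjective:
    def test_linear_weighted_values(self):
        prob = AllocationProblem(efficiency=np.array([2.0, 1.0]), delta_sq=1.0)
        assert allocation_objective(np.array([1.0, 0.0]), prob) == pytest.approx(1.0)
        assert allocation_objective(np.array([0.5, 0.5]), prob) == pytest.approx(0.75)

    def test_saturating_effect_vanishes_at_zero(self):
        prob = AllocationProblem(
            efficiency=np.array([3.0, 1.0]),
            delta_sq=1.0,
            g_family=["saturating", "linear"],
            g_param=[4.0, float("nan")],
        )
        assert allocation_objective(np.array([0.0, 1.0]), prob) == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        prob = AllocationProblem(efficiency=np.array([1.0, 1.0]), delta_sq=1.0)
        with pytest.raises(ValueError):
            allocation_objective(np.array([1.0]), prob)

    def test_infeasible_variance_cap_rejected(self):
        with pytest.raises(InfeasibleProblemError):
            AllocationProblem(efficiency=np.ones(4), delta_sq=0.2)  # 1/n = 0.25


class TestSimplexProjection:
    def test_simplex_points_are_fixed(self):
        v = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(project_to_simplex(v), v, atol=1e-12)

    def test_known_projection(self):
        np.testing.assert_allclose(
            project_to_simplex(np.array([0.5, 0.5, 1.0])),
            [1 / 6, 1 / 6, 2 / 3],
            atol=1e-12,
        )

    def test_symmetric_negative_input_projects_to_uniform(self):
        np.testing.assert_allclose(project_to_simplex(np.array([-5.0, -5.0])), [0.5, 0.5])

    @given(
        arrays(
            float,
            st.integers(2, 8),
            elements=st.floats(-10, 10, allow_nan=False),
        )
    )
    def test_projection_lands_on_simplex_and_is_idempotent(self, v):
        x = project_to_simplex(v)
        assert np.all(x >= 0)
        assert x.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(project_to_simplex(x), x, atol=1e-9)

    @settings(max_examples=15)
    @given(st.integers(0, 10_000))
    def test_matches_scipy_constrained_least_squares(self, seed):
        # independent route: minimize ||x - v||^2 over the simplex with SLSQP
        from scipy.optimize import minimize

        v = np.random.default_rng(seed).uniform(-2, 2, size=4)
        x = project_to_simplex(v)
        res = minimize(
            lambda z: np.sum((z - v) ** 2),
            np.full(4, 0.25),
            method="SLSQP",
            bounds=[(0, None)] * 4,
            constraints={"type": "eq", "fun": lambda z: z.sum() - 1},
            options={"ftol": 1e-14, "maxiter": 500},
        )
        np.testing.assert_allclose(x, res.x, atol=1e-5)


class TestVarianceCap:
    def test_closed_form_two_target_case(self):
        x = enforce_variance_cap(np.array([1.0, 0.0]), 0.625)
        np.testing.assert_allclose(x, [0.75, 0.25])
        assert float(x @ x) == pytest.approx(0.625, abs=1e-15)

    def test_uniform_is_fixed_for_any_admissible_cap(self):
        u = np.full(5, 0.2)
        np.testing.assert_array_equal(enforce_variance_cap(u, 0.2), u)
        np.testing.assert_array_equal(enforce_variance_cap(u, 1.0), u)

    @given(st.integers(0, 10_000))
    def test_shrink_preserves_component_ranking(self, seed):
        rng = np.random.default_rng(seed)
        x = project_to_simplex(rng.uniform(0, 1, size=5))
        d2 = rng.uniform(0.2, 1.0)
        y = enforce_variance_cap(x, d2)
        assert y.sum() == pytest.approx(1.0, abs=1e-9)
        assert float(y @ y) <= d2 + 1e-9
        np.testing.assert_array_equal(np.argsort(x, kind="stable"), np.argsort(y, kind="stable"))

    def test_infeasible_cap_rejected(self):
        with pytest.raises(InfeasibleProblemError):
            enforce_variance_cap(np.array([0.5, 0.5]), 0.3)


class TestRepair:
    @given(
        arrays(float, 5, elements=st.floats(-3, 3, allow_nan=False)),
        st.floats(0.25, 1.0),
    )
    def test_repair_feasible_and_idempotent(self, v, delta_sq):
        prob = AllocationProblem(efficiency=np.ones(5), delta_sq=delta_sq)
        x, _ = repair(v, prob)
        assert x.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(x >= -1e-12)
        assert float(x @ x) <= delta_sq + 1e-9
        x2, changed2 = repair(x, prob)
        np.testing.assert_allclose(x2, x, atol=1e-9)
        assert not changed2

    def test_feasible_input_not_flagged(self, linear_problem):
        x = np.full(4, 0.25)
        _, changed = repair(x, linear_problem)
        assert not changed


class TestJainBalance:
    def test_uniform_is_perfectly_balanced(self):
        assert jain_balance(np.full(7, 1 / 7)) == pytest.approx(1.0)

    def test_one_hot_gives_reciprocal_n(self):
        assert jain_balance(np.array([0.0, 0.0, 0.0, 1.0])) == pytest.approx(0.25)

    def test_two_target_example(self):
        assert jain_balance(np.array([0.75, 0.25])) == pytest.approx(0.8)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            jain_balance(np.zeros(3))


class TestKKTOracle:
    def test_unit_cap_gives_one_hot_argmax(self):
        x, f = kkt_oracle_linear(np.array([1.0, 3.0, 2.0]), 1.0)
        np.testing.assert_array_equal(x, [0.0, 1.0, 0.0])
        assert f == 3.0

    def test_minimal_cap_gives_uniform(self):
        e = np.array([1.0, 2.0, 3.0, 4.0])
        x, f = kkt_oracle_linear(e, 0.25)
        np.testing.assert_allclose(x, 0.25)
        assert f == pytest.approx(e.mean())

    def test_binding_cap_closed_form(self):
        x, f = kkt_oracle_linear(np.array([2.0, 1.0]), 0.625)
        np.testing.assert_allclose(x, [0.75, 0.25], atol=1e-12)
        assert f == pytest.approx(1.75)

    @given(st.integers(0, 10_000))
    def test_matches_dense_grid_search_for_n3(self, seed):
        rng = np.random.default_rng(seed)
        e = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=3))
        d2 = rng.uniform(1 / 3, 1.0)
        x, f = kkt_oracle_linear(e, d2)
        f_grid = grid_oracle_n3(e, d2)
        # grid can only undershoot, by at most O(step * |E|)
        assert f >= f_grid - 1e-9
        assert f - f_grid <= 5e-3
        assert x.sum() == pytest.approx(1.0, abs=1e-9)
        assert float(x @ x) <= d2 + 1e-9

    def test_infeasible_cap_rejected(self):
        with pytest.raises(InfeasibleProblemError):
            kkt_oracle_linear(np.ones(4), 0.1)


class TestSolveAllocation:
    def test_recovers_oracle_optimum_on_linear_problem(self):
        e = np.array([1.9, 1.2, 0.8, 0.6, 0.5])
        prob = AllocationProblem(efficiency=e, delta_sq=0.4)
        x_star, f_star = kkt_oracle_linear(prob.weights * e, 0.4)
        gaps = []
        for seed in range(5):
            sol = solve_allocation(prob, OptimizerConfig(pop_size=30, max_iter=300, seed=seed))
            gaps.append((f_star - sol.objective_value) / f_star)
        assert np.median(gaps) <= 1e-3

    def test_solution_satisfies_all_invariants(self, linear_problem):
        sol = solve_allocation(linear_problem, OptimizerConfig(pop_size=20, max_iter=60, seed=2))
        assert sol.feasible["simplex"] and sol.feasible["nonneg"] and sol.feasible["variance"]
        assert sol.x.sum() == pytest.approx(1.0, abs=1e-9)
        assert float(sol.x @ sol.x) <= linear_problem.delta_sq + 1e-9
        assert sol.balance >= 1.0 / (linear_problem.n * linear_problem.delta_sq) - 1e-9

    def test_minimal_cap_forces_uniform_regardless_of_efficiency(self):
        prob = AllocationProblem(efficiency=np.array([9.0, 1.0, 1.0]), delta_sq=1 / 3)
        sol = solve_allocation(prob, OptimizerConfig(pop_size=15, max_iter=30, seed=0))
        np.testing.assert_allclose(sol.x, 1 / 3, atol=1e-9)

    def test_ssa_backend_also_feasible(self, linear_problem):
        sol = solve_allocation(
            linear_problem, OptimizerConfig(pop_size=20, max_iter=60, seed=2), algorithm="ssa"
        )
        assert all(sol.feasible[k] for k in ("simplex", "nonneg", "variance"))

    def test_unknown_algorithm_rejected(self, linear_problem):
        with pytest.raises(ConfigurationError):
            solve_allocation(linear_problem, OptimizerConfig(), algorithm="pso")

    def test_monotone_share_in_efficiency_for_saturating_effects(self):
        # raising one target's efficiency never lowers its optimal share
        def best_share(e0):
            prob = AllocationProblem(
                efficiency=np.array([e0, 1.0, 1.0]),
                delta_sq=0.9,
                g_family=["saturating"] * 3,
                g_param=[4.0] * 3,
            )
            sol = solve_allocation(prob, OptimizerConfig(pop_size=25, max_iter=150, seed=7))
            return sol.x[0]

        shares = [best_share(e) for e in (0.8, 1.5, 3.0)]
        assert shares[0] <= shares[1] + 5e-3 <= shares[2] + 1e-2


class TestProblemIO:
    def test_csv_json_roundtrip(self, tmp_path, linear_problem):
        csv_p, meta_p = tmp_path / "prob.csv", tmp_path / "prob.json"
        save_problem(linear_problem, csv_p, meta_p)
        back = load_problem(csv_p, meta_p)
        np.testing.assert_allclose(back.efficiency, linear_problem.efficiency)
        np.testing.assert_allclose(back.weights, linear_problem.weights)
        assert back.delta_sq == linear_problem.delta_sq
        assert back.category == linear_problem.category
        assert back.g_family == linear_problem.g_family

    def test_missing_columns_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("target_id,efficiency\nA1,1.0\n")
        (tmp_path / "bad.json").write_text('{"n": 1, "delta_sq": 1.0}\n')
        with pytest.raises(ConfigurationError, match="missing columns"):
            load_problem(tmp_path / "bad.csv", tmp_path / "bad.json")
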