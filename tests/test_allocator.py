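"""Allocator: LP optima, enumeration oracle, greedy special case, duals."""

import math

import numpy as np
import pytest

import prevalloc as pv
from prevalloc.allocator import OracleSizeError

from conftest import make_problem, random_capacity_free_instance, random_small_instance


@pytest.fixture()
def two_program_problem():
    # A strictly better than B at the same cost
    return make_problem({"A": [(2.0, 100.0, 10.0)], "B": [(1.0, 100.0, 10.0)]})


@pytest.fixture()
def capacity_problem():
    # one program, two identical ages, capacity below total demand
    return make_problem({"A": [(2.0, 100.0, 10.0), (2.0, 100.0, 10.0)]}, caps={"A": 12.0})


@pytest.fixture()
def greedy_problem():
    # A at 100 euro/QALY (max spend 500), B at 200 euro/QALY (max spend 400)
    return make_problem({"A": [(1.0, 100.0, 5.0)], "B": [(0.5, 100.0, 4.0)]})


class TestSolveAllocation:
    def test_zero_budget_zero_allocation(self, two_program_problem):
        a = pv.solve_allocation(two_program_problem, 0.0)
        assert a.optimal
        assert a.total_qalys == 0.0
        assert (a.participants == 0).all()

    def test_funds_better_program_first(self, two_program_problem):
        a = pv.solve_allocation(two_program_problem, 500.0)
        assert a.total_qalys == pytest.approx(10.0, rel=1e-9)
        assert a.participants["A1"] == pytest.approx(5.0, rel=1e-9)
        assert a.participants["B1"] == pytest.approx(0.0, abs=1e-9)

    def test_capacity_split_prefers_youngest(self, capacity_problem):
        a = pv.solve_allocation(capacity_problem, 10_000.0)
        assert a.total_qalys == pytest.approx(24.0, rel=1e-9)
        assert a.spend == pytest.approx(1200.0, rel=1e-9)
        assert a.participants["A1"] == pytest.approx(10.0, rel=1e-9)
        assert a.participants["A2"] == pytest.approx(2.0, rel=1e-9)
        assert "cap:A" in a.binding

    def test_deterministic_across_runs(self, capacity_problem):
        a1 = pv.solve_allocation(capacity_problem, 10_000.0)
        a2 = pv.solve_allocation(capacity_problem, 10_000.0)
        assert (a1.participants == a2.participants).all()

    def test_feasibility_invariants_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            prob, budget = random_small_instance(rng)
            a = pv.solve_allocation(prob, budget)
            assert a.optimal
            df = a.to_frame(prob)
            tol = 1e-6
            assert (df["participants"] >= -tol).all()
            assert (df["participants"] <= df["demand"] * (1 + tol) + tol).all()
            per_prog = df.groupby("program_code")[["participants"]].sum()
            for code, row in per_prog.iterrows():
                cap = df.loc[df["program_code"] == code, "capacity"].iloc[0]
                assert row["participants"] <= cap * (1 + tol) + tol
            assert a.spend <= budget * (1 + tol) + tol
            assert a.total_qalys == pytest.approx(df["qalys"].sum(), rel=1e-9, abs=1e-9)

    def test_monotone_in_budget(self):
        rng = np.random.default_rng(12)
        prob, _ = random_small_instance(rng)
        total = sum(max(c.cost_per_participant, 0) * c.demand for c in prob.cells)
        values = [
            pv.solve_allocation(prob, b).total_qalys
            for b in np.linspace(0, 1.1 * total, 8)
        ]
        assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(values, values[1:]))

    def test_capacity_removal_never_hurts(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            prob, budget = random_small_instance(rng)
            with_caps = pv.solve_allocation(prob, budget).total_qalys
            without = pv.solve_allocation(pv.drop_capacities(prob), budget).total_qalys
            assert without >= with_caps - 1e-9 * max(1.0, abs(with_caps))


class TestOracle:
    def test_matches_lp_on_example(self, two_program_problem):
        o = pv.oracle_solve(two_program_problem, 500.0)
        assert o.total_qalys == pytest.approx(10.0, rel=1e-9)

    def test_box_optimum_at_large_budget(self, two_program_problem):
        o = pv.oracle_solve(two_program_problem, 1e9)
        assert o.total_qalys == pytest.approx(30.0, rel=1e-9)
        assert (o.participants == 10.0).all()

    def test_fractional_funding_single_cell(self):
        prob = make_problem({"A": [(1.0, 100.0, 10.0)]})
        o = pv.oracle_solve(prob, 500.0)
        assert o.participants["A1"] == pytest.approx(5.0, rel=1e-9)

    def test_size_guard(self):
        prob = make_problem({f"P{k}": [(1.0, 100.0, 10.0)] for k in range(4)})
        with pytest.raises(OracleSizeError):
            pv.oracle_solve(prob, 100.0)


class TestGreedy:
    def test_hand_checkable_example(self, greedy_problem):
        g = pv.greedy_solve(greedy_problem, 700.0)
        assert g.total_qalys == pytest.approx(6.0, rel=1e-12)
        assert g.participants["A1"] == pytest.approx(5.0)
        assert g.participants["B1"] == pytest.approx(2.0)

    def test_zero_budget_empty(self, greedy_problem):
        g = pv.greedy_solve(greedy_problem, 0.0)
        assert (g.participants == 0).all()

    def test_equal_ratios_funded_lexicographically(self):
        prob = make_problem({"B": [(1.0, 100.0, 5.0)], "A": [(1.0, 100.0, 5.0)]})
        g = pv.greedy_solve(prob, 250.0)
        assert g.participants["A1"] == pytest.approx(2.5)
        assert g.participants["B1"] == pytest.approx(0.0)

    def test_rejects_capacitated_problem(self):
        prob = make_problem({"A": [(1.0, 100.0, 5.0)]}, caps={"A": 3.0})
        with pytest.raises(ValueError, match="solve_allocation"):
            pv.greedy_solve(prob, 100.0)


class TestShadowPrices:
    def test_slack_budget_has_zero_price(self, two_program_problem):
        sp = pv.shadow_prices(two_program_problem, 1e9)
        assert sp.budget_price == pytest.approx(0.0, abs=1e-12)

    def test_budget_price_is_segment_slope(self, greedy_problem):
        # interior of the first greedy segment: 1 QALY per 100 euro
        sp = pv.shadow_prices(greedy_problem, 300.0)
        assert sp.budget_price == pytest.approx(0.01, rel=1e-9)

    def test_capacity_price_by_finite_difference(self, capacity_problem):
        sp = pv.shadow_prices(capacity_problem, 10_000.0)
        assert sp.capacity_price["A"] == pytest.approx(2.0, rel=1e-9)
        base = pv.solve_allocation(capacity_problem, 10_000.0).total_qalys
        bumped = capacity_problem.copy()
        bumped.capacities = {pid: cap + 1.0 for pid, cap in bumped.capacities.items()}
        assert pv.solve_allocation(bumped, 10_000.0).total_qalys - base == pytest.approx(
            sp.capacity_price["A"], rel=1e-9
        )

    def test_budget_dual_matches_forward_difference(self, greedy_problem):
        b = 300.0
        sp = pv.shadow_prices(greedy_problem, b)
        db = 1e-3 * b
        v0 = pv.solve_allocation(greedy_problem, b).total_qalys
        v1 = pv.solve_allocation(greedy_problem, b + db).total_qalys
        assert sp.budget_price == pytest.approx((v1 - v0) / db, rel=1e-4)


class TestMaxHealthMinCost:
    def test_uncapped_funds_all_demand(self, two_program_problem):
        end = pv.max_health_min_cost(two_program_problem)
        assert (end.participants == 10.0).all()
        assert end.spend == pytest.approx(2000.0, rel=1e-12)

    def test_cap_filled_with_cheaper_age_first(self):
        # equal q, different c across ages; capacity forces a choice
        prob = make_problem({"A": [(2.0, 200.0, 10.0), (2.0, 100.0, 10.0)]},
                            caps={"A": 12.0})
        end = pv.max_health_min_cost(prob)
        oracle = pv.oracle_solve(prob, end.spend)
        assert end.total_qalys == pytest.approx(24.0, rel=1e-9)
        assert end.participants["A2"] == pytest.approx(10.0, rel=1e-9)
        assert end.participants["A1"] == pytest.approx(2.0, rel=1e-9)
        assert oracle.total_qalys == pytest.approx(end.total_qalys, rel=1e-9)

    def test_dominated_cell_unfunded(self):
        prob = make_problem({"A": [(1.0, 100.0, 10.0)], "Z": [(-0.5, 10.0, 10.0)]})
        end = pv.max_health_min_cost(prob)
        assert end.participants["Z1"] == pytest.approx(0.0, abs=1e-9)

    def test_negative_budget_infeasible_without_cost_savers(self, two_program_problem):
        a = pv.solve_allocation(two_program_problem, -100.0)
        assert a.status == "infeasible"

    def test_cost_saving_cell_funds_under_negative_budget(self):
        prob = make_problem({"A": [(1.0, -50.0, 10.0)]})
        a = pv.solve_allocation(prob, -100.0)
        assert a.optimal
        assert a.participants["A1"] > 0
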