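"""Instance factories for verification and benchmarking.

Used by the test-suite and the reproduction script to build small allocation
problems: a hand-specified factory and two seeded random-instance families
(one inside the enumeration oracle's size guard, one capacity-free for the
greedy special case).
"""

from __future__ import annotations

import math

import numpy as np

from .problem_model import AgeGroup, AllocationProblem, Cell, Program


def make_problem(cells_spec: dict, caps: dict | None = None,
                 populations: dict | None = None) -> AllocationProblem:
    """Build a problem from ``{code: [(q, c, demand), ...per age]}`` plus
    optional ``{code: capacity}`` and ``{code: population}`` mappings."""
    n_ages = max(len(v) for v in cells_spec.values())
    ages = [AgeGroup(i + 1, f"a{i + 1}", 30.0 + 10 * i) for i in range(n_ages)]
    progs, cells, capd = [], [], {}
    for k, (code, spec) in enumerate(cells_spec.items()):
        pop = (populations or {}).get(code, "general")
        p = Program(k + 1, code, code, pop)
        progs.append(p)
        for a, (q, c, d) in enumerate(spec):
            cells.append(Cell(p.id, a + 1, q, c, d))
        capd[p.id] = math.inf if not caps or code not in caps else caps[code]
    return AllocationProblem(progs, ages, cells, capd,
                             {"general_demand_net_of_diabetes": True})


def random_small_instance(rng: np.random.Generator):
    """Random instance within the enumeration oracle's size guard
    (<= 3 programs x 2 ages), with occasional cost-saving cells and random
    capacities; returns (problem, budget)."""
    n_p = int(rng.integers(1, 4))
    n_a = int(rng.integers(1, 3))
    spec, caps = {}, {}
    for k in range(n_p):
        code = f"P{k + 1}"
        rows = []
        for _ in range(n_a):
            q = float(rng.uniform(0.05, 2.0))
            c = float(rng.uniform(20.0, 500.0))
            if rng.random() < 0.1:
                c = -c
            rows.append((q, c, float(rng.uniform(1.0, 20.0))))
        spec[code] = rows
        if rng.random() >= 0.4:
            caps[code] = float(rng.uniform(2.0, 20.0 * n_a))
    problem = make_problem(spec, caps)
    total = sum(max(c.cost_per_participant, 0.0) * c.demand for c in problem.cells)
    budget = float(rng.uniform(0.0, 1.2) * total)
    return problem, budget


def random_capacity_free_instance(rng: np.random.Generator):
    """Random capacity-free instance with strictly positive (q, c) for the
    greedy special case; returns (problem, budget)."""
    n_p = int(rng.integers(2, 6))
    n_a = int(rng.integers(1, 4))
    spec = {
        f"P{k + 1}": [
            (
                float(rng.uniform(0.05, 2.0)),
                float(rng.uniform(20.0, 500.0)),
                float(rng.uniform(1.0, 50.0)),
            )
            for _ in range(n_a)
        ]
        for k in range(n_p)
    }
    problem = make_problem(spec)
    total = sum(c.cost_per_participant * c.demand for c in problem.cells)
    budget = float(rng.uniform(0.0, 1.1) * total)
    return problem, budget
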