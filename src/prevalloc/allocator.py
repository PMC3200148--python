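"""Budget-constrained QALY maximisation.

The decision problem is the linear program

    max_p  sum_ja p_ja q_ja
    s.t.   sum_ja p_ja c_ja <= b          (budget)
           sum_a  p_ja      <= cap_j      (capacity, per program)
           0 <= p_ja <= dem_ja            (demand boxes)

with continuous participant numbers p_ja (fractional funding of a target
group is allowed; the indivisible-program variant is an integer program and
out of scope here).

:func:`solve_allocation` returns a deterministic optimal vertex via a
three-stage lexicographic solve: (1) maximise QALYs, (2) minimise spend among
QALY-optimal allocations, (3) break remaining ties toward lexicographically
earlier cells (program code, then youngest age first).  Stage 1 also yields
the dual values reported by :func:`shadow_prices`.

:func:`oracle_solve` is an independent brute-force check that enumerates all
basic feasible solutions of small instances, and :func:`greedy_solve` the
classic continuous-knapsack solution for the capacity-free special case.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .problem_model import AllocationProblem, Cell, GENERAL

#: participant-level tolerance used for support / binding detection
SUPPORT_TOL = 1e-7


class SolverError(RuntimeError):
    """The LP solver failed with an unexpected status."""


class OracleSizeError(ValueError):
    """Instance too large for the enumeration oracle."""


@dataclass
class Allocation:
    """A solution of the allocation LP.

    ``participants`` is indexed by cell code (e.g. ``"S1"``) in canonical
    order.  ``binding`` lists the constraints active at the optimum
    (``"budget"``, ``"cap:<code>"``, ``"dem:<cell>"``).
    """

    participants: pd.Series
    budget: float
    spend: float
    total_qalys: float
    status: str  # optimal | infeasible
    binding: list[str] = field(default_factory=list)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def funded_cells(self, tol: float = SUPPORT_TOL) -> frozenset[str]:
        return frozenset(self.participants.index[self.participants > tol])

    def to_frame(self, problem: AllocationProblem) -> pd.DataFrame:
        df = problem.to_frame().set_index("cell_code")
        df["participants"] = self.participants
        df["spend"] = df["participants"] * df["cost_per_participant"]
        df["qalys"] = df["participants"] * df["qaly_per_participant"]
        return df.reset_index()

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "budget": None if math.isinf(self.budget) else self.budget,
            "spend": self.spend,
            "total_qalys": self.total_qalys,
            "participants": {k: float(v) for k, v in self.participants.items()},
            "binding": list(self.binding),
        }


@dataclass
class ShadowPriceReport:
    """LP duals at the optimum: marginal QALYs per unit relaxation of each
    constraint.  Non-unique at degenerate optima, in which case
    ``degenerate`` is set."""

    budget_price: float
    capacity_price: dict[str, float]
    demand_price: dict[str, float]
    degenerate: bool = False


@dataclass
class _LPData:
    """Arrays for the LP in canonical cell order."""

    codes: list[str]
    q: np.ndarray
    c: np.ndarray
    dem: np.ndarray
    cap_rows: np.ndarray  # (n_capped, n_cells) 0/1 incidence
    cap_rhs: np.ndarray
    cap_codes: list[str]

    @classmethod
    def build(cls, problem: AllocationProblem) -> "_LPData":
        cells = problem.ordered_cells()
        for cell in cells:
            if not cell.has_outcomes:
                raise ValueError(
                    f"cell {problem.cell_code(cell)} has no (q, c) outcomes; the"
                    " league-table fixture alone cannot be optimised — use the"
                    " demo problem or the synthetic generator"
                )
        codes = [problem.cell_code(c) for c in cells]
        q = np.array([c.qaly_per_participant for c in cells], dtype=float)
        c = np.array([c.cost_per_participant for c in cells], dtype=float)
        dem = np.array([c.demand for c in cells], dtype=float)
        rows, rhs, cap_codes = [], [], []
        for prog in sorted(problem.programs, key=lambda p: p.code):
            cap = problem.capacity(prog.id)
            if math.isinf(cap):
                continue
            rows.append([1.0 if cell.program_id == prog.id else 0.0 for cell in cells])
            rhs.append(cap)
            cap_codes.append(prog.code)
        cap_rows = np.array(rows, dtype=float) if rows else np.zeros((0, len(cells)))
        return cls(codes, q, c, dem, cap_rows, np.array(rhs, dtype=float), cap_codes)

    @property
    def n(self) -> int:
        return len(self.codes)


def _run_lp(obj, A_ub, b_ub, bounds, A_eq=None, b_eq=None):
    res = linprog(obj, A_ub=A_ub if len(b_ub) else None,
                  b_ub=b_ub if len(b_ub) else None,
                  A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    return res


def _stack(data: _LPData, budget: float | None):
    rows, rhs = [], []
    if budget is not None and not math.isinf(budget):
        rows.append(data.c)
        rhs.append(budget)
    if data.cap_rows.shape[0]:
        rows.extend(data.cap_rows)
        rhs.extend(data.cap_rhs)
    A = np.vstack(rows) if rows else np.zeros((0, data.n))
    return A, np.array(rhs, dtype=float)


#: duals smaller than this are treated as zero when identifying the optimal
#: face (float noise in HiGHS duals is orders of magnitude below)
_DUAL_TOL = 1e-11


class _Face:
    """Feasible region progressively restricted to the optimal faces of a
    sequence of LP objectives (lexicographic solving)."""

    def __init__(self, A_ub: np.ndarray, rhs_ub: np.ndarray, bounds: list[tuple[float, float]]):
        self.A_ub = A_ub
        self.rhs_ub = rhs_ub
        self.A_eq = np.zeros((0, A_ub.shape[1] if A_ub.size else len(bounds)))
        self.rhs_eq = np.zeros(0)
        self.bounds = [list(b) for b in bounds]

    def solve(self, obj: np.ndarray):
        return linprog(
            obj,
            A_ub=self.A_ub if len(self.rhs_ub) else None,
            b_ub=self.rhs_ub if len(self.rhs_ub) else None,
            A_eq=self.A_eq if len(self.rhs_eq) else None,
            b_eq=self.rhs_eq if len(self.rhs_eq) else None,
            bounds=[tuple(b) for b in self.bounds],
            method="highs",
        )

    def tighten(self, res) -> None:
        """Move inequality rows with nonzero dual to equalities and fix
        variables with nonzero reduced cost at their bound.  Remaining
        inequality rows get a 1e-9 relative slack: optimality is already
        pinned by the complementary-slackness restrictions, and the slack
        absorbs float-summation mismatch between our dot products and the
        solver's when many variables end up fixed at their bounds."""
        if len(self.rhs_ub):
            lam = np.abs(res.ineqlin.marginals)
            tight = lam > _DUAL_TOL
            if tight.any():
                self.A_eq = np.vstack([self.A_eq, self.A_ub[tight]])
                self.rhs_eq = np.append(self.rhs_eq, self.rhs_ub[tight])
                self.A_ub = self.A_ub[~tight]
                self.rhs_ub = self.rhs_ub[~tight]
            self.rhs_ub = self.rhs_ub + 1e-9 * np.maximum(1.0, np.abs(self.rhs_ub))
        lower_rc = np.abs(res.lower.marginals)
        upper_rc = np.abs(res.upper.marginals)
        for i, b in enumerate(self.bounds):
            if lower_rc[i] > _DUAL_TOL:
                b[1] = b[0]
            elif upper_rc[i] > _DUAL_TOL:
                b[0] = b[1]


def solve_allocation(problem: AllocationProblem, budget: float | None) -> Allocation:
    """Optimal allocation for a fixed budget (``None`` or ``inf`` means
    unlimited).  Deterministic: lexicographic max-QALY / min-spend /
    youngest-first vertex, with participant values clipped to [0, dem]."""
    data = _LPData.build(problem)
    has_budget = budget is not None and not math.isinf(budget)
    bvalue = float(budget) if has_budget else math.inf
    bounds = [(0.0, d) for d in data.dem]
    A, rhs = _stack(data, budget if has_budget else None)

    res1 = _run_lp(-data.q, A, rhs, bounds)
    if res1.status == 2:  # infeasible (possible for negative budgets)
        return Allocation(
            participants=pd.Series(np.full(data.n, np.nan), index=data.codes),
            budget=bvalue, spend=math.nan, total_qalys=math.nan, status="infeasible",
        )
    if res1.status != 0:
        raise SolverError(f"LP stage 1 failed: {res1.message} (status {res1.status})")
    assert res1.status != 3, "unbounded cannot occur: all variables are boxed"

    # Restrict to the optimal face via complementary slackness: with an
    # optimal dual in hand, a feasible point is optimal iff every constraint
    # carrying a nonzero dual is tight.  Encoding the face through its tight
    # constraints (rather than pinning the float objective value by equality)
    # keeps the later stages numerically well posed.
    face = _Face(A, rhs, bounds)
    face.tighten(res1)
    best = res1.x

    # stage 2: minimise spend among QALY-optimal allocations.  When the
    # budget sits a float-width above a breakpoint the optimal face is
    # numerically hair-thin and presolve may reject it; the optimum is then
    # essentially unique and the previous stage's vertex already is it.
    res2 = face.solve(data.c)
    if res2.status == 0:
        face.tighten(res2)
        best = res2.x
        # stage 3: break remaining ties toward lexicographically earlier cells
        w = np.array([(data.n - i) if data.q[i] > 0 else 0.0 for i in range(data.n)])
        res3 = face.solve(-w)
        if res3.status == 0:
            best = res3.x

    p = np.clip(best, 0.0, data.dem)
    return _package(problem, data, p, bvalue)


def _package(problem: AllocationProblem, data: _LPData, p: np.ndarray, budget: float) -> Allocation:
    spend = float(data.c @ p)
    qalys = float(data.q @ p)
    binding = []
    scale = max(1.0, abs(budget)) if not math.isinf(budget) else 1.0
    if not math.isinf(budget) and spend >= budget - 1e-6 * scale:
        binding.append("budget")
    for row, cap, code in zip(data.cap_rows, data.cap_rhs, data.cap_codes):
        if row @ p >= cap - 1e-6 * max(1.0, cap):
            binding.append(f"cap:{code}")
    for i, code in enumerate(data.codes):
        if p[i] >= data.dem[i] - 1e-6 * max(1.0, data.dem[i]) and data.dem[i] > 0:
            binding.append(f"dem:{code}")
    return Allocation(
        participants=pd.Series(p, index=data.codes),
        budget=budget,
        spend=spend,
        total_qalys=qalys,
        status="optimal",
        binding=binding,
    )


def max_health_min_cost(problem: AllocationProblem) -> Allocation:
    """Lexicographic solve: maximise QALYs with unlimited budget, then
    minimise spend among QALY-optimal allocations.  Defines the right
    endpoint of the efficiency frontier (maximal useful budget, maximal
    health)."""
    return solve_allocation(problem, None)


def shadow_prices(problem: AllocationProblem, budget: float | None) -> ShadowPriceReport:
    """Constraint duals at the optimum: QALYs per extra euro of budget, per
    extra unit of program capacity, per extra person of cell demand."""
    data = _LPData.build(problem)
    has_budget = budget is not None and not math.isinf(budget)
    bounds = [(0.0, d) for d in data.dem]
    A, rhs = _stack(data, budget if has_budget else None)
    res = _run_lp(-data.q, A, rhs, bounds)
    if res.status != 0:
        raise SolverError(f"LP failed: {res.message} (status {res.status})")

    marg = res.ineqlin.marginals  # d(min obj)/d rhs, <= 0 for a max problem
    k = 0
    budget_price = 0.0
    if has_budget:
        budget_price = -float(marg[0])
        k = 1
    capacity_price = {
        code: -float(marg[k + i]) for i, code in enumerate(data.cap_codes)
    }
    demand_price = {
        code: -float(res.upper.marginals[i]) for i, code in enumerate(data.codes)
    }

    # primal degeneracy: more tight constraints than variables at the vertex
    p = res.x
    tight = 0
    for row, b in zip(A, rhs):
        if row @ p >= b - 1e-7 * max(1.0, abs(b)):
            tight += 1
    for i in range(data.n):
        if p[i] <= 1e-7 * max(1.0, data.dem[i]):
            tight += 1
        if p[i] >= data.dem[i] - 1e-7 * max(1.0, data.dem[i]):
            tight += 1
    return ShadowPriceReport(
        budget_price=budget_price,
        capacity_price=capacity_price,
        demand_price=demand_price,
        degenerate=tight > data.n,
    )


# ---------------------------------------------------------------------------
# Independent verification routes
# ---------------------------------------------------------------------------

_ORACLE_MAX_PROGRAMS = 3
_ORACLE_MAX_AGES = 2


def oracle_solve(problem: AllocationProblem, budget: float | None) -> Allocation:
    """Exact optimum of a small instance by enumerating all basic feasible
    solutions (every choice of n active constraints among the inequality rows
    and the variable bounds).  Guarded to <= 3 programs x 2 ages."""
    if len(problem.programs) > _ORACLE_MAX_PROGRAMS or len(problem.age_groups) > _ORACLE_MAX_AGES:
        raise OracleSizeError(
            f"oracle limited to {_ORACLE_MAX_PROGRAMS} programs x {_ORACLE_MAX_AGES} ages,"
            f" got {len(problem.programs)} x {len(problem.age_groups)}"
        )
    data = _LPData.build(problem)
    n = data.n
    has_budget = budget is not None and not math.isinf(budget)
    A, rhs = _stack(data, budget if has_budget else None)

    # constraint library: (normal vector, rhs) rows for A p <= b plus bounds
    normals: list[np.ndarray] = [row for row in A]
    offsets: list[float] = list(rhs)
    for i in range(n):
        e = np.zeros(n)
        e[i] = -1.0
        normals.append(e)  # -p_i <= 0
        offsets.append(0.0)
        e2 = np.zeros(n)
        e2[i] = 1.0
        normals.append(e2)  # p_i <= dem_i
        offsets.append(data.dem[i])

    best_p = None
    best_obj = -math.inf
    m = len(normals)
    N = np.array(normals)
    O = np.array(offsets)
    for combo in itertools.combinations(range(m), n):
        M = N[list(combo)]
        b = O[list(combo)]
        try:
            p = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(p)):
            continue
        slack = N @ p - O
        if np.any(slack > 1e-7 * np.maximum(1.0, np.abs(O))):
            continue
        obj = float(data.q @ p)
        if best_p is None or obj > best_obj:
            best_obj = obj
            best_p = p
    if best_p is None:
        return Allocation(
            participants=pd.Series(np.full(n, np.nan), index=data.codes),
            budget=float(budget) if has_budget else math.inf,
            spend=math.nan, total_qalys=math.nan, status="infeasible",
        )
    p = np.clip(best_p, 0.0, data.dem)
    return _package(problem, data, p, float(budget) if has_budget else math.inf)


def greedy_solve(problem: AllocationProblem, budget: float) -> Allocation:
    """Continuous-knapsack solution for the capacity-free special case: fund
    cells in ascending c/q order up to demand until the budget is exhausted,
    the last cell fractionally.  Provably optimal for the single-resource
    box-constrained LP; ties broken by (program code, age id)."""
    for pid, cap in problem.capacities.items():
        if not math.isinf(cap):
            raise ValueError(
                "greedy_solve requires all capacities unbounded; use"
                " solve_allocation for capacity-constrained problems"
            )
    data = _LPData.build(problem)
    if np.any(data.q <= 0) or np.any(data.c <= 0):
        raise ValueError(
            "greedy_solve requires all q > 0 and c > 0; use solve_allocation"
        )
    if budget < 0:
        raise ValueError("greedy_solve requires budget >= 0")
    order = sorted(range(data.n), key=lambda i: (data.c[i] / data.q[i], data.codes[i]))
    p = np.zeros(data.n)
    remaining = float(budget)
    for i in order:
        if remaining <= 0:
            break
        take = min(data.dem[i], remaining / data.c[i])
        p[i] = take
        remaining -= take * data.c[i]
    return _package(problem, data, p, float(budget))
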