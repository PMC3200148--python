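"""Efficiency-frontier tracing and allocation summaries.

The value function V(b) of the allocation LP — maximal QALYs attainable at
budget b — is piecewise linear and concave in b.  Its breakpoints mark
changes in the optimal basis: interventions entering (and sometimes leaving)
the funded set.  Each linear segment's slope is the shadow price of the
budget there, and its reciprocal the incremental cost-effectiveness ratio
(ICER) of the health bought on that segment: the ICER sequence is strictly
increasing along the frontier.

Breakpoints are located by bisection on the budget dual, which changes value
only at breakpoints; segment slopes are then recomputed from the exact value
differences so that slopes, values and ICERs are mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allocator import (
    SUPPORT_TOL,
    Allocation,
    max_health_min_cost,
    shadow_prices,
    solve_allocation,
)
from .problem_model import GENERAL, AllocationProblem, round_to_hundred

#: relative width to which breakpoints are refined (fraction of the frontier's
#: maximal budget)
BREAKPOINT_REL_TOL = 1e-9
#: relative tolerance for deciding two budget duals are equal
SLOPE_REL_TOL = 1e-6


class FrontierError(RuntimeError):
    pass


@dataclass
class FrontierSegment:
    """One linear piece of the budget -> health value function."""

    b_lo: float
    b_hi: float
    slope: float  # QALY per euro
    icer: float  # euro per QALY (= 1/slope)
    entering: tuple[str, ...]  # cell codes newly funded at b_lo
    leaving: tuple[str, ...]  # cell codes defunded at b_lo
    funded: frozenset[str] = field(default_factory=frozenset)


@dataclass
class Frontier:
    """Piecewise-linear efficiency frontier with its full-implementation
    endpoint (maximal useful budget, maximal health)."""

    segments: list[FrontierSegment]
    endpoint: tuple[float, float]
    base_funded: frozenset[str] = field(default_factory=frozenset)
    _b: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    _v: np.ndarray = field(default_factory=lambda: np.array([0.0]))

    @property
    def breakpoints(self) -> np.ndarray:
        return self._b

    def value(self, budget: float) -> float:
        """Maximal QALYs attainable at ``budget`` (saturates beyond the
        endpoint)."""
        if budget < self._b[0] - 1e-9 * max(1.0, abs(self._b[0])):
            raise ValueError(f"budget {budget} below frontier start {self._b[0]}")
        return float(np.interp(min(budget, self._b[-1]), self._b, self._v))

    def segment_at(self, budget: float) -> FrontierSegment:
        """Segment containing ``budget``; an exact breakpoint belongs to the
        segment on its left."""
        if not self.segments:
            raise FrontierError("frontier has no segments")
        b = min(budget, self.endpoint[0])
        for seg in self.segments:
            if seg.b_lo < b <= seg.b_hi:
                return seg
        return self.segments[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "b_lo": s.b_lo,
                    "b_hi": s.b_hi,
                    "slope_qaly_per_euro": s.slope,
                    "icer_euro_per_qaly": s.icer,
                    "entering": " ".join(f"+{c}" for c in s.entering),
                    "leaving": " ".join(f"-{c}" for c in s.leaving),
                }
                for s in self.segments
            ]
        )


@dataclass
class AllocationSummary:
    """Budget-level report row: how much is spent/gained in the general
    population, and the incremental cost per QALY at that budget."""

    budget: float
    spend: float
    total_qalys: float
    pct_spend_general: float | None  # None when spend is 0 (undefined)
    pct_qaly_general: float | None
    icer: float | None
    entering: tuple[str, ...] = ()
    leaving: tuple[str, ...] = ()
    saturated: bool = False

    def to_dict(self) -> dict:
        return {
            "budget": self.budget,
            "spend": self.spend,
            "total_qalys": self.total_qalys,
            "pct_spend_general": self.pct_spend_general,
            "pct_qaly_general": self.pct_qaly_general,
            "icer": self.icer,
            "entering": " ".join(f"+{c}" for c in self.entering),
            "leaving": " ".join(f"-{c}" for c in self.leaving),
            "saturated": self.saturated,
        }


def _slope(problem: AllocationProblem, budget: float) -> float:
    return shadow_prices(problem, budget).budget_price


def _slopes_differ(s1: float, s2: float) -> bool:
    scale = max(abs(s1), abs(s2))
    return scale > 0 and abs(s1 - s2) > SLOPE_REL_TOL * scale


def trace_frontier(problem: AllocationProblem) -> Frontier:
    """Trace the full efficiency frontier from b = 0 to the
    full-implementation endpoint."""
    end = max_health_min_cost(problem)
    b_max = end.spend
    if b_max <= 0:
        alloc0 = solve_allocation(problem, 0.0)
        return Frontier(
            segments=[],
            endpoint=(max(b_max, 0.0), end.total_qalys),
            base_funded=alloc0.funded_cells(),
            _b=np.array([0.0]),
            _v=np.array([alloc0.total_qalys]),
        )

    tol = BREAKPOINT_REL_TOL * max(1.0, b_max)
    s_lo = _slope(problem, 0.0)
    s_hi = _slope(problem, b_max)
    breakpoints: list[float] = []
    stack = [(0.0, b_max, s_lo, s_hi)]
    while stack:
        lo, hi, slo, shi = stack.pop()
        if not _slopes_differ(slo, shi):
            continue
        if hi - lo <= tol:
            breakpoints.append(0.5 * (lo + hi))
            continue
        mid = 0.5 * (lo + hi)
        smid = _slope(problem, mid)
        stack.append((lo, mid, slo, smid))
        stack.append((mid, hi, smid, shi))
    breakpoints.sort()

    # deduplicate near-coincident breakpoints
    bps: list[float] = []
    for b in breakpoints:
        if not bps or b - bps[-1] > tol:
            bps.append(b)

    grid = np.array([0.0] + bps + [b_max])
    values = np.array([solve_allocation(problem, b).total_qalys for b in grid])

    alloc0 = solve_allocation(problem, 0.0)
    base_funded = alloc0.funded_cells()
    segments: list[FrontierSegment] = []
    prev_funded = base_funded
    for i in range(len(grid) - 1):
        b_lo, b_hi = float(grid[i]), float(grid[i + 1])
        if b_hi - b_lo <= tol:
            continue
        slope = (values[i + 1] - values[i]) / (b_hi - b_lo)
        if slope <= 0:
            continue  # flat tail: budget no longer buys health
        mid_alloc = solve_allocation(problem, 0.5 * (b_lo + b_hi))
        funded = mid_alloc.funded_cells()
        entering = tuple(sorted(funded - prev_funded))
        leaving = tuple(sorted(prev_funded - funded))
        segments.append(
            FrontierSegment(
                b_lo=b_lo,
                b_hi=b_hi,
                slope=slope,
                icer=1.0 / slope,
                entering=entering,
                leaving=leaving,
                funded=funded,
            )
        )
        prev_funded = funded

    # merge consecutive segments whose slopes agree (no basis change between)
    merged: list[FrontierSegment] = []
    for seg in segments:
        if merged and not _slopes_differ(merged[-1].slope, seg.slope):
            prev = merged[-1]
            merged[-1] = FrontierSegment(
                b_lo=prev.b_lo,
                b_hi=seg.b_hi,
                slope=(prev.slope * (prev.b_hi - prev.b_lo) + seg.slope * (seg.b_hi - seg.b_lo))
                / (seg.b_hi - prev.b_lo),
                icer=prev.icer,
                entering=prev.entering,
                leaving=prev.leaving,
                funded=seg.funded,
            )
        else:
            merged.append(seg)

    return Frontier(
        segments=merged,
        endpoint=(b_max, end.total_qalys),
        base_funded=base_funded,
        _b=grid,
        _v=values,
    )


def _population_split(problem: AllocationProblem, alloc: Allocation) -> tuple[
    float | None, float | None
]:
    df = alloc.to_frame(problem)
    total_spend = df["spend"].sum()
    total_q = df["qalys"].sum()
    gen = df[df["population"] == GENERAL]
    pct_spend = None if total_spend <= 0 else 100.0 * gen["spend"].sum() / total_spend
    pct_q = None if total_q <= 0 else 100.0 * gen["qalys"].sum() / total_q
    return pct_spend, pct_q


def summarize_allocation(
    problem: AllocationProblem,
    budget: float,
    reference_budget: float | None = None,
    frontier: Frontier | None = None,
) -> AllocationSummary:
    """Allocation report at one budget: % spent / % gained in the general
    population, total QALYs, the ICER of the frontier segment containing the
    budget, and interventions entering/leaving relative to an optional
    reference budget.  Budgets beyond the frontier endpoint saturate."""
    if budget < 0:
        raise ValueError("budget must be >= 0")
    if frontier is None:
        frontier = trace_frontier(problem)
    b_max = frontier.endpoint[0]
    saturated = budget > b_max
    eff_budget = min(budget, b_max)
    alloc = solve_allocation(problem, eff_budget)
    pct_spend, pct_q = _population_split(problem, alloc)

    icer = None
    if frontier.segments and eff_budget > 0:
        icer = frontier.segment_at(eff_budget).icer

    entering: tuple[str, ...] = ()
    leaving: tuple[str, ...] = ()
    if reference_budget is not None:
        ref = solve_allocation(problem, min(reference_budget, b_max))
        funded = alloc.funded_cells()
        ref_funded = ref.funded_cells()
        entering = tuple(sorted(funded - ref_funded))
        leaving = tuple(sorted(ref_funded - funded))

    return AllocationSummary(
        budget=budget,
        spend=alloc.spend,
        total_qalys=alloc.total_qalys,
        pct_spend_general=pct_spend,
        pct_qaly_general=pct_q,
        icer=icer,
        entering=entering,
        leaving=leaving,
        saturated=saturated,
    )


@dataclass(frozen=True)
class EndpointCER:
    """Average cost-effectiveness of full implementation: endpoint spend
    divided by endpoint QALYs, raw and rounded to the nearest 100 euro."""

    spend: float
    qalys: float
    raw: float
    rounded: float


def endpoint_average_cer(spend: float, qalys: float) -> EndpointCER:
    """Average CER arithmetic for a given frontier endpoint."""
    if qalys <= 0:
        raise ValueError("endpoint average CER undefined: QALYs must be > 0")
    raw = spend / qalys
    return EndpointCER(spend=spend, qalys=qalys, raw=raw, rounded=round_to_hundred(raw))


def average_cer_of_endpoint(problem: AllocationProblem) -> EndpointCER:
    """Average CER of the problem's own full-implementation endpoint."""
    end = max_health_min_cost(problem)
    return endpoint_average_cer(end.spend, end.total_qalys)


def budget_grid(frontier: Frontier, n: int = 25) -> np.ndarray:
    """Logarithmic reporting grid from the cheapest breakpoint scale up to
    the endpoint, plus all breakpoints (budgets span several orders of
    magnitude)."""
    b_max = frontier.endpoint[0]
    if b_max <= 0:
        return np.array([0.0])
    lo = max(b_max * 1e-4, min((s.b_hi for s in frontier.segments), default=b_max) * 0.1)
    log_grid = np.geomspace(lo, b_max, n)
    grid = np.unique(np.concatenate([[0.0], frontier.breakpoints, log_grid, [b_max]]))
    return grid[grid <= b_max]
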