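"""Sensitivity analyses: capacity removal, discount-rate and time-horizon
variants, as orchestrated frontier comparisons.

Capacity scenarios only relax constraints and can run on any static problem.
Discount and horizon scenarios change the per-participant outcomes (q, c)
themselves, so every cell must be re-simulated: they therefore require the
cohort-simulator configuration (:class:`~prevalloc.cohort.SyntheticStudy`),
not just a static problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import LIFETIME, DiscountSpec, SyntheticStudy
from .frontier import Frontier, trace_frontier
from .problem_model import AllocationProblem


class ScenarioError(ValueError):
    pass


class StaticProblemError(ScenarioError):
    """A discount/horizon scenario was requested on a static problem.

    Changing discount rates or the time horizon changes every cell's
    per-participant (q, c): they must be re-derived by re-running the cohort
    simulator, which a static problem does not carry.  Pass a
    :class:`SyntheticStudy` (or other cohort configuration) instead.
    """


@dataclass(frozen=True)
class Scenario:
    """One sensitivity scenario: capacity switch plus optional re-simulation
    settings (``discount=None`` keeps the source's base discounting and
    horizon)."""

    label: str
    capacities_active: bool = True
    discount: DiscountSpec | None = None

    @property
    def needs_resimulation(self) -> bool:
        return self.discount is not None


@dataclass
class ScenarioComparison:
    """Frontiers per scenario evaluated on one shared budget grid."""

    frontiers: dict[str, Frontier]
    grid: np.ndarray
    table: pd.DataFrame  # long format: scenario, budget, qalys, icer

    def values(self, label: str) -> np.ndarray:
        f = self.frontiers[label]
        return np.array([f.value(b) for b in self.grid])


def drop_capacities(problem: AllocationProblem) -> AllocationProblem:
    """Copy of a problem with every program capacity unbounded (the original
    is untouched); idempotent."""
    out = problem.copy()
    out.capacities = {p.id: math.inf for p in out.programs}
    return out


def _scenario_problem(
    source: AllocationProblem | SyntheticStudy, scenario: Scenario
) -> AllocationProblem:
    if isinstance(source, SyntheticStudy):
        problem = source.problem(scenario.discount)
    else:
        if scenario.needs_resimulation:
            raise StaticProblemError(
                f"scenario {scenario.label!r} varies discounting or the time"
                " horizon, which requires re-simulating every cell's (q, c):"
                " a static AllocationProblem only supports capacity scenarios."
                " Provide the cohort-simulator configuration (SyntheticStudy)."
            )
        problem = source.copy()
    if not scenario.capacities_active:
        problem = drop_capacities(problem)
    return problem


def scenario_frontiers(
    source: AllocationProblem | SyntheticStudy,
    scenarios: list[Scenario],
    grid_points: int = 25,
) -> ScenarioComparison:
    """One frontier per scenario, all evaluated on a shared budget grid (the
    union of every scenario's breakpoints plus a logarithmic grid), so that
    pointwise orderings between scenarios are well defined."""
    if not scenarios:
        raise ScenarioError("scenario list is empty")
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ScenarioError(f"scenario labels must be unique, got {labels}")

    frontiers = {s.label: trace_frontier(_scenario_problem(source, s)) for s in scenarios}

    b_max = max(f.endpoint[0] for f in frontiers.values())
    parts = [np.array([0.0]), np.array([b_max])]
    for f in frontiers.values():
        parts.append(np.asarray(f.breakpoints))
    if b_max > 0:
        parts.append(np.geomspace(max(b_max * 1e-4, 1.0), b_max, grid_points))
    grid = np.unique(np.concatenate(parts))
    grid = grid[(grid >= 0) & (grid <= b_max)]

    rows = []
    for label, f in frontiers.items():
        for b in grid:
            icer = None
            if f.segments and 0 < b:
                icer = f.segment_at(min(b, f.endpoint[0])).icer
            rows.append(
                {"scenario": label, "budget": float(b), "qalys": f.value(float(b)), "icer": icer}
            )
    return ScenarioComparison(frontiers=frontiers, grid=grid, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------


def capacity_preset() -> list[Scenario]:
    """Model with versus without capacity constraints."""
    return [
        Scenario("with capacity constraints", capacities_active=True),
        Scenario("without capacity constraints", capacities_active=False),
    ]


def discount_preset(horizon: float | str = LIFETIME) -> list[Scenario]:
    """The standard discount-rate variants: 0%/0%, the Dutch-standard base
    case (health 1.5%, costs 4%), 4%/4%, and the health-at-0% variant."""
    return [
        Scenario("discount 0%/0%", discount=DiscountSpec(0.0, 0.0, horizon)),
        Scenario("base case 1.5%/4%", discount=DiscountSpec(0.015, 0.04, horizon)),
        Scenario("discount 4%/4%", discount=DiscountSpec(0.04, 0.04, horizon)),
        Scenario("health 0%, costs 4%", discount=DiscountSpec(0.0, 0.04, horizon)),
    ]


def horizon_preset(rate_health: float = 0.015, rate_cost: float = 0.04) -> list[Scenario]:
    """Time-horizon variants: 25 years, 50 years, lifetime."""
    return [
        Scenario("horizon 25y", discount=DiscountSpec(rate_health, rate_cost, 25)),
        Scenario("horizon 50y", discount=DiscountSpec(rate_health, rate_cost, 50)),
        Scenario("lifetime", discount=DiscountSpec(rate_health, rate_cost, LIFETIME)),
    ]


PRESETS = {
    "capacity": capacity_preset,
    "discount": discount_preset,
    "horizon": horizon_preset,
}


def load_scenarios(path: str | Path) -> list[Scenario]:
    """Read scenarios from a YAML file: a list of mappings with keys
    ``label``, ``capacities_active``, and optionally ``rate_health``,
    ``rate_cost``, ``horizon`` (presence of any of the three triggers
    re-simulation)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list):
        raise ScenarioError(f"{path}: expected a YAML list of scenarios")
    out = []
    for item in doc:
        discount = None
        if any(k in item for k in ("rate_health", "rate_cost", "horizon")):
            discount = DiscountSpec(
                rate_health=item.get("rate_health", 0.015),
                rate_cost=item.get("rate_cost", 0.04),
                horizon=item.get("horizon", LIFETIME),
            )
        out.append(
            Scenario(
                label=item["label"],
                capacities_active=item.get("capacities_active", True),
                discount=discount,
            )
        )
    return out
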