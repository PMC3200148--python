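"""Simplified multi-state Markov cohort model and synthetic problem generator.

The allocation analysis needs only one number pair per program x age cell:
the lifetime-discounted QALY gain and net healthcare-cost change per
participant versus care as usual.  In the original study those came from a
large national chronic-disease simulation model whose inputs are not
reproducible here; this module provides a deliberately simplified stand-in
with the same qualitative behaviour:

* three states — ``well``, ``chronic``, ``dead`` — with age-dependent annual
  transition probabilities (Gompertz-type background mortality, rising chronic
  incidence, excess mortality in the chronic state);
* age-declining utility weights, so life-years gained late in life count less;
* annual care costs per state, so prevention that extends life also accrues
  care costs in the life-years gained;
* interventions as transient hazard multipliers (relapse / non-adherence is
  encoded as a finite effect duration) plus an annual fee for a finite number
  of years;
* differential discounting of health and costs.

The seeded generator assembles complete 12-program x 3-age allocation
problems whose average cost-effectiveness ratios are calibrated to a target
range, with disjoint general/diabetes target populations, smaller demand for
the diabetes group, and per-program capacity limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .problem_model import (
    CANONICAL_AGE_GROUPS,
    DIABETES,
    GENERAL,
    AgeGroup,
    AllocationProblem,
    Cell,
    Program,
)

WELL, CHRONIC, DEAD = 0, 1, 2

LIFETIME = "lifetime"

#: Occupancy threshold at which a "lifetime" simulation stops: the cohort is
#: considered extinct once dead-state occupancy reaches 1 - 1e-9.
EXTINCTION_TOL = 1e-9


class CalibrationError(RuntimeError):
    """The generator could not reach the requested CER range."""


class ModelInvariantError(ValueError):
    """A cohort model violates a structural invariant (e.g. non-stochastic
    transition matrix)."""


@dataclass(frozen=True)
class DiscountSpec:
    """Differential annual discounting of health and costs.

    Defaults follow the Dutch pharmacoeconomic guideline: 1.5%/year for
    health effects and 4%/year for costs.  ``horizon`` is a number of years
    or ``"lifetime"`` (simulate until the cohort is extinct or reaches the
    model's age cap).
    """

    rate_health: float = 0.015
    rate_cost: float = 0.04
    horizon: float | str = LIFETIME

    def __post_init__(self) -> None:
        if self.rate_health < 0 or self.rate_cost < 0:
            raise ValueError("discount rates must be >= 0")
        if self.horizon != LIFETIME and not self.horizon > 0:
            raise ValueError(f"horizon must be positive or 'lifetime', got {self.horizon!r}")

    @property
    def horizon_years(self) -> float:
        return math.inf if self.horizon == LIFETIME else float(self.horizon)


@dataclass(frozen=True)
class CohortModel:
    """Parametric three-state annual-cycle cohort model.

    Hazards are exponential in age (reference age 20): background mortality
    ``mortality_base * exp(mortality_growth * (age - 20))``, chronic incidence
    analogous, with a relative-risk multiplier on mortality in the chronic
    state.  Utilities decline linearly with age; annual care costs rise
    linearly with age, with a fixed excess in the chronic state.
    """

    mortality_base: float = 3.0e-4
    mortality_growth: float = 0.09
    incidence_base: float = 8.0e-4
    incidence_growth: float = 0.05
    chronic_mortality_rr: float = 2.5
    utility_well_at20: float = 0.95
    utility_slope: float = 0.0015  # utility lost per year of age
    chronic_utility_decrement: float = 0.15
    care_cost_well_at20: float = 800.0
    care_cost_slope: float = 25.0  # euro per year of age
    chronic_care_excess: float = 2500.0
    age_cap: float = 105.0
    ref_age: float = 20.0

    def transition_matrix(
        self, age: float, incidence_multiplier: float = 1.0, mortality_multiplier: float = 1.0
    ) -> np.ndarray:
        """Row-stochastic annual transition matrix at integer age.  The dead
        state is absorbing."""
        da = age - self.ref_age
        p_wd = self.mortality_base * math.exp(self.mortality_growth * da) * mortality_multiplier
        p_wc = self.incidence_base * math.exp(self.incidence_growth * da) * incidence_multiplier
        p_wd = min(max(p_wd, 0.0), 1.0)
        p_wc = min(max(p_wc, 0.0), 1.0)
        if p_wd + p_wc > 1.0:  # keep the row stochastic at extreme ages
            scale = 1.0 / (p_wd + p_wc)
            p_wd *= scale
            p_wc *= scale
        p_cd = min(
            max(self.chronic_mortality_rr * self.mortality_base
                * math.exp(self.mortality_growth * da), 0.0),
            1.0,
        )
        P = np.array(
            [
                [1.0 - p_wc - p_wd, p_wc, p_wd],
                [0.0, 1.0 - p_cd, p_cd],
                [0.0, 0.0, 1.0],
            ]
        )
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ModelInvariantError(f"transition matrix rows do not sum to 1 at age {age}")
        if (P < -1e-15).any() or (P > 1.0 + 1e-15).any():
            raise ModelInvariantError(f"transition probabilities outside [0, 1] at age {age}")
        return P

    def utilities(self, age: float) -> np.ndarray:
        u_well = self.utility_well_at20 - self.utility_slope * (age - self.ref_age)
        u_well = min(max(u_well, 0.0), 1.0)
        u_chronic = min(max(u_well - self.chronic_utility_decrement, 0.0), 1.0)
        return np.array([u_well, u_chronic, 0.0])

    def care_costs(self, age: float) -> np.ndarray:
        base = max(self.care_cost_well_at20 + self.care_cost_slope * (age - self.ref_age), 0.0)
        return np.array([base, base + self.chronic_care_excess, 0.0])

    def validate(self, ages: Iterable[float] | None = None) -> None:
        """Raise :class:`ModelInvariantError` if any invariant fails on an
        age grid (default: ref_age .. age_cap)."""
        if ages is None:
            ages = np.arange(self.ref_age, self.age_cap + 1.0)
        prev_u = None
        for age in ages:
            self.transition_matrix(age)
            u = self.utilities(age)
            if (u < 0).any() or (u > 1).any():
                raise ModelInvariantError(f"utilities outside [0, 1] at age {age}")
            if prev_u is not None and u[WELL] > prev_u + 1e-12:
                raise ModelInvariantError("utility must not increase with age")
            prev_u = u[WELL]


EffectTarget = Literal["incidence", "mortality"]


@dataclass(frozen=True)
class InterventionEffect:
    """A preventive intervention as seen by the cohort model.

    ``hazard_multiplier`` scales the well->chronic and/or well->dead annual
    probabilities (targets selectable) for ``effect_duration`` years, after
    which it reverts to 1 — a crude encoding of relapse and non-adherence.
    ``annual_intervention_cost`` is charged at each cycle start, per
    participant still alive, for ``cost_duration`` years.
    """

    hazard_multiplier: float = 1.0
    targets: tuple[EffectTarget, ...] = ("incidence", "mortality")
    effect_duration: float = math.inf
    annual_intervention_cost: float = 0.0
    cost_duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.hazard_multiplier > 0:
            raise ValueError("hazard_multiplier must be > 0")
        if self.effect_duration < 0 or self.cost_duration < 0:
            raise ValueError("durations must be >= 0")
        for t in self.targets:
            if t not in ("incidence", "mortality"):
                raise ValueError(f"unknown effect target {t!r}")


@dataclass(frozen=True)
class CohortOutcome:
    """Discounted per-participant totals from one cohort run."""

    qalys: float
    care_costs: float
    intervention_costs: float

    @property
    def costs(self) -> float:
        return self.care_costs + self.intervention_costs


def npv(stream: Sequence[float], rate: float, start_year: int = 1) -> float:
    """Net present value of an annual stream.

    ``stream[i]`` occurs at the end of year ``start_year + i``; with the
    default ``start_year=1`` the first element is discounted one year.  Pass
    ``start_year=0`` for streams whose first amount falls due immediately
    (undiscounted).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    total = 0.0
    for i, amount in enumerate(stream):
        t = start_year + i
        total += amount / (1.0 + rate) ** t
    return total


def simulate_cohort(
    model: CohortModel,
    effect: InterventionEffect | None,
    start_age: float,
    discount: DiscountSpec,
    *,
    half_cycle: bool = True,
    initial: Sequence[float] = (1.0, 0.0, 0.0),
) -> CohortOutcome:
    """Deterministic (expected-value) cohort simulation with annual cycles.

    QALYs and care costs use a half-cycle correction by default (state
    occupancy averaged over cycle start and end); with ``half_cycle=False``
    they accrue on end-of-cycle occupancy.  Either way, the accrual of cycle
    ``t`` is discounted by ``(1+r)^-t`` while intervention fees, charged at
    cycle start, are discounted by ``(1+r)^-(t-1)``.

    A lifetime horizon runs until dead-state occupancy reaches ``1 - 1e-9``
    or the cohort ages past ``model.age_cap``.
    """
    if not model.ref_age <= start_age <= model.age_cap:
        raise ValueError(
            f"start_age {start_age} outside model age range"
            f" [{model.ref_age}, {model.age_cap}]"
        )
    x = np.asarray(initial, dtype=float)
    if x.shape != (3,) or abs(x.sum() - 1.0) > 1e-12 or (x < 0).any():
        raise ValueError("initial occupancy must be a distribution over 3 states")

    eff = effect or InterventionEffect()
    horizon = discount.horizon_years
    rh, rc = discount.rate_health, discount.rate_cost

    qalys = 0.0
    care = 0.0
    fees = 0.0
    t = 1
    while t <= horizon:
        age = start_age + (t - 1)
        if age >= model.age_cap:
            break
        active = t <= eff.effect_duration
        inc_m = eff.hazard_multiplier if active and "incidence" in eff.targets else 1.0
        mort_m = eff.hazard_multiplier if active and "mortality" in eff.targets else 1.0
        P = model.transition_matrix(age, inc_m, mort_m)
        x_next = x @ P
        occ = 0.5 * (x + x_next) if half_cycle else x_next
        qalys += float(occ @ model.utilities(age)) / (1.0 + rh) ** t
        care += float(occ @ model.care_costs(age)) / (1.0 + rc) ** t
        if t <= eff.cost_duration:
            alive = float(x[WELL] + x[CHRONIC])
            fees += eff.annual_intervention_cost * alive / (1.0 + rc) ** (t - 1)
        x = x_next
        if horizon == math.inf and x[DEAD] >= 1.0 - EXTINCTION_TOL:
            break
        t += 1
    return CohortOutcome(qalys=qalys, care_costs=care, intervention_costs=fees)


def evaluate_cell(
    model: CohortModel,
    effect: InterventionEffect | None,
    start_age: float,
    discount: DiscountSpec,
    *,
    half_cycle: bool = True,
) -> tuple[float, float]:
    """Per-participant cell outcomes (q, c) versus usual care.

    q is the discounted QALY difference; c is the discounted intervention
    cost plus the full long-term change in care costs — including care costs
    accrued in life-years gained.
    """
    base = simulate_cohort(model, None, start_age, discount, half_cycle=half_cycle)
    treated = simulate_cohort(model, effect, start_age, discount, half_cycle=half_cycle)
    q = treated.qalys - base.qalys
    c = treated.costs - base.care_costs
    return q, c


# ---------------------------------------------------------------------------
# Closed forms used as independent oracles in the test-suite
# ---------------------------------------------------------------------------


def geometric_life_years(survival: float, rate: float, *, half_cycle: bool) -> float:
    """Discounted life expectancy of a two-state (alive/dead) cohort with
    constant annual survival probability ``s`` and utility 1.

    End-of-cycle accrual gives the geometric series sum_{t>=1} s^t/(1+r)^t =
    x/(1-x) with x = s/(1+r); half-cycle accrual replaces s^t by
    (s^{t-1}+s^t)/2, giving (1+s)/(2(1+r)) / (1-x).
    """
    x = survival / (1.0 + rate)
    if x >= 1.0:
        raise ValueError("series diverges: survival/(1+rate) must be < 1")
    if half_cycle:
        return (1.0 + survival) / (2.0 * (1.0 + rate)) / (1.0 - x)
    return x / (1.0 - x)


def two_state_model(annual_survival: float) -> CohortModel:
    """Degenerate cohort model with no chronic state: constant mortality
    hazard ``1 - s``, utility 1, zero care costs, effectively no age cap."""
    return CohortModel(
        mortality_base=1.0 - annual_survival,
        mortality_growth=0.0,
        incidence_base=0.0,
        incidence_growth=0.0,
        chronic_mortality_rr=1.0,
        utility_well_at20=1.0,
        utility_slope=0.0,
        chronic_utility_decrement=0.0,
        care_cost_well_at20=0.0,
        care_cost_slope=0.0,
        chronic_care_excess=0.0,
        age_cap=1.0e7,
    )


# ---------------------------------------------------------------------------
# Synthetic study generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """A fully specified synthetic study: cohort models, intervention
    effects, demands and capacities, from which an
    :class:`AllocationProblem` can be derived under any discounting/horizon
    assumption (needed for the sensitivity analyses, which re-simulate every
    cell)."""

    programs: list[Program]
    age_groups: list[AgeGroup]
    models: dict[str, CohortModel]  # population tag -> model
    effects: dict[tuple[int, int], InterventionEffect]  # (program_id, age_id)
    demands: dict[tuple[int, int], float]
    capacities: dict[int, float]
    base_discount: DiscountSpec = field(default_factory=DiscountSpec)
    meta: dict = field(default_factory=dict)

    def problem(self, discount: DiscountSpec | None = None) -> AllocationProblem:
        """Evaluate every cell under ``discount`` (default: the study's base
        discounting) and assemble the allocation problem."""
        disc = discount or self.base_discount
        cells = []
        for prog in self.programs:
            model = self.models[prog.population]
            for age in self.age_groups:
                key = (prog.id, age.id)
                q, c = evaluate_cell(model, self.effects[key], age.start_age, disc)
                cells.append(
                    Cell(
                        program_id=prog.id,
                        age_id=age.id,
                        qaly_per_participant=q,
                        cost_per_participant=c,
                        demand=self.demands[key],
                    )
                )
        meta = dict(self.meta)
        meta.update(
            {
                "discount_rate_health": disc.rate_health,
                "discount_rate_cost": disc.rate_cost,
                "horizon": disc.horizon,
            }
        )
        return AllocationProblem(
            programs=list(self.programs),
            age_groups=list(self.age_groups),
            cells=cells,
            capacities=dict(self.capacities),
            meta=meta,
        )


#: The diabetes population is modelled as a high-risk variant of the general
#: population: higher chronic incidence and background mortality, higher care
#: costs.  Fixed multipliers, not seeded.
_DIABETES_SCALING = {
    "mortality_base": 1.8,
    "incidence_base": 2.5,
    "chronic_care_excess": 1.2,
}

_CALIBRATION_TRIES = 25


def _diabetes_model(base: CohortModel) -> CohortModel:
    return replace(
        base,
        mortality_base=base.mortality_base * _DIABETES_SCALING["mortality_base"],
        incidence_base=base.incidence_base * _DIABETES_SCALING["incidence_base"],
        chronic_care_excess=base.chronic_care_excess * _DIABETES_SCALING["chronic_care_excess"],
    )


def generate_study(
    seed: int,
    n_programs: int = 12,
    n_ages: int = 3,
    cer_range: tuple[float, float] = (1400.0, 59600.0),
    capacity_tightness: float = 0.6,
    discount: DiscountSpec | None = None,
) -> SyntheticStudy:
    """Seeded generator of a complete synthetic study.

    Half the programs target the general population, half the (much smaller)
    diabetes population.  Each cell receives a log-uniform target average CER
    within ``cer_range``; because per-cell cost is affine in the annual
    intervention fee, the fee solving ``(c0 + fee*F)/q = target`` is computed
    exactly from two cohort runs, so every generated cell's average CER hits
    its target.  Intervention effects act on chronic incidence (prevention
    averts disease rather than death directly), which keeps the zero-fee cost
    ``c0`` below the cheapest target; if a draw still cannot be calibrated
    within a bounded number of redraws a :class:`CalibrationError` is raised.
    """
    if n_programs % 2 != 0:
        raise ValueError("n_programs must be even (half general, half diabetes)")
    if not 0 < capacity_tightness <= 1:
        raise ValueError("capacity_tightness must be in (0, 1]")
    lo, hi = cer_range
    if not 0 < lo < hi:
        raise ValueError(f"invalid cer_range {cer_range}")
    disc = discount or DiscountSpec()

    rng = np.random.default_rng(seed)
    base_model = CohortModel()
    models = {GENERAL: base_model, DIABETES: _diabetes_model(base_model)}

    age_groups = [AgeGroup(i, lab, s) for i, lab, s in CANONICAL_AGE_GROUPS[:n_ages]]
    programs = []
    for k in range(n_programs):
        pop = GENERAL if k < n_programs // 2 else DIABETES
        idx = k + 1 if pop == GENERAL else k + 1 - n_programs // 2
        code = f"{'G' if pop == GENERAL else 'D'}{idx:02d}"
        title = f"Synthetic {'general-population' if pop == GENERAL else 'diabetes'} program {idx}"
        programs.append(Program(id=k + 1, code=code, title=title, population=pop))

    effects: dict[tuple[int, int], InterventionEffect] = {}
    demands: dict[tuple[int, int], float] = {}
    for prog in programs:
        model = models[prog.population]
        for age in age_groups:
            key = (prog.id, age.id)
            target = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            effects[key] = _calibrate_effect(model, age.start_age, disc, target, rng)
            if prog.population == GENERAL:
                demands[key] = float(rng.uniform(150e3, 600e3))
            else:
                demands[key] = float(rng.uniform(15e3, 60e3))

    capacities = {
        prog.id: capacity_tightness * sum(demands[(prog.id, a.id)] for a in age_groups)
        for prog in programs
    }

    return SyntheticStudy(
        programs=programs,
        age_groups=age_groups,
        models=models,
        effects=effects,
        demands=demands,
        capacities=capacities,
        base_discount=disc,
        meta={
            "generator_seed": int(seed),
            "n_programs": n_programs,
            "n_ages": n_ages,
            "cer_range": list(cer_range),
            "capacity_tightness": capacity_tightness,
            "currency": "EUR, price level 2007",
            "general_demand_net_of_diabetes": True,
            "reference_population": 16_400_000,
            "source": "synthetic cohort-simulator generator",
        },
    )


def _calibrate_effect(
    model: CohortModel,
    start_age: float,
    discount: DiscountSpec,
    target_cer: float,
    rng: np.random.Generator,
) -> InterventionEffect:
    """Draw effect strength/durations, then solve the annual fee so that the
    cell's average CER equals ``target_cer`` exactly (cost is affine in the
    fee)."""
    last = None
    for _ in range(_CALIBRATION_TRIES):
        mult = float(rng.uniform(0.85, 0.96))
        eff_dur = int(rng.integers(8, 21))
        cost_dur = int(rng.integers(3, 11))
        proto = InterventionEffect(
            hazard_multiplier=mult,
            targets=("incidence",),
            effect_duration=eff_dur,
            annual_intervention_cost=0.0,
            cost_duration=cost_dur,
        )
        q, c0 = evaluate_cell(model, proto, start_age, discount)
        if q <= 0:
            last = f"non-positive health gain (q={q:.3g})"
            continue
        _, c1 = evaluate_cell(
            model, replace(proto, annual_intervention_cost=1.0), start_age, discount
        )
        fee_factor = c1 - c0  # discounted alive-weighted fee-years
        fee = (target_cer * q - c0) / fee_factor
        if fee < 0:
            last = f"target {target_cer:.0f} below zero-fee ratio {c0 / q:.0f}"
            continue
        return replace(proto, annual_intervention_cost=fee)
    raise CalibrationError(
        f"could not calibrate a cell to CER {target_cer:.0f} within"
        f" {_CALIBRATION_TRIES} draws (last failure: {last})"
    )


def generate_problem(
    seed: int,
    n_programs: int = 12,
    n_ages: int = 3,
    cer_range: tuple[float, float] = (1400.0, 59600.0),
    capacity_tightness: float = 0.6,
    discount: DiscountSpec | None = None,
) -> AllocationProblem:
    """Seeded synthetic :class:`AllocationProblem` (see
    :func:`generate_study`); deterministic field-by-field for a given seed."""
    return generate_study(
        seed,
        n_programs=n_programs,
        n_ages=n_ages,
        cer_range=cer_range,
        capacity_tightness=capacity_tightness,
        discount=discount,
    ).problem()
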