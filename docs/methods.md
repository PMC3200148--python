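# Methods

This note documents the models, numerical choices and limitations of
`prevalloc` in the order the pipeline uses them: the allocation LP, the
frontier tracer, the cohort simulator and its synthetic-study generator, and
the sensitivity machinery.

## The allocation model

The decision problem is a linear program over continuous participant numbers
`p_ja` (program `j`, age group `a`): maximise total discounted QALYs
`Σ p_ja q_ja` subject to a budget constraint on total discounted net cost
`Σ p_ja c_ja ≤ b`, per-program capacity constraints `Σ_a p_ja ≤ cap_j`
(professional supply, pooled over ages), and demand boxes
`0 ≤ p_ja ≤ dem_ja` (size of the eligible group, per age). Key modelling
conventions:

- **Continuous participants.** Target groups can be funded fractionally;
  the indivisible-program variant is an integer program and out of scope.
- **Costs are lifetime net costs**, intervention fees plus the full
  downstream effect on healthcare costs, including care costs in life-years
  gained. Cost-saving cells (`c < 0`, `q > 0`) are legitimate inputs: they
  enter the optimal solution at any budget and effectively enlarge it.
  Dominated cells (`q ≤ 0`) are retained in problems but never funded, and
  are excluded from league tables.
- **Disjoint target populations.** Diabetes-specific programs take priority
  where target groups overlap, so demand figures for general-population
  programs must be net of diabetes patients; `validate_problem` asserts the
  corresponding metadata flag on mixed problems.

### Solving and determinism

`solve_allocation` runs HiGHS (via `scipy.optimize.linprog`) three times,
lexicographically: (1) maximise QALYs; (2) minimise spend among QALY-optimal
allocations; (3) break remaining ties toward lexicographically earlier cells
(program code, then youngest age first). Stages 2–3 operate on the optimal
face identified by complementary slackness: inequality rows with nonzero
duals become equalities and variables with nonzero reduced costs are fixed
at their bounds. This is numerically far more robust than pinning the float
objective value with an equality constraint. Two guards matter:

- duals below `1e-11` are treated as zero when identifying the face;
- retained inequality rows get a `1e-9` relative slack in later stages (the
  restriction already pins optimality; the slack absorbs float-summation
  mismatch when many variables sit at bounds), and when a budget lies a
  float-width above a breakpoint — where the face is hair-thin and the
  optimum essentially unique — a rejected refinement stage falls back to the
  previous stage's vertex.

Solutions are clipped to `[0, dem]` after solving. Shadow prices
(QALY per extra euro of budget, per extra unit of capacity, per extra person
of demand) are the stage-1 duals; primal degeneracy (more tight constraints
than variables) is flagged because duals are then non-unique, and the
reported values are one valid dual vector rather than a resolved choice.

### Verification routes

Two independent solvers check the LP path. `oracle_solve` enumerates every
choice of `n` active constraints among the inequality rows and variable
bounds (all basic solutions), keeps the feasible ones and returns the best —
exact, and guarded to ≤ 3 programs × 2 ages where the enumeration is cheap.
`greedy_solve` implements the continuous-knapsack argument for the
capacity-free case: fund cells in ascending `c/q` order up to demand, the
last one fractionally; this is provably optimal for a single resource with
box constraints. The test-suite holds the LP to the oracle (1e-6 relative)
and to the greedy solution (1e-9 relative) on seeded random instance
families.

## Frontier tracing

The value function `V(b)` is concave and piecewise linear, so its derivative
— the budget's shadow price — is a step function that changes only at
breakpoints. `trace_frontier` bisects on the budget dual between `b = 0` and
the full-implementation spend (from the lexicographic max-health/min-spend
solve), refining each breakpoint to relative width 1e-9. Segment slopes are
then recomputed from exact value differences between consecutive
breakpoints, so values, slopes and ICERs (`1/slope`) are mutually
consistent; duals at segment midpoints would serve equally but can be
degenerate exactly at breakpoints. Adjacent segments whose slopes agree to
1e-6 relative are merged; slope comparisons are relative because budget
duals are of order 1e-5 QALY/€ on realistic problems.

Entry/exit bookkeeping compares funded supports (participants > 1e-7) at
consecutive segment midpoints; the funded set is *not* assumed nested in the
budget — under a binding capacity, growing budgets can swap a cheap
low-gain age group out in favour of a costlier high-gain one, and such exits
are reported. At an exact breakpoint a budget belongs to the left segment.
Reporting budget grids are logarithmic by default because realistic budget
ranges span four orders of magnitude.

## The cohort simulator

The allocation model only needs per-cell `(q, c)`. The original study
derived these from a national multi-disease simulation model; this package
ships a deliberately simplified stand-in with three states — well, chronic,
dead — that preserves the qualitative economics:

- **Hazards** are exponential in age: background mortality
  `m0·exp(gm·(age−20))` (default `m0 = 3e-4`, `gm = 0.09`, i.e. doubling
  roughly every 8 years, a Gompertz-type schedule), chronic incidence
  `i0·exp(gi·(age−20))` (default `i0 = 8e-4`, `gi = 0.05`), and a
  relative risk of 2.5 on mortality in the chronic state.
- **Utilities decline with age** (0.95 at age 20, −0.0015/year; −0.15 in
  the chronic state), so life-years gained late in life count less.
- **Care costs rise with age** (€800/year at 20, +€25/year of age, +€2,500
  in the chronic state, euro 2007), so averted disease saves money while
  extended life costs money.
- **Interventions** multiply the well→chronic and/or well→dead hazards for a
  finite effect duration (relapse and non-adherence collapse into this
  horizon) and charge an annual fee, per participant alive, for a finite
  cost duration.

Cycles are annual. QALYs and care costs accrue on the average of start- and
end-of-cycle occupancy (half-cycle correction, the standard cohort-model
convention; an end-of-cycle variant is available via `half_cycle=False` and
both are held to their respective geometric closed forms on a two-state
model). Cycle-`t` accruals are discounted by `(1+r)^-t`; intervention fees
are charged at cycle start, hence discounted by `(1+r)^-(t-1)`. Health and
costs are discounted at separate rates, default 1.5%/year for health and
4%/year for costs per the Dutch pharmacoeconomic guideline. "Lifetime"
horizons run until dead-state occupancy reaches `1 − 1e-9` or age 105; that
extinction cutoff bounds the truncation error of discounted totals at well
below 1e-9 for any discounted setting.

### The synthetic-study generator

`generate_study(seed)` emulates the study design: 12 programs (half general
population, half diabetes) × 3 age groups with representative entry ages 32,
55 and 72 (mid-interval; 72 for the open-ended 65+ category). The diabetes
population is a high-risk variant of the base cohort model (incidence ×2.5,
background mortality ×1.8, chronic care excess ×1.2 — fixed constants).
Demand is drawn at 150k–600k persons per general-population cell and
15k–60k per diabetes cell, reflecting the much smaller diagnosed group;
capacity is `capacity_tightness × total demand` per program (default 0.6, so
capacity genuinely binds at large budgets).

Each cell receives a log-uniform target average CER in the published range
€1,400–€59,600 per QALY. Intervention effects act on **chronic incidence**
(hazard multiplier 0.85–0.96 for 8–20 years, fee for 3–10 years): averting
disease yields both QALYs and care-cost savings, which keeps the zero-fee
cost below the cheapest target so the annual fee solving
`(c0 + fee·F)/q = target` is non-negative. Because cost is affine in the
fee, the calibration is exact from two cohort runs per cell (the fee factor
`F` is the discounted alive-weighted fee-year count); a draw that cannot be
calibrated is redrawn up to 25 times before a `CalibrationError`. Generated
average CERs therefore sit inside the published range by construction, and
everything is deterministic per seed.

What the generator does **not** emulate: multi-disease competing risks,
risk-factor distributions, secular trends, overlap between interventions
(health effects are additive by assumption), or any estimate of a real
intervention's effect size. Tests passing on synthetic problems demonstrate
the correctness of the optimisation and sensitivity machinery and the
qualitative frontier economics — not the study's absolute numbers, whose
per-cell inputs are unpublished.

## Sensitivity analyses

Scenarios combine a capacity switch with optional re-simulation settings.
Capacity removal is a pure constraint relaxation and runs on any static
problem; discount-rate or horizon changes alter every `(q, c)` and therefore
require the cohort configuration (a `SyntheticStudy`), not a static problem —
requesting otherwise raises an explicit error. All scenario frontiers are
evaluated on one shared budget grid (union of every scenario's breakpoints
plus a log grid) so pointwise orderings are well defined. The shipped
presets mirror the standard variants: discounting 0%/0%, 1.5%/4% (base),
4%/4%, health-at-0%; horizons 25y/50y/lifetime; capacities on/off.

Expected orderings, asserted in the tests on the seeded study: removing
capacities moves the frontier weakly outward and strictly raises the
endpoint when a capacity binds there; longer horizons raise the frontier
(short horizons leave out late health gains); discounting both streams at
4% moves the frontier inward relative to the base case, discounting nothing
moves it outward.

## Known limitations

- Per-participant outcomes are means; no probabilistic sensitivity analysis
  or stochastic programming (deterministic inputs only).
- No equity weighting, no interaction effects between interventions, no
  integer (indivisible-program) variant.
- The packaged league table stores published ratios only; the companion
  demo problem fixes synthetic per-participant QALY gains (0.25/0.20/0.12 by
  age) and derives costs as `ratio × q`, so its ratios are faithful but its
  scale is illustrative.
- Reported percentages are rounded to integers in CSV outputs; raw values
  are retained in JSON.
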