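# prevalloc

Optimal allocation of a prevention budget over a portfolio of
cardiovascular/diabetes prevention programs.

## The problem

Cardiovascular prevention — smoking cessation support, lifestyle programs for
overweight, blood-pressure medication, statins — can be offered to the
general population or targeted at diagnosed diabetes patients, a high-risk
group that profits more per person but is an order of magnitude smaller.
Cost-effectiveness league tables rank interventions by their average cost per
QALY, but a ranking ignores *program size*: a program reaching 300,000 people
is worth something different from one reaching 30,000. Deciding how to split
a budget between universal and targeted prevention therefore needs a resource
allocation model, not just a league table.

`prevalloc` is a library plus analysis pipeline for exactly this decision.
It is aimed at health economists and HTA analysts who want to go from
per-participant cost-effectiveness evidence to budget-dependent optimal
intervention portfolios, with capacity constraints and sensitivity analyses.

## The model

With programs *j* = 1,…,12 and age groups *a* = 1,…,3, let *q<sub>ja</sub>*
and *c<sub>ja</sub>* be the lifetime-discounted QALY gain and net healthcare
cost per participant versus care as usual, *dem<sub>ja</sub>* the size of the
eligible target group, and *cap<sub>j</sub>* the professional supply limit of
program *j*. For a budget *b* the allocation LP chooses participant numbers
*p<sub>ja</sub>*:

```
max_p   Σ_j Σ_a p_ja q_ja
s.t.    Σ_j Σ_a p_ja c_ja ≤ b          (budget)
        Σ_a p_ja ≤ cap_j   for all j   (capacity)
        0 ≤ p_ja ≤ dem_ja  for all j,a (demand)
```

Sweeping *b* traces the **efficiency frontier**: a concave piecewise-linear
budget→health value function whose segment slopes are the budget's shadow
prices and whose reciprocal slopes are incremental cost-effectiveness ratios
(ICERs), strictly increasing along the frontier. Corner points mark
interventions entering — and sometimes leaving — the optimal set.

The package contains:

- `problem_model` — domain types, CSV/JSON readers/writers, the packaged
  36-row league table of published average cost-per-QALY ratios, and
  league-table operations (ranking, band counts);
- `cohort` — a simplified three-state (well/chronic/dead) annual-cycle Markov
  cohort simulator producing per-participant discounted (q, c) versus usual
  care, and a seeded generator of complete synthetic allocation problems
  calibrated to the published CER range;
- `allocator` — the LP solver (lexicographic max-QALY / min-spend /
  deterministic tie-break), an exact enumeration oracle for small instances,
  the greedy continuous-knapsack solver for the capacity-free case, and
  constraint shadow prices;
- `frontier` — frontier tracing via bisection on the budget dual, segment
  ICERs, entry/exit bookkeeping, and allocation summaries (% spent/gained in
  the general population);
- `sensitivity` — capacity-removal, discount-rate and time-horizon scenario
  comparisons on a shared budget grid;
- `cli` — a `prevalloc` command with `league-table`, `optimize`,
  `sensitivity` and `generate` subcommands.

## Worked example

```python
>>> import prevalloc as pv
>>> table = pv.load_league_table()
>>> ranked = pv.rank_by_cer(table)
>>> ranked.rows[0].code, ranked.rows[0].average_cer
('S1', 1400.0)
>>> pv.count_by_cer_band(table, 0, 10_000), pv.count_by_cer_band(table, 0, 10_000, "diabetes")
(17, 11)
>>> pv.endpoint_average_cer(7_253e6, 561_000).rounded   # full implementation
12900.0
```

Minimal GP smoking-cessation counseling for 20–44-year-olds (`S1`) is the
most cost-effective intervention at €1,400 per QALY; 17 of the 36
intervention × age cells cost less than €10,000 per QALY and 11 of those
target diabetes patients. Funding everything costs about €12,900 per QALY on
average.

The analysis pipeline runs on the synthetic study (seed 1):

```
$ python analysis/03_trace_frontier.py
frontier (seed 1): 42 segments
  endpoint with capacities   : EUR 3,146M -> 181,707 QALYs (EUR 17,300/QALY on average)
  endpoint without capacities: EUR 3,943M -> 228,569 QALYs
  capacity limits forgo 46,861 QALYs (26% more health attainable without them)
  at EUR 255.3M: 77.0% of spending and 82.0% of QALY gains in the general population
```

i.e. on this synthetic problem, professional-capacity limits cut the maximal
attainable health gain by about a quarter, and the optimal split between
universal and targeted prevention depends on the budget level. Scripts
`analysis/01…04` write their tables under `results/`.

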