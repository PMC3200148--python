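"""Domain types for prevention resource-allocation problems.

An :class:`AllocationProblem` describes the decision faced by a health-care
payer: a set of preventive programs ``j`` (smoking cessation, lifestyle,
blood-pressure medication, statins, ...), each offered either to the general
population or to diagnosed diabetes patients, crossed with a set of age groups
``a``.  Every program x age *cell* carries the lifetime-discounted health gain
per participant ``q_ja`` (QALYs), the lifetime-discounted net cost per
participant ``c_ja`` (euro), and a demand ceiling ``dem_ja`` (the size of the
eligible target group).  Each program additionally has a capacity ceiling
``cap_j`` on participants summed over all age groups (professional supply).

This module also ships, as package data, the published league table of average
cost-effectiveness ratios for the 12 Dutch cardiovascular/diabetes prevention
programs in three age categories (36 rows), and the league-table operations
(ranking, cost-per-QALY band counts) used to summarise it.

All monetary values are euro at 2007 price level.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GENERAL = "general"
DIABETES = "diabetes"
POPULATIONS = (GENERAL, DIABETES)

#: canonical age categories used throughout; representative cohort entry ages
#: are the interval midpoints (72 for the open-ended oldest category).
CANONICAL_AGE_GROUPS = (
    (1, "20-44", 32.0),
    (2, "45-64", 55.0),
    (3, "65+", 72.0),
)

_CANONICAL_START_AGE = {label: start for _, label, start in CANONICAL_AGE_GROUPS}

_FIXTURE_RESOURCE = "cer_league_table.csv"

PROBLEM_CSV_COLUMNS = [
    "program_code",
    "program_title",
    "population",
    "age_label",
    "qaly_per_participant",
    "cost_per_participant",
    "demand",
    "capacity",
]


class ProblemError(ValueError):
    """Base class for problem-construction failures."""


class ParseError(ProblemError):
    """A file could not be parsed into a problem."""


class ValidationError(ProblemError):
    """A parsed problem violates a structural invariant."""


class DegenerateCellError(ProblemError):
    """A cell with q = 0 and c = 0 has no defined cost-effectiveness ratio."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeGroup:
    """One age category; ``start_age`` is the cohort entry age used by the
    cohort simulator."""

    id: int
    label: str
    start_age: float


@dataclass(frozen=True)
class Program:
    """One preventive program, offered to exactly one target population."""

    id: int
    code: str
    title: str
    population: str

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(
                f"program {self.code!r}: population must be one of {POPULATIONS},"
                f" got {self.population!r}"
            )


@dataclass(frozen=True)
class Cell:
    """Per-participant outcomes and demand for one program x age combination.

    ``qaly_per_participant`` and ``cost_per_participant`` are net present
    values versus care as usual; ``demand`` is the maximum number of
    participants (size of the eligible group).  Outcomes may be ``None`` for
    league-table-only problem stubs where only the c/q ratio is known.
    """

    program_id: int
    age_id: int
    qaly_per_participant: float | None
    cost_per_participant: float | None
    demand: float

    @property
    def has_outcomes(self) -> bool:
        return self.qaly_per_participant is not None and self.cost_per_participant is not None


@dataclass
class AllocationProblem:
    """The full decision problem.

    ``capacities`` maps program id -> cap_j (persons, summed over age groups;
    ``math.inf`` means unconstrained).  The available budget is *not* a field:
    it enters as an argument to the allocator operations.
    """

    programs: list[Program]
    age_groups: list[AgeGroup]
    cells: list[Cell]
    capacities: dict[int, float]
    meta: dict = field(default_factory=dict)

    # -- indexing helpers ---------------------------------------------------

    def program(self, program_id: int) -> Program:
        return self._programs_by_id[program_id]

    def age_group(self, age_id: int) -> AgeGroup:
        return self._ages_by_id[age_id]

    @property
    def _programs_by_id(self) -> dict[int, Program]:
        return {p.id: p for p in self.programs}

    @property
    def _ages_by_id(self) -> dict[int, AgeGroup]:
        return {a.id: a for a in self.age_groups}

    def cell_code(self, cell: Cell) -> str:
        """Short display code for a cell, e.g. ``"S1"`` (program ``S`` in the
        youngest age category)."""
        return f"{self.program(cell.program_id).code}{cell.age_id}"

    def ordered_cells(self) -> list[Cell]:
        """Cells in the canonical deterministic order: by (program code,
        age id).  All vector representations use this order."""
        codes = {p.id: p.code for p in self.programs}
        return sorted(self.cells, key=lambda c: (codes[c.program_id], c.age_id))

    def cell(self, program_id: int, age_id: int) -> Cell:
        for c in self.cells:
            if c.program_id == program_id and c.age_id == age_id:
                return c
        raise KeyError((program_id, age_id))

    def capacity(self, program_id: int) -> float:
        return self.capacities.get(program_id, math.inf)

    def copy(self) -> "AllocationProblem":
        return AllocationProblem(
            programs=list(self.programs),
            age_groups=list(self.age_groups),
            cells=list(self.cells),
            capacities=dict(self.capacities),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Cell-level view as a DataFrame in canonical order."""
        rows = []
        for c in self.ordered_cells():
            prog = self.program(c.program_id)
            age = self.age_group(c.age_id)
            rows.append(
                {
                    "cell_code": self.cell_code(c),
                    "program_code": prog.code,
                    "program_title": prog.title,
                    "population": prog.population,
                    "age_label": age.label,
                    "qaly_per_participant": c.qaly_per_participant,
                    "cost_per_participant": c.cost_per_participant,
                    "demand": c.demand,
                    "capacity": self.capacity(c.program_id),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CERRow:
    """One league-table entry: the average cost-effectiveness ratio of one
    program in one age category versus care as usual."""

    code: str
    age_label: str
    population: str
    average_cer: float | None
    flag: str = "ok"  # ok | cost_saving | dominated
    title: str = ""


@dataclass
class CERTable:
    """League table of average cost-per-QALY ratios."""

    rows: list[CERRow]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[CERRow]:
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "short_name": r.code,
                    "age_label": r.age_label,
                    "population": r.population,
                    "average_cer": r.average_cer,
                    "flag": r.flag,
                    "title": r.title,
                }
                for r in self.rows
            ]
        )


@dataclass(frozen=True)
class CostEffectiveness:
    """Average CER of a single cell; ``rounded`` is to the nearest 100 euro,
    matching how such league tables are conventionally printed."""

    ratio: float | None
    flag: str  # ok | cost_saving | dominated
    rounded: float | None


# ---------------------------------------------------------------------------
# League-table operations
# ---------------------------------------------------------------------------


def round_to_hundred(x: float) -> float:
    return round(x / 100.0) * 100.0


def average_cer(cell: Cell) -> CostEffectiveness:
    """Average cost-effectiveness ratio c/q of one cell versus usual care.

    Cells with negative cost and positive health gain are flagged
    ``cost_saving`` (always worth funding); cells with non-positive health
    gain are flagged ``dominated`` (never funded).
    """
    q = cell.qaly_per_participant
    c = cell.cost_per_participant
    if q is None or c is None:
        raise ProblemError("cell has no (q, c) outcomes; ratio undefined")
    if q == 0 and c == 0:
        raise DegenerateCellError("cell with q = 0 and c = 0 has no defined ratio")
    if q <= 0:
        return CostEffectiveness(ratio=None, flag="dominated", rounded=None)
    ratio = c / q
    flag = "cost_saving" if c < 0 else "ok"
    return CostEffectiveness(ratio=ratio, flag=flag, rounded=round_to_hundred(ratio))


def cer_table(problem: AllocationProblem) -> CERTable:
    """League table recomputed from a problem's per-cell (q, c) outcomes."""
    rows = []
    for cell in problem.ordered_cells():
        prog = problem.program(cell.program_id)
        age = problem.age_group(cell.age_id)
        ce = average_cer(cell)
        rows.append(
            CERRow(
                code=problem.cell_code(cell),
                age_label=age.label,
                population=prog.population,
                average_cer=ce.ratio,
                flag=ce.flag,
                title=prog.title,
            )
        )
    return CERTable(rows)


def rank_by_cer(table: CERTable) -> CERTable:
    """Sort a league table at increasing cost per QALY.

    Cost-saving rows come first (most cost-saving first); dominated rows are
    excluded with a log notice; ties broken by (code, age label).
    """
    kept = [r for r in table.rows if r.flag != "dominated"]
    dropped = [r for r in table.rows if r.flag == "dominated"]
    for r in dropped:
        logger.info("rank_by_cer: excluding dominated row %s (%s)", r.code, r.age_label)
    return CERTable(sorted(kept, key=lambda r: (r.average_cer, r.code, r.age_label)))


def count_by_cer_band(
    table: CERTable,
    lower: float,
    upper: float,
    population: str | None = None,
) -> int:
    """Number of league-table rows with ``lower < ratio < upper`` (exclusive
    endpoints), optionally restricted to one target population."""
    if not lower < upper:
        raise ValueError(f"band bounds must satisfy lower < upper, got ({lower}, {upper})")
    if population is not None and population not in POPULATIONS:
        raise ValueError(
            f"unknown population tag {population!r}; valid tags: {list(POPULATIONS)}"
        )
    n = 0
    for r in table.rows:
        if r.flag == "dominated" or r.average_cer is None:
            continue
        if population is not None and r.population != population:
            continue
        if lower < r.average_cer < upper:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------


def _fixture_text() -> str:
    return resources.files("prevalloc.data").joinpath(_FIXTURE_RESOURCE).read_text()


def load_league_table() -> CERTable:
    """The packaged 36-row league table of published average cost-per-QALY
    ratios (12 programs x 3 age categories, euro 2007)."""
    reader = csv.DictReader(io.StringIO(_fixture_text()))
    rows = [
        CERRow(
            code=rec["short_name"],
            age_label=rec["age_label"],
            population=rec["population"],
            average_cer=float(rec["average_cer"]),
            flag="ok",
            title=rec["title"],
        )
        for rec in reader
    ]
    return CERTable(rows)


def fixture_problem_stub() -> AllocationProblem:
    """AllocationProblem skeleton backed by the packaged league table: correct
    programs/ages, but per-cell (q, c) outcomes unset (only ratios are
    published) and demand unknown (set to +inf).  Useful for structural work;
    the allocator requires full outcomes — see :func:`demo_problem`."""
    reader = csv.DictReader(io.StringIO(_fixture_text()))
    records = list(reader)
    return _stub_from_records(records)


def _stub_from_records(records: list[dict]) -> AllocationProblem:
    age_groups = [AgeGroup(i, lab, s) for i, lab, s in CANONICAL_AGE_GROUPS]
    age_by_label = {a.label: a for a in age_groups}
    programs: list[Program] = []
    prog_by_code: dict[str, Program] = {}
    cells: list[Cell] = []
    for rec in records:
        code = rec["program_code"]
        if code not in prog_by_code:
            prog = Program(
                id=len(programs) + 1,
                code=code,
                title=rec["title"],
                population=rec["population"],
            )
            programs.append(prog)
            prog_by_code[code] = prog
        prog = prog_by_code[code]
        age = age_by_label[rec["age_label"]]
        cells.append(
            Cell(
                program_id=prog.id,
                age_id=age.id,
                qaly_per_participant=None,
                cost_per_participant=None,
                demand=math.inf,
            )
        )
    return AllocationProblem(
        programs=programs,
        age_groups=age_groups,
        cells=cells,
        capacities={p.id: math.inf for p in programs},
        meta={"currency": "EUR, price level 2007", "source": "packaged league-table fixture"},
    )


#: Synthetic per-participant QALY gains used by :func:`demo_problem` (the
#: published table gives only c/q ratios).  Values decline with age: most of
#: the lifetime benefit of prevention accrues to the young.
DEMO_QALY_PER_PARTICIPANT = {1: 0.25, 2: 0.20, 3: 0.12}

#: Synthetic demand ceilings (persons per cell).  The diabetes target group is
#: roughly an order of magnitude smaller than the general population.
DEMO_DEMAND = {
    GENERAL: {1: 400_000.0, 2: 350_000.0, 3: 250_000.0},
    DIABETES: {1: 40_000.0, 2: 35_000.0, 3: 25_000.0},
}

#: Synthetic capacity: fraction of a program's total demand that professional
#: supply can actually serve.
DEMO_CAPACITY_FRACTION = 0.6


def demo_problem() -> AllocationProblem:
    """Synthetic end-to-end companion problem built on the packaged league
    table: q per participant is fixed per age group (documented constants
    above) and c is derived as ratio x q, so every cell reproduces its
    published average CER exactly while demands/capacities are synthetic.
    """
    problem = fixture_problem_stub()
    table = {(r.code): r for r in load_league_table().rows}
    new_cells = []
    for cell in problem.cells:
        prog = problem.program(cell.program_id)
        code = problem.cell_code(cell)
        ratio = table[code].average_cer
        q = DEMO_QALY_PER_PARTICIPANT[cell.age_id]
        new_cells.append(
            replace(
                cell,
                qaly_per_participant=q,
                cost_per_participant=ratio * q,
                demand=DEMO_DEMAND[prog.population][cell.age_id],
            )
        )
    problem.cells = new_cells
    problem.capacities = {
        p.id: DEMO_CAPACITY_FRACTION
        * sum(c.demand for c in problem.cells if c.program_id == p.id)
        for p in problem.programs
    }
    problem.meta.update(
        {
            "source": "synthetic demo problem on the packaged league-table fixture",
            "general_demand_net_of_diabetes": True,
            "reference_population": 16_400_000,  # persons, for per-capita reporting
        }
    )
    return problem


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_float(value, *, what: str, where: str) -> float:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        raise ParseError(f"{where}: missing {what}")
    if isinstance(value, str) and value.strip().lower() in {"inf", "+inf", "infinity"}:
        return math.inf
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{where}: cannot parse {what} from {value!r}") from exc


def load_problem(path: str | Path, format: str | None = None) -> AllocationProblem:
    """Read an :class:`AllocationProblem` from CSV or JSON.

    Missing capacity is interpreted as unbounded.  Raises :class:`ParseError`
    for malformed files and :class:`ValidationError` for structurally invalid
    problems (duplicate cells, negative demand or capacity, ...).
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        problem = _load_problem_csv(path)
    elif fmt == "json":
        problem = _load_problem_json(path)
    else:
        raise ParseError(f"unsupported problem format {fmt!r} (expected csv or json)")
    violations = validate_problem(problem, _structural_only=True)
    if violations:
        raise ValidationError("; ".join(violations))
    return problem


def _load_problem_csv(path: Path) -> AllocationProblem:
    try:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ParseError(f"{path}: empty file, header row required")
            missing = [c for c in PROBLEM_CSV_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise ParseError(f"{path}: missing required columns {missing}")
            records = list(reader)
    except OSError as exc:
        raise ParseError(f"{path}: {exc}") from exc

    age_groups: list[AgeGroup] = []
    age_by_label: dict[str, AgeGroup] = {}
    programs: list[Program] = []
    prog_by_code: dict[str, Program] = {}
    cells: list[Cell] = []
    capacities: dict[int, float] = {}

    for lineno, rec in enumerate(records, start=2):
        where = f"{path}:{lineno}"
        label = rec["age_label"]
        if label not in age_by_label:
            if "start_age" in rec and rec.get("start_age"):
                start = _parse_float(rec["start_age"], what="start_age", where=where)
            else:
                start = _CANONICAL_START_AGE.get(label, 20.0 + 25.0 * len(age_by_label))
            age = AgeGroup(id=len(age_groups) + 1, label=label, start_age=start)
            age_groups.append(age)
            age_by_label[label] = age
        age = age_by_label[label]

        code = rec["program_code"]
        if code not in prog_by_code:
            prog = Program(
                id=len(programs) + 1,
                code=code,
                title=rec.get("program_title", code),
                population=rec["population"],
            )
            programs.append(prog)
            prog_by_code[code] = prog
        prog = prog_by_code[code]

        cap = rec.get("capacity")
        cap_value = math.inf if cap in (None, "") else _parse_float(cap, what="capacity", where=where)
        if prog.id in capacities and not _same(capacities[prog.id], cap_value):
            raise ParseError(
                f"{where}: capacity for program {code!r} disagrees with an earlier row"
                f" ({cap_value} vs {capacities[prog.id]})"
            )
        capacities[prog.id] = cap_value

        cells.append(
            Cell(
                program_id=prog.id,
                age_id=age.id,
                qaly_per_participant=_opt_float(rec.get("qaly_per_participant")),
                cost_per_participant=_opt_float(rec.get("cost_per_participant")),
                demand=_parse_float(rec["demand"], what="demand", where=where),
            )
        )

    return AllocationProblem(
        programs=programs, age_groups=age_groups, cells=cells, capacities=capacities, meta={}
    )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    return _parse_float(value, what="value", where="<cell>")


def _same(a: float, b: float) -> bool:
    if math.isinf(a) and math.isinf(b):
        return True
    return abs(a - b) <= 1e-9 * max(1.0, abs(a), abs(b))


def _load_problem_json(path: Path) -> AllocationProblem:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for key in ("programs", "age_groups", "cells"):
        if key not in doc:
            raise ParseError(f"{path}: missing top-level key {key!r}")
    try:
        programs = [
            Program(id=p["id"], code=p["code"], title=p.get("title", p["code"]),
                    population=p["population"])
            for p in doc["programs"]
        ]
        age_groups = [
            AgeGroup(id=a["id"], label=a["label"], start_age=a["start_age"])
            for a in doc["age_groups"]
        ]
        cells = [
            Cell(
                program_id=c["program_id"],
                age_id=c["age_id"],
                qaly_per_participant=c.get("qaly_per_participant"),
                cost_per_participant=c.get("cost_per_participant"),
                demand=math.inf if c["demand"] is None else c["demand"],
            )
            for c in doc["cells"]
        ]
    except KeyError as exc:
        raise ParseError(f"{path}: missing key {exc.args[0]!r}") from exc
    capacities = {
        int(k): (math.inf if v is None else v)
        for k, v in doc.get("capacities", {}).items()
    }
    return AllocationProblem(
        programs=programs,
        age_groups=age_groups,
        cells=cells,
        capacities=capacities,
        meta=doc.get("meta", {}),
    )


def write_problem(problem: AllocationProblem, path: str | Path, format: str | None = None) -> None:
    """Write a problem to CSV or JSON.  JSON round-trips all numeric fields
    bit-exactly; CSV writes full ``repr`` precision."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        _write_problem_csv(problem, path)
    elif fmt == "json":
        _write_problem_json(problem, path)
    else:
        raise ValueError(f"unsupported problem format {fmt!r} (expected csv or json)")


def _num(x: float | None) -> str:
    if x is None:
        return ""
    if math.isinf(x):
        return "inf"
    return repr(float(x))


def _write_problem_csv(problem: AllocationProblem, path: Path) -> None:
    cols = PROBLEM_CSV_COLUMNS + ["age_id", "start_age"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for cell in problem.ordered_cells():
            prog = problem.program(cell.program_id)
            age = problem.age_group(cell.age_id)
            writer.writerow(
                [
                    prog.code,
                    prog.title,
                    prog.population,
                    age.label,
                    _num(cell.qaly_per_participant),
                    _num(cell.cost_per_participant),
                    _num(cell.demand),
                    _num(problem.capacity(cell.program_id)),
                    age.id,
                    _num(age.start_age),
                ]
            )


def _jsonable(x: float | None):
    if x is None:
        return None
    if math.isinf(x):
        return None  # JSON has no inf; None means unbounded
    return x


def _write_problem_json(problem: AllocationProblem, path: Path) -> None:
    doc = {
        "programs": [
            {"id": p.id, "code": p.code, "title": p.title, "population": p.population}
            for p in problem.programs
        ],
        "age_groups": [
            {"id": a.id, "label": a.label, "start_age": a.start_age}
            for a in problem.age_groups
        ],
        "cells": [
            {
                "program_id": c.program_id,
                "age_id": c.age_id,
                "qaly_per_participant": c.qaly_per_participant,
                "cost_per_participant": c.cost_per_participant,
                "demand": _jsonable(c.demand),
            }
            for c in problem.ordered_cells()
        ],
        "capacities": {str(k): _jsonable(v) for k, v in sorted(problem.capacities.items())},
        "meta": problem.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_problem(problem: AllocationProblem, *, _structural_only: bool = False) -> list[str]:
    """Check all type invariants; returns a list of violations (empty iff
    valid), never raises.

    Beyond structural checks, asserts the disjoint-target-population
    convention: when a problem mixes general-population and diabetes programs,
    its metadata must declare that general-population demand figures are net
    of diabetes patients (diabetes-specific programs take priority where the
    target groups overlap).
    """
    v: list[str] = []

    codes = [p.code for p in problem.programs]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        v.append(f"duplicate program codes: {dupes}")
    labels = [a.label for a in problem.age_groups]
    if len(set(labels)) != len(labels):
        v.append("duplicate age labels")
    ids = [a.id for a in problem.age_groups]
    starts = [a.start_age for a in sorted(problem.age_groups, key=lambda a: a.id)]
    if len(set(ids)) != len(ids):
        v.append("duplicate age ids")
    elif any(s2 <= s1 for s1, s2 in zip(starts, starts[1:])):
        v.append("start_age must be strictly increasing with age id")

    seen: set[tuple[int, int]] = set()
    prog_ids = {p.id for p in problem.programs}
    age_ids = {a.id for a in problem.age_groups}
    for cell in problem.cells:
        key = (cell.program_id, cell.age_id)
        name = f"({cell.program_id}, {cell.age_id})"
        if key in seen:
            code = problem._programs_by_id.get(cell.program_id)
            v.append(
                f"duplicate cell for (program {code.code if code else cell.program_id},"
                f" age {cell.age_id})"
            )
        seen.add(key)
        if cell.program_id not in prog_ids or cell.age_id not in age_ids:
            v.append(f"cell {name} references unknown program or age id")
            continue
        if not cell.demand >= 0:
            v.append(f"cell {problem.cell_code(cell)}: negative demand {cell.demand}")
        for attr in ("qaly_per_participant", "cost_per_participant"):
            val = getattr(cell, attr)
            if val is not None and not math.isfinite(val):
                v.append(f"cell {problem.cell_code(cell)}: non-finite {attr}")
    for p in problem.programs:
        for a in problem.age_groups:
            if (p.id, a.id) not in seen:
                v.append(f"missing cell for (program {p.code}, age {a.label})")

    for pid, cap in problem.capacities.items():
        if not cap >= 0:
            prog = problem._programs_by_id.get(pid)
            v.append(f"program {prog.code if prog else pid}: negative capacity {cap}")

    if not _structural_only:
        pops = {p.population for p in problem.programs}
        if pops == set(POPULATIONS) and not problem.meta.get("general_demand_net_of_diabetes"):
            v.append(
                "problem mixes general and diabetes programs but meta flag"
                " 'general_demand_net_of_diabetes' is not set: demand of"
                " general-population programs must be declared net of diabetes"
                " patients (target populations disjoint)"
            )
    return v
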