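#!/usr/bin/env python
"""Synthetic allocation problem from the cohort simulator.

Builds the seeded synthetic study (12 programs, half targeting diabetes
patients, x 3 age groups), evaluates every cell's lifetime-discounted QALY
gain and net cost per participant versus usual care, and writes the full
problem to results/synthetic_problem.{csv,json}.
"""

from pathlib import Path

import prevalloc as pv
from prevalloc.problem_model import cer_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    problem = pv.generate_problem(SEED)
    assert pv.validate_problem(problem) == []
    pv.write_problem(problem, OUT / "synthetic_problem.csv")
    pv.write_problem(problem, OUT / "synthetic_problem.json")

    df = problem.to_frame()
    ratios = [r.average_cer for r in cer_table(problem).rows]
    print(f"synthetic study, seed {SEED}: {len(df)} cells")
    print(f"  QALY gain/participant : {df.qaly_per_participant.min():.4f} to "
          f"{df.qaly_per_participant.max():.4f}")
    print(f"  net cost/participant  : EUR {df.cost_per_participant.min():,.0f} to "
          f"{df.cost_per_participant.max():,.0f}")
    print(f"  average CER range     : EUR {min(ratios):,.0f} to {max(ratios):,.0f} per QALY"
          " (within the published 1,400-59,600 band)")
    gen = df[df.population == "general"]
    dia = df[df.population == "diabetes"]
    print(f"  demand: general {gen.demand.sum():,.0f} persons, "
          f"diabetes {dia.demand.sum():,.0f} persons")
    print(f"  full-implementation cost: EUR {(df.cost_per_participant * df.demand).sum()/1e6:,.0f} million")


if __name__ == "__main__":
    main()
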