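"""Shared fixtures for the test-suite.

All problem instances are built programmatically (see
:mod:`prevalloc.testing`); the only stored data is the packaged league-table
fixture inside the library itself.
"""

from __future__ import annotations

import pytest

import prevalloc as pv
from prevalloc.testing import (  # noqa: F401  (re-exported for test modules)
    make_problem,
    random_capacity_free_instance,
    random_small_instance,
)


@pytest.fixture(scope="session")
def study():
    """The default seeded synthetic study (seed 1)."""
    return pv.generate_study(1)


@pytest.fixture(scope="session")
def generated_problem(study):
    return study.problem()


@pytest.fixture(scope="session")
def generated_frontier(generated_problem):
    return pv.trace_frontier(generated_problem)


@pytest.fixture(scope="session")
def league_table():
    return pv.load_league_table()
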