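"""Shared fixtures: the worked-example scenario (p0=0.15, p1=0.3,
alpha=0.0025, beta=0.36) and its performance grids, built once per session."""

import numpy as np
import pytest

from devplan import (
    GlobalErrorSpec,
    build_plans,
    evaluate_grid,
    evaluate_line,
)

P0, P1 = 0.15, 0.30
ALPHA, BETA = 0.0025, 0.36
OBSERVED = (0.15, 0.41)


@pytest.fixture(scope="session")
def worked_example_plans():
    return build_plans(P0, P1, GlobalErrorSpec(ALPHA, BETA))


@pytest.fixture(scope="session")
def line_grids(worked_example_plans):
    """Per-plan metrics along the line pC = p0 on a 0.01 lattice."""
    pe = np.linspace(0.0, 1.0, 101)
    return {
        pid: evaluate_line(plan, P0, pe)
        for pid, plan in worked_example_plans.items()
    }


@pytest.fixture(scope="session")
def full_grids(worked_example_plans):
    """Full 101 x 101 lattice over the response-rate square for all plans."""
    return evaluate_grid(worked_example_plans, grid_step=0.01)
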