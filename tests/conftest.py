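"""Shared fixtures: parameter sets, schedules, and a cached synthetic study.

Session-scoped fixtures cache expensive objects (simulations, a maximum-
likelihood fit) so that independent tests can share them without re-running
the numerics.
"""
import numpy as np
import pytest

from bcellqsp import (
    AntigenSchedule,
    CalibrationProblem,
    StudyDesign,
    build_parameters,
    fit,
    generate_observations,
    simulate,
)

#: Optimizer settings for test-suite fits: reach the optimum to ~1e-4 in
#: -2LL at a fraction of the default cost (verified against a long run).
FAST_FIT = dict(fatol=1e-4, xatol=1e-2, restart=True, maxiter=200)

#: Solver tolerances for likelihood evaluation inside fitting loops.
LOOP_TOL = dict(rtol=1e-6, atol=1e-3)


@pytest.fixture(scope="session")
def params_paper():
    return build_parameters(mode="paper")


@pytest.fixture(scope="session")
def params_sc():
    return build_parameters(mode="self_consistent")


@pytest.fixture(scope="session")
def schedule():
    return AntigenSchedule()


@pytest.fixture(scope="session")
def reference_trajectory(params_sc, schedule):
    """Full-model response simulation, day 0-350 at 0.5-day resolution."""
    return simulate(params_sc, schedule, t_end=350.0, dt_out=0.5)


@pytest.fixture(scope="session")
def synthetic_study(params_sc, schedule):
    """One synthetic study (seed 42) with its ground truth."""
    table, truth = generate_observations(
        params_sc, schedule, StudyDesign(seed=42)
    )
    return table, truth


@pytest.fixture(scope="session")
def fitted(params_sc, schedule, synthetic_study):
    """Problem + ML fit of the seed-42 study, shared across tests."""
    table, truth = synthetic_study
    problem = CalibrationProblem(table, params_sc, schedule, **LOOP_TOL)
    result = fit(problem, seed=1, **FAST_FIT)
    return problem, result, truth
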