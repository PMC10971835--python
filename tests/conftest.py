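"""Shared fixtures: coarse-grid solved cases reused across the suite.

The coarse settings (nx=120, nr=(8,4,8)) resolve all qualitative physics --
counter-current pressure profiles, membrane exchange, boundary layers -- at
about a second per solve; quantitative comparisons against published values
run at production resolution in the acceptance tests only.
"""

import dataclasses

import pytest

import hollowfiber as hf
from hollowfiber.grid import grid_for_case

COARSE = dict(nx=120, nr_tube=8, nr_mem=4, nr_shell=8)


def coarse_case(name, scheme="central", **overrides):
    case = hf.builtin_case(name)
    solver = dataclasses.replace(case.solver, scheme=scheme, **COARSE)
    return dataclasses.replace(case, solver=solver)


def solve_case(case):
    grid = grid_for_case(case)
    flow = hf.solve_flow(grid, case)
    conc = hf.solve_concentration(grid, flow, case)
    return grid, flow, conc


@pytest.fixture(scope="session")
def urea_coarse():
    case = coarse_case("baseline_urea")
    return (case, *solve_case(case))


@pytest.fixture(scope="session")
def bilirubin_coarse():
    case = coarse_case("baseline_bilirubin")
    return (case, *solve_case(case))


@pytest.fixture(scope="session")
def bsa_coarse():
    case = coarse_case("baseline_bsa")
    return (case, *solve_case(case))


@pytest.fixture(scope="session")
def bilirubin_upwind_coarse():
    case = coarse_case("baseline_bilirubin", scheme="upwind")
    return (case, *solve_case(case))
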