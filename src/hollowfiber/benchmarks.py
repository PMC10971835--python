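"""Analytic verification benchmarks for the 2D solvers.

The numerical model reproduces a commercial-CFD-class computation with an
independent discretization, so every solver claim is anchored to closed-form
or independently computed references before any dialyzer prediction is
trusted:

* closed-membrane Poiseuille flow -- the lumen pressure gradient and
  centreline velocity against Hagen-Poiseuille;
* a no-flow diffusion slab -- the exactly linear steady profile between two
  fixed-concentration ends;
* the Graetz configuration (fully developed lumen flow, fixed wall
  concentration) -- the asymptotic decay rate of the mixed-cup concentration
  against the leading eigenvalue of the Graetz-Sturm-Liouville problem,
  computed here by an independent shooting method (scipy ODE integration +
  root bracketing), not by the finite-volume solver under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .config import (ModuleGeometry, OperatingConditions, SimulationCase,
                     SoluteSpec, SolverSettings, ML_MIN)
from .errors import DomainError
from .flow import FlowField, solve_flow
from .grid import build_grid
from .membrane import MembraneSpec
from .transport import solve_concentration

__all__ = [
    "BenchmarkCase", "impermeable_membrane", "poiseuille_case",
    "run_poiseuille", "diffusion_slab_case", "run_diffusion_slab",
    "graetz_case", "graetz_decay_rate_oracle", "run_graetz", "verify",
]

_TABLE_GEOMETRY = ModuleGeometry(r1=1.0e-4, r2=1.45e-4, r3=2.10e-4,
                                 L=0.27, N=12000)


@dataclass(frozen=True)
class BenchmarkCase:
    """A solver verification case with its closed-form reference."""

    name: str
    case: SimulationCase
    analytic: dict
    tolerance: float

    def __post_init__(self):
        if self.tolerance <= 0:
            raise DomainError("benchmark tolerance must be positive")


def impermeable_membrane(geometry: ModuleGeometry) -> MembraneSpec:
    """A closed (solid) membrane: zero Darcy permeability and solute transport."""
    return MembraneSpec(rp=1e-9, eps=0.0, psi=1.0, delta=geometry.delta,
                        Lp=0.0, D0=0.0, K0=0.0, sigma=0.0, alpha=0.0)


def _solver(nx, nr_tube, scheme="central"):
    return SolverSettings(nx=nx, nr_tube=nr_tube, nr_mem=4, nr_shell=max(
        4, nr_tube // 2), stretch=1.15, scheme=scheme)


def poiseuille_case(geometry: ModuleGeometry | None = None,
                    tube_flow_mL_min: float = 300.0,
                    nx: int = 200, nr_tube: int = 16) -> BenchmarkCase:
    """Closed-membrane lumen flow against Hagen-Poiseuille.

    References: fully developed pressure drop ``8 mu L Q_f / (pi r1^4)`` and
    centreline velocity ``2 x`` the mean.
    """
    g = geometry or _TABLE_GEOMETRY
    op = OperatingConditions(QB_in=tube_flow_mL_min * ML_MIN, QD_in=0.0)
    solute = SoluteSpec(name="tracer", MW=60.0, rs=0.24e-9, C_in=1.0)
    case = SimulationCase(geometry=g, operating=op, solute=solute,
                          membrane=impermeable_membrane(g),
                          solver=_solver(nx, nr_tube))
    Q_f = op.QB_in / g.N
    dp_ref = 8.0 * op.mu * g.L * Q_f / (math.pi * g.r1**4)
    u_mean = Q_f / (math.pi * g.r1**2)
    return BenchmarkCase(
        name="poiseuille",
        case=case,
        analytic={"dp_ref": dp_ref, "centerline_ref": 2.0 * u_mean,
                  "u_mean": u_mean},
        tolerance=0.02,
    )


def run_poiseuille(bench: BenchmarkCase) -> dict:
    """Solve the closed-membrane case and compare with the analytic profile."""
    case = bench.case
    s = case.solver
    grid = build_grid(case.geometry, s.nx, s.nr_tube, s.nr_mem, s.nr_shell,
                      stretch=s.stretch)
    fl = solve_flow(grid, case)
    # fully developed pressure gradient from the central 60 % of the lumen axis
    x, p = grid.xc, fl.p[:, 0]
    lo, hi = int(0.2 * grid.nx), int(0.8 * grid.nx)
    slope = np.polyfit(x[lo:hi], p[lo:hi], 1)[0]
    dp = -slope * case.geometry.L
    # centreline velocity at mid-length; u rows carry ring averages sampled
    # at the quadratic-mean radius, so invert the parabola there
    r0 = math.sqrt(0.5 * (grid.r_faces[0] ** 2 + grid.r_faces[1] ** 2))
    u_c = fl.u[grid.nx // 2, 0] / (1.0 - (r0 / grid.r1) ** 2)
    return {
        "dp_measured": float(dp),
        "dp_ref": bench.analytic["dp_ref"],
        "dp_rel_error": float(abs(dp - bench.analytic["dp_ref"])
                              / bench.analytic["dp_ref"]),
        "centerline_measured": float(u_c),
        "centerline_ref": bench.analytic["centerline_ref"],
        "centerline_rel_error": float(
            abs(u_c - bench.analytic["centerline_ref"])
            / bench.analytic["centerline_ref"]),
        "flow": fl,
        "grid": grid,
    }


def diffusion_slab_case(C_left: float = 1.0, C_right: float = 0.2,
                        nx: int = 60, nr_tube: int = 8) -> BenchmarkCase:
    """No-flow lumen slab with fixed concentrations at both ends.

    The steady solution is exactly linear in x; with uniform spacing the
    finite-volume solution is nodally exact, so the tolerance is round-off
    scale.
    """
    g = _TABLE_GEOMETRY
    op = OperatingConditions(QB_in=0.0, QD_in=0.0)
    solute = SoluteSpec(name="tracer", MW=60.0, rs=0.24e-9, C_in=C_left)
    case = SimulationCase(geometry=g, operating=op, solute=solute,
                          membrane=impermeable_membrane(g),
                          solver=_solver(nx, nr_tube))
    return BenchmarkCase(
        name="diffusion_slab", case=case,
        analytic={"C_left": C_left, "C_right": C_right},
        tolerance=1e-8,
    )


def run_diffusion_slab(bench: BenchmarkCase) -> dict:
    case = bench.case
    s = case.solver
    grid = build_grid(case.geometry, s.nx, s.nr_tube, s.nr_mem, s.nr_shell,
                      stretch=s.stretch)
    fl = solve_flow(grid, case)     # zero everywhere (no inflow)
    cc = solve_concentration(
        grid, fl, case, tube_outlet_dirichlet=bench.analytic["C_right"])
    C0, C1 = bench.analytic["C_left"], bench.analytic["C_right"]
    C_exact = C0 + (C1 - C0) * grid.xc / case.geometry.L
    err = np.max(np.abs(cc.Cb[:, :grid.nr_tube]
                        - C_exact[:, None])) / max(abs(C0), abs(C1))
    return {"max_rel_error": float(err), "conc": cc, "grid": grid}


def graetz_decay_rate_oracle(Ds: float, u_mean: float, R: float) -> float:
    """Asymptotic mixed-cup decay rate (1/m) of the Graetz problem.

    Independently computes the leading eigenvalue c of
    ``(eta f')' + c eta (1 - eta^2) f = 0`` with ``f'(0) = 0, f(1) = 0``
    (eta = r/R) by shooting, then returns ``gamma = c Ds / (2 u_mean R^2)``.
    """

    def f_at_wall(c):
        def rhs(eta, y):
            return [y[1] / eta, -c * eta * (1.0 - eta * eta) * y[0]]

        eta0 = 1e-8
        sol = solve_ivp(rhs, (eta0, 1.0), [1.0, -0.5 * c * eta0**2],
                        rtol=1e-10, atol=1e-12, dense_output=False)
        return sol.y[0, -1]

    c = brentq(f_at_wall, 5.0, 25.0, xtol=1e-10)
    return c * Ds / (2.0 * u_mean * R * R)


def graetz_case(Ds: float = 1.69e-9, tube_flow_mL_min: float = 300.0,
                L: float = 0.05, nx: int = 200, nr_tube: int = 16,
                scheme: str = "central") -> BenchmarkCase:
    """Fully developed lumen flow with zero wall concentration.

    Downstream of the thermal entrance the mixed-cup concentration decays as
    ``exp(-gamma x)`` with gamma from the leading Graetz eigenvalue.
    """
    g = ModuleGeometry(r1=_TABLE_GEOMETRY.r1, r2=_TABLE_GEOMETRY.r2,
                       r3=_TABLE_GEOMETRY.r3, L=L, N=_TABLE_GEOMETRY.N)
    op = OperatingConditions(QB_in=tube_flow_mL_min * ML_MIN, QD_in=0.0)
    solute = SoluteSpec(name="tracer", MW=60.0, rs=0.24e-9, C_in=1.0, Ds=Ds)
    case = SimulationCase(geometry=g, operating=op, solute=solute,
                          membrane=impermeable_membrane(g),
                          solver=_solver(nx, nr_tube, scheme))
    u_mean = (op.QB_in / g.N) / (math.pi * g.r1**2)
    gamma = graetz_decay_rate_oracle(Ds, u_mean, g.r1)
    return BenchmarkCase(
        name="graetz", case=case,
        analytic={"decay_rate_ref": gamma, "u_mean": u_mean},
        tolerance=0.02,
    )


def _parabolic_flow(grid, case, u_mean) -> FlowField:
    """Analytic fully developed lumen flow (no transmembrane exchange)."""
    u = np.zeros((grid.nx + 1, grid.nr))
    # sample the parabola at the quadratic-mean ring radius so the discrete
    # row fluxes u * Ax are the exact ring flows
    rs = np.sqrt(0.5 * (grid.r_faces[:grid.nr_tube] ** 2
                        + grid.r_faces[1:grid.nr_tube + 1] ** 2))
    u[:, :grid.nr_tube] = (2.0 * u_mean * (1.0 - (rs / grid.r1) ** 2))[None, :]
    return FlowField(grid=grid, case=case, p=np.zeros((grid.nx, grid.nr)),
                     u=u, v=np.zeros((grid.nx, grid.nr + 1)),
                     residuals={"continuity_max": 0.0, "momentum_max": 0.0})


def run_graetz(bench: BenchmarkCase) -> dict:
    """Measure the mixed-cup decay rate of the finite-volume solution."""
    case = bench.case
    s = case.solver
    grid = build_grid(case.geometry, s.nx, s.nr_tube, s.nr_mem, s.nr_shell,
                      stretch=s.stretch)
    fl = _parabolic_flow(grid, case, bench.analytic["u_mean"])
    cc = solve_concentration(grid, fl, case, tube_wall_dirichlet=0.0)
    jt = slice(0, grid.nr_tube)
    Ax = np.pi * (grid.r_faces[1:grid.nr_tube + 1] ** 2
                  - grid.r_faces[:grid.nr_tube] ** 2)
    w = fl.u[0, jt] * Ax
    theta = (cc.Cb[:, jt] @ w) / w.sum()
    # fit the decay downstream of the entrance, above round-off
    mask = (theta < 0.5) & (theta > 1e-6)
    if mask.sum() >= 2:
        x = grid.xc[mask]
        gamma = -np.polyfit(x, np.log(theta[mask]), 1)[0]
    else:                       # no decay (e.g. vanishing diffusivity)
        gamma = 0.0
    ref = bench.analytic["decay_rate_ref"]
    return {
        "decay_rate_measured": float(gamma),
        "decay_rate_ref": float(ref),
        "rel_error": float(abs(gamma - ref) / ref),
        "theta": theta,
        "outlet_theta": float(theta[-1]),
        "grid": grid,
    }


def verify(fast: bool = False) -> list[dict]:
    """Run the full benchmark suite; returns a machine-readable report."""
    report = []

    bench = poiseuille_case(nx=100 if fast else 200, nr_tube=12 if fast else 16)
    res = run_poiseuille(bench)
    report.append({
        "name": "poiseuille_dp",
        "measured": res["dp_measured"], "reference": res["dp_ref"],
        "rel_error": res["dp_rel_error"], "tolerance": bench.tolerance,
        "passed": res["dp_rel_error"] < bench.tolerance,
    })
    report.append({
        "name": "poiseuille_centerline",
        "measured": res["centerline_measured"],
        "reference": res["centerline_ref"],
        "rel_error": res["centerline_rel_error"], "tolerance": bench.tolerance,
        "passed": res["centerline_rel_error"] < bench.tolerance,
    })

    bench = diffusion_slab_case(nx=40 if fast else 60)
    res = run_diffusion_slab(bench)
    report.append({
        "name": "diffusion_slab_linear",
        "measured": res["max_rel_error"], "reference": 0.0,
        "rel_error": res["max_rel_error"], "tolerance": bench.tolerance,
        "passed": res["max_rel_error"] < bench.tolerance,
    })

    bench = graetz_case(nx=120 if fast else 200, nr_tube=12 if fast else 16)
    res = run_graetz(bench)
    report.append({
        "name": "graetz_decay_rate",
        "measured": res["decay_rate_measured"],
        "reference": res["decay_rate_ref"],
        "rel_error": res["rel_error"], "tolerance": bench.tolerance,
        "passed": res["rel_error"] < bench.tolerance,
    })
    return report
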