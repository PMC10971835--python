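"""Post-processing: clearance, transmembrane-pressure profiles, sweeps.

Clearance follows the standard dialyzer definition

.. math::

    CL_S = \\frac{Q_{B,in}\\,\\bar C_{s,in} - Q_{B,out}\\,\\bar C_{s,out}}
                {\\bar C_{s,in}}

with flow-weighted (mixed-cup) averages over the tube-side inlet/outlet
sections, computed per fiber and scaled to module level by the fiber count.
The transmembrane pressure is approximated, as is standard for these units,
by the difference between the pressure along the axis (lumen) and along the
outer symmetry radius (shell) at the same axial position; its maximum
positive value is reported at the tube-inlet end, where the counter-current
profiles peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ML_MIN, SimulationCase, rebuild
from .errors import DomainError
from .flow import FlowField, solve_flow
from .grid import Grid, grid_for_case
from .transport import ConcentrationField, solve_concentration

__all__ = [
    "ClearanceResult", "TMPProfile", "SimulationResult",
    "clearance", "clearance_formula", "outlet_max_concentration",
    "tmp_profile", "simulate", "run_sweep",
]


def outlet_max_concentration(conc: "ConcentrationField", grid: Grid) -> float:
    """Maximum solute concentration over the tube outlet section (mol/m^3).

    The maximum sits on the axis; cell values are ring averages, so the
    axis value is recovered by even-quadratic extrapolation
    ``C(r) = C0 + a r^2`` through the two innermost rows (sampled at their
    quadratic-mean radii).  This makes the scalar independent of where the
    innermost cell centre happens to fall, which matters when comparing
    grids in the mesh-independence study.
    """
    rs = np.sqrt(0.5 * (grid.r_faces[:-1] ** 2 + grid.r_faces[1:] ** 2))
    c1, c2 = conc.Cb[-1, 0], conc.Cb[-1, 1]
    r1, r2 = rs[0], rs[1]
    c_axis = c1 + (c1 - c2) * r1 * r1 / (r2 * r2 - r1 * r1)
    return float(max(c_axis, conc.Cb[-1, :grid.nr_tube].max()))


def clearance_formula(QB_in: float, QB_out: float, C_in: float,
                      C_out: float) -> float:
    """Dialyzer clearance ``(QB_in C_in - QB_out C_out) / C_in``.

    Units follow the inputs: feeding flows in mL/min returns mL/min.
    """
    if C_in <= 0:
        raise DomainError("clearance undefined for zero inlet concentration")
    return (QB_in * C_in - QB_out * C_out) / C_in


@dataclass(frozen=True)
class ClearanceResult:
    """Module-scale clearance and its bookkeeping (flows in mL/min)."""

    CLS: float
    QB_in: float
    QB_out: float
    C_in_avg: float     # mol/m^3
    C_out_avg: float
    filtrate: float     # mL/min, module scale
    residuals: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TMPProfile:
    """Axial transmembrane-pressure profile from the two symmetry lines."""

    x: np.ndarray
    p_axis: np.ndarray
    p_symmetry: np.ndarray
    dp: np.ndarray
    x_cross: float | None
    max_positive: float   # dp extrapolated to the tube-inlet end x = 0

    @property
    def positive_area(self) -> float:
        """Integral of the positive part of the TMP profile (Pa m).

        The filtration driving strength: with zero-gauge outlets the peak
        TMP at x=0 is pinned by the lumen pressure drop, so the response of
        filtration to the dialysate flow shows up in this integral (and in
        ``x_cross``), not in ``max_positive``.
        """
        dx = np.gradient(self.x)
        return float(np.sum(np.maximum(self.dp, 0.0) * dx))


@dataclass
class SimulationResult:
    """Bundle of one full steady solve."""

    case: SimulationCase
    grid: Grid
    flow: FlowField
    conc: ConcentrationField
    clearance: ClearanceResult
    tmp: TMPProfile


def clearance(flow: FlowField, conc: ConcentrationField,
              case: SimulationCase) -> ClearanceResult:
    """Mixed-cup clearance of the module, from the per-fiber discrete fluxes."""
    C_in = case.solute.C_in
    if C_in <= 0:
        raise DomainError("clearance undefined for zero inlet concentration")
    N = case.geometry.N
    g = flow.grid
    QB_in_f = flow.tube_flow_at(0)
    QB_out_f = flow.tube_flow_at(g.nx)
    solute_out = conc.boundary_fluxes["tube_outflow"]     # mol/s per fiber
    C_out_avg = solute_out / QB_out_f if QB_out_f > 0 else float("nan")
    CLS_f = clearance_formula(QB_in_f, QB_out_f, C_in, C_out_avg)  # m^3/s
    return ClearanceResult(
        CLS=CLS_f * N / ML_MIN,
        QB_in=QB_in_f * N / ML_MIN,
        QB_out=QB_out_f * N / ML_MIN,
        C_in_avg=C_in,
        C_out_avg=C_out_avg,
        filtrate=flow.filtrate_flow * N / ML_MIN,
        residuals={
            "flow": dict(flow.residuals),
            "solute_mass_balance": conc.mass_balance_residual,
        },
    )


def tmp_profile(flow: FlowField, grid: Grid) -> TMPProfile:
    """Axis-minus-outer-symmetry pressure difference along the module."""
    p_axis = flow.p[:, 0].copy()
    p_sym = flow.p[:, -1].copy()
    dp = p_axis - p_sym
    x = grid.xc.copy()
    sign = np.sign(dp)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx):
        k = idx[0]
        f = dp[k] / (dp[k] - dp[k + 1])
        x_cross = float(x[k] + f * (x[k + 1] - x[k]))
    else:
        x_cross = None
    # extrapolate the (nearly linear) profile to the tube-inlet end
    max_pos = float(dp[0] - (dp[1] - dp[0]) * x[0] / (x[1] - x[0]))
    return TMPProfile(x=x, p_axis=p_axis, p_symmetry=p_sym, dp=dp,
                      x_cross=x_cross, max_positive=max_pos)


def simulate(case: SimulationCase) -> SimulationResult:
    """One full steady solve: grid, flow, solute, clearance, TMP."""
    g = grid_for_case(case)
    fl = solve_flow(g, case)
    cc = solve_concentration(g, fl, case)
    return SimulationResult(
        case=case, grid=g, flow=fl, conc=cc,
        clearance=clearance(fl, cc, case),
        tmp=tmp_profile(fl, g),
    )


_SWEEP_PARAMS = {
    # name -> (case override key, conversion from sweep units to SI)
    "tube_flow": ("QB_in", ML_MIN),     # mL/min
    "shell_flow": ("QD_in", ML_MIN),    # mL/min
    "length": ("L", 1e-3),              # mm
}


def run_sweep(base: SimulationCase, parameter: str, values) -> pd.DataFrame:
    """One full solve per value of an operating parameter.

    ``parameter`` is one of ``tube_flow``/``shell_flow`` (values in mL/min)
    or ``length`` (values in mm) -- the units used in the configuration
    schema.  Per-case solver failures are recorded in the ``error`` column
    and the sweep continues.
    """
    if parameter not in _SWEEP_PARAMS:
        raise DomainError(
            f"unknown sweep parameter {parameter!r}; "
            f"choose from {sorted(_SWEEP_PARAMS)}")
    values = list(values)
    if not values:
        raise DomainError("sweep needs at least one value")
    key, conv = _SWEEP_PARAMS[parameter]
    records = []
    for val in values:
        rec = {"parameter": parameter, "value": val}
        try:
            case = rebuild(base, **{key: val * conv})
            res = simulate(case)
            rec.update(
                CLS=res.clearance.CLS,
                max_TMP=res.tmp.max_positive,
                tmp_positive_area=res.tmp.positive_area,
                x_cross=res.tmp.x_cross,
                filtrate=res.clearance.filtrate,
                QB_out=res.clearance.QB_out,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            rec.update(CLS=np.nan, max_TMP=np.nan, tmp_positive_area=np.nan,
                       x_cross=np.nan, filtrate=np.nan, QB_out=np.nan,
                       error=str(exc))
        records.append(rec)
    return pd.DataFrame.from_records(records)
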