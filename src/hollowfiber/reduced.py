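"""Fast quasi-1D counter-current model of one fiber unit.

This is the classic Krogh-type reduction of the representative unit: at each
axial station the lumen and shell are described by their pressures, axial
flows and mixed-cup concentrations, coupled through the membrane source
terms -- the volumetric flux ``Jv = Lp (p_t - p_s)`` and the solute flux
``Js = (1-sigma) Cm Jv + K0 (C_t - C_s)`` acting over the membrane
mid-surface perimeter ``2 pi r_mid``.  Axial pressure gradients follow from
exact Poiseuille resistances: ``8 mu/(pi r1^4)`` per unit length in the
lumen and the closed-form concentric-annulus resistance (no-slip at r2,
zero shear at the outer symmetry radius r3) in the shell.

The model is an independent cross-check for the 2D finite-volume solver
(same membrane physics, entirely different discretization: it resolves no
radial profiles, so it carries no lumen/shell concentration-polarization
resistance) and a fast screening tool for parameter sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, SolverError
from .membrane import volumetric_flux

__all__ = ["AxialProfiles", "annular_shell_conductance", "solve_counter_current"]

ML_MIN = 1e-6 / 60.0


def annular_shell_conductance(r2: float, r3: float) -> float:
    """Poiseuille conductance K of the shell annulus: Q = -(dp/dx) K / mu.

    Closed form for axial flow in a concentric annulus with no slip on the
    inner wall (r2, the fiber surface) and zero shear on the outer radius
    (r3, the symmetry boundary between neighbouring representative units).
    Derivation: w(r) = (G/4mu)(r^2 - r2^2) - (G r3^2/2mu) ln(r/r2) with
    G = dp/dx; integrating 2 pi r w gives
    K = -pi [ (r3^4 - r2^4)/8 + (r3^2 - r2^2)^2/4 - (r3^4/2) ln(r3/r2) ],
    which is positive because the bracket is negative for r3 > r2.
    """
    if not 0 < r2 < r3:
        raise DomainError(f"need 0 < r2 < r3, got r2={r2}, r3={r3}")
    bracket = ((r3**4 - r2**4) / 8.0 + (r3**2 - r2**2) ** 2 / 4.0
               - (r3**4 / 2.0) * math.log(r3 / r2))
    return -math.pi * bracket


@dataclass
class AxialProfiles:
    """Per-station solution of the quasi-1D model (per fiber, SI units)."""

    case: object
    x: np.ndarray          # station centres (m)
    p_tube: np.ndarray     # (Pa)
    p_shell: np.ndarray
    Q_tube: np.ndarray     # station-face axial flows, length n+1 (m^3/s)
    Q_shell: np.ndarray    # signed (negative: toward x=0), length n+1
    C_tube: np.ndarray     # mixed-cup concentrations (mol/m^3)
    C_shell: np.ndarray
    Jv: np.ndarray         # transmembrane volumetric flux (m/s)
    Js: np.ndarray         # transmembrane solute flux (mol m^-2 s^-1)
    iterations: int = 0

    @property
    def tmp(self) -> np.ndarray:
        """Transmembrane pressure profile p_tube - p_shell (Pa)."""
        return self.p_tube - self.p_shell

    @property
    def x_cross(self) -> float | None:
        """Axial position where the TMP changes sign (linear interpolation)."""
        dp = self.tmp
        sign = np.sign(dp)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if len(idx) == 0:
            return None
        k = idx[0]
        f = dp[k] / (dp[k] - dp[k + 1])
        return float(self.x[k] + f * (self.x[k + 1] - self.x[k]))

    @property
    def clearance_mL_min(self) -> float:
        """Module-scale clearance from the station-resolved outlet state."""
        case = self.case
        N = case.geometry.N
        C_in = case.solute.C_in
        if C_in <= 0:
            raise DomainError("clearance undefined for zero inlet concentration")
        QB_in = self.Q_tube[0] * N
        QB_out = self.Q_tube[-1] * N
        CLS = (QB_in * C_in - QB_out * self.C_tube[-1]) / C_in
        return CLS / ML_MIN

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.x, "p_tube": self.p_tube, "p_shell": self.p_shell,
            "tmp": self.tmp,
            "Q_tube": 0.5 * (self.Q_tube[:-1] + self.Q_tube[1:]),
            "Q_shell": 0.5 * (self.Q_shell[:-1] + self.Q_shell[1:]),
            "C_tube": self.C_tube, "C_shell": self.C_shell,
            "Jv": self.Jv, "Js": self.Js,
        })


def solve_counter_current(case, n_stations: int = 400, tol: float = 1e-10,
                          max_iter: int = 500) -> AxialProfiles:
    """Iterate the station equations to a fixed point.

    Pressure/flow and the two upwinded species balances are swept
    alternately (Gauss-Seidel over the counter-current coupling) until the
    maximum relative change of every profile falls below ``tol``.
    """
    if n_stations < 10:
        raise DomainError(f"need at least 10 stations, got {n_stations}")
    g, op, mem, sol = case.geometry, case.operating, case.membrane, case.solute
    n = n_stations
    L = g.L
    dx = L / n
    x = (np.arange(n) + 0.5) * dx
    perim = 2.0 * math.pi * 0.5 * (g.r1 + g.r2)   # membrane mid-surface
    area = perim * dx

    R_tube = 8.0 * op.mu / (math.pi * g.r1**4)        # dp/dx per unit Q
    K_shell = annular_shell_conductance(g.r2, g.r3)
    R_shell = op.mu / K_shell

    QB_f = op.QB_in / g.N
    QD_f = op.QD_in / g.N

    Jv = np.zeros(n)
    C_t = np.full(n, sol.C_in)
    C_s = np.zeros(n)
    p_t = np.zeros(n)
    p_s = np.zeros(n)
    one_m_sig = 1.0 - mem.sigma

    def rel_change(a, b, scale):
        return np.max(np.abs(a - b)) / max(scale, 1e-300)

    for it in range(1, max_iter + 1):
        # --- volume balances (telescoping sums, exact) ---
        Q_t = np.concatenate([[QB_f], QB_f - np.cumsum(Jv) * area])
        Q_s = np.zeros(n + 1)
        Q_s[n] = -QD_f
        Q_s[:n] = -QD_f - (np.cumsum((Jv * area)[::-1])[::-1])

        # --- pressures from per-station Poiseuille resistances ---
        Qt_c = 0.5 * (Q_t[:-1] + Q_t[1:])
        Qs_c = 0.5 * (Q_s[:-1] + Q_s[1:])
        # tube: p(L) = p_out_tube, integrate upstream
        drop_t = R_tube * Qt_c * dx
        p_t_new = op.p_out_tube + (np.cumsum(drop_t[::-1])[::-1])
        # shell: p(0) = p_out_shell; dp/dx = -R_shell * Q_s (> 0 for Q_s < 0)
        incr_s = -R_shell * Qs_c * dx
        p_s_new = op.p_out_shell + np.cumsum(incr_s) - 0.5 * incr_s
        p_t_new = p_t_new - 0.5 * drop_t  # face-to-centre correction

        Jv_new = volumetric_flux(mem.Lp, p_t_new - p_s_new)

        # --- species sweeps (upwind, semi-implicit in the local cell) ---
        C_t_new = C_t.copy()
        C_s_new = C_s.copy()
        a_conv = one_m_sig * Jv_new * 0.5
        for k in range(n):       # tube marches with the flow, x = 0 -> L
            upstream = sol.C_in if k == 0 else C_t_new[k - 1]
            b = (a_conv[k] - mem.K0) * C_s_new[k]
            denom = Q_t[k + 1] + (a_conv[k] + mem.K0) * area
            C_t_new[k] = (Q_t[k] * upstream - b * area) / denom
        for k in range(n - 1, -1, -1):   # shell marches x = L -> 0
            upstream = 0.0 if k == n - 1 else C_s_new[k + 1]
            src = ((a_conv[k] + mem.K0) * C_t_new[k]) * area
            denom = -Q_s[k] * 1.0 + (mem.K0 - a_conv[k]) * area
            C_s_new[k] = ((-Q_s[k + 1]) * upstream + src) / denom

        scale_p = max(np.max(np.abs(p_t_new)), np.max(np.abs(p_s_new)), 1.0)
        change = max(
            rel_change(p_t_new, p_t, scale_p),
            rel_change(C_t_new, C_t, max(sol.C_in, np.max(np.abs(C_t_new)), 1e-300)),
            rel_change(C_s_new, C_s, max(sol.C_in, 1e-300)),
        )
        p_t, p_s, Jv, C_t, C_s = p_t_new, p_s_new, Jv_new, C_t_new, C_s_new
        if change < tol:
            break
    else:
        raise SolverError(
            f"quasi-1D fixed point not converged in {max_iter} iterations "
            f"(last change {change:.3e})")

    Cm = 0.5 * (C_t + C_s)
    Js = one_m_sig * Cm * Jv + mem.K0 * (C_t - C_s)
    return AxialProfiles(case=case, x=x, p_tube=p_t, p_shell=p_s,
                         Q_tube=Q_t, Q_shell=Q_s, C_tube=C_t, C_shell=C_s,
                         Jv=Jv, Js=Js, iterations=it)
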