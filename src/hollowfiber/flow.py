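"""Steady axisymmetric flow and pressure in the three-region unit.

The flow problem is incompressible creeping flow (tube-side Re ~ 2.7 at the
baseline operating point, far below any inertial regime), so the momentum
equations are linearized to Stokes form and augmented with a Darcy drag term
``-mu/alpha * v`` that is active only in membrane-tagged cells (Brinkman
formulation of the porous band).  The axial in-membrane drag coefficient is
``anisotropy_factor`` times the radial one, suppressing axial seepage along
the membrane.

Discretization: finite volumes on a staggered (MAC) arrangement -- pressures
at cell centres, axial velocity u on constant-x faces, radial velocity v on
constant-r faces -- with full axisymmetric 2*pi*r metrics.  The staggered
arrangement is inf-sup stable, so no pressure stabilization is needed, and
because the problem is linear the whole saddle-point system (u, v, p) is
assembled once and solved by a sparse direct factorization: the "converged"
state is exact up to round-off, and residuals are reported by direct
evaluation of the discrete continuity and momentum operators.

Boundary conditions: plug inflow at the tube inlet (x=0, r<r1) and shell
inlet (x=L, r2<r<r3); pressure outlets (zero gauge by default) on the two
opposite ends; symmetry on the axis r=0 and the outer radius r=r3 of the
representative unit; no-slip walls on the fiber-end faces of the membrane
band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DomainError, SolverError
from .grid import Grid

__all__ = ["FlowField", "solve_flow", "darcy_drag"]


def darcy_drag(membrane, mu: float, direction: str = "radial",
               anisotropy_factor: float = 1000.0) -> float:
    """Viscous Darcy drag coefficient ``mu/alpha`` (Pa s / m^2) for one direction.

    The radial coefficient is ``mu * 8 psi / (rp^2 eps)``; the axial one is
    ``anisotropy_factor`` times larger (seepage along the membrane is
    physically blocked by the pore orientation).
    """
    if membrane.alpha < 0:
        raise DomainError("membrane Darcy permeability must be >= 0")
    if membrane.alpha == 0.0:
        return np.inf
    base = mu / membrane.alpha
    if direction == "radial":
        return base
    if direction == "axial":
        return anisotropy_factor * base
    raise DomainError(f"unknown direction {direction!r}")


@dataclass
class FlowField:
    """Converged pressure/velocity solution on the staggered grid.

    p has shape (nx, nr); u (nx+1, nr) on x-faces; v (nx, nr+1) on r-faces.
    ``filtrate_flow`` is the net transmembrane volumetric flow per fiber
    (m^3/s), measured at the membrane mid-surface.
    """

    grid: Grid
    case: object
    p: np.ndarray
    u: np.ndarray
    v: np.ndarray
    residuals: dict = field(default_factory=dict)

    @property
    def filtrate_flow(self) -> float:
        j = self.grid.j_mem_lo + self.grid.nr_mem // 2
        per = self._circ(self.grid.r_faces[j]) * self.grid.dx
        return float(np.sum(self.v[:, j] * per))

    def _circ(self, r) -> float:
        return 2.0 * np.pi * r if self.case.solver.axisymmetric else 1.0

    def _face_areas_x(self) -> np.ndarray:
        g = self.grid
        if self.case.solver.axisymmetric:
            return np.pi * (g.r_faces[1:] ** 2 - g.r_faces[:-1] ** 2)
        return g.dr.copy()

    def tube_flow_at(self, i_face: int) -> float:
        """Volumetric tube-side flow (m^3/s per fiber) through x-face i."""
        Ax = self._face_areas_x()
        jt = slice(0, self.grid.nr_tube)
        return float(np.sum(self.u[i_face, jt] * Ax[jt]))

    def shell_flow_at(self, i_face: int) -> float:
        """Signed shell-side axial flow through x-face i (negative: toward x=0)."""
        Ax = self._face_areas_x()
        js = slice(self.grid.j_mem_hi, self.grid.nr)
        return float(np.sum(self.u[i_face, js] * Ax[js]))

    def transmembrane_velocity(self) -> np.ndarray:
        """Radial (superficial) velocity at the membrane mid-surface, per axial cell."""
        j = self.grid.j_mem_lo + self.grid.nr_mem // 2
        return self.v[:, j].copy()


def solve_flow(grid: Grid, case) -> FlowField:
    """Assemble and directly solve the staggered Stokes-Brinkman system."""
    g = grid
    s = case.solver
    op = case.operating
    mem = case.membrane
    mu = op.mu
    nx, nr = g.nx, g.nr
    axisym = s.axisymmetric

    xc, rc, dx, dr = g.xc, g.rc, g.dx, g.dr
    rf = g.r_faces

    if axisym:
        Ax = np.pi * (rf[1:] ** 2 - rf[:-1] ** 2)        # x-face area per row
        circ_f = 2.0 * np.pi * rf                          # per-length width at r-faces
        circ_c = 2.0 * np.pi * rc                          # ... at row centres
    else:
        Ax = dr.copy()
        circ_f = np.ones(nr + 1)
        circ_c = np.ones(nr)

    # radial sampling points of the u rows: the quadratic-mean ring radius,
    # at which the ring average of any quadratic profile equals its point
    # value -- this makes the discrete developed Poiseuille profile and its
    # pressure gradient exact up to entrance effects
    if axisym:
        rstar = np.sqrt(0.5 * (rf[:-1] ** 2 + rf[1:] ** 2))
    else:
        rstar = rc.copy()

    jm_lo, jm_hi = g.j_mem_lo, g.j_mem_hi
    is_mem_row = g.row_is_membrane()
    impermeable = mem.alpha == 0.0
    if impermeable:
        drag_r = np.where(is_mem_row, np.inf, 0.0)
        drag_x = drag_r
    else:
        drag_r = np.where(is_mem_row, mu / mem.alpha, 0.0)
        drag_x = np.where(is_mem_row, s.anisotropy_factor * mu / mem.alpha, 0.0)

    u_in_t = case.tube_inlet_velocity
    u_in_s = case.shell_inlet_velocity

    n_u = (nx + 1) * nr
    n_v = nx * (nr + 1)
    n_p = nx * nr

    def iu(i, j):
        return i * nr + j

    def iv(i, j):
        return n_u + i * (nr + 1) + j

    def ip(i, j):
        return n_u + n_v + i * nr + j

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_u + n_v + n_p)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # du/dr stencils at interior radial faces, per band.  Inside the tube and
    # shell bands a three-point Lagrange derivative evaluated AT the face is
    # used: it is exact for the parabolic (and any quadratic) developed
    # profile, which keeps the discrete Poiseuille resistances accurate on
    # the stretched grid.  Membrane-interior faces keep the two-point form
    # (the axial velocity there is drag-suppressed to ~0).
    def _deriv3(w, xs):
        x0, x1, x2 = xs
        return (
            ((w - x1) + (w - x2)) / ((x0 - x1) * (x0 - x2)),
            ((w - x0) + (w - x2)) / ((x1 - x0) * (x1 - x2)),
            ((w - x0) + (w - x1)) / ((x2 - x0) * (x2 - x1)),
        )

    grad_stencil = {}
    for f in range(1, nr):
        lo_row, hi_row = f - 1, f
        if f in (jm_lo, jm_hi):      # membrane surfaces handled as walls
            continue
        same_band = (hi_row < jm_lo) or (jm_lo <= lo_row and hi_row < jm_hi) \
            or (lo_row >= jm_hi)
        band_lo, band_hi = (0, jm_lo - 1) if hi_row < jm_lo else (
            (jm_lo, jm_hi - 1) if hi_row < jm_hi else (jm_hi, nr - 1))
        in_mem = jm_lo <= lo_row < jm_hi
        if same_band and not in_mem and band_hi - band_lo >= 2:
            j2 = f + 1 if f + 1 <= band_hi else f - 2
            rows3 = sorted((f - 1, f, j2))
            coefs = _deriv3(rf[f], [rstar[k] for k in rows3])
            grad_stencil[f] = list(zip(rows3, coefs))
        else:
            d = rstar[f] - rstar[f - 1]
            grad_stencil[f] = [(f - 1, -1.0 / d), (f, 1.0 / d)]

    # ---------------- u-momentum ----------------
    for j in range(nr):
        tube_row = j < jm_lo
        mem_row = jm_lo <= j < jm_hi
        for i in range(nx + 1):
            r = iu(i, j)
            # Dirichlet nodes: inlets and fiber-end membrane walls
            if i == 0 and tube_row:
                add(r, r, 1.0)
                rhs[r] = u_in_t
                continue
            if i == 0 and mem_row:
                add(r, r, 1.0)
                continue
            if i == nx and mem_row:
                add(r, r, 1.0)
                continue
            if i == nx and not tube_row and not mem_row:
                add(r, r, 1.0)
                rhs[r] = -u_in_s
                continue
            if mem_row and impermeable:
                add(r, r, 1.0)
                continue
            # control volume extent in x
            xl = xc[i - 1] if i > 0 else g.x_faces[0]
            xr = xc[i] if i < nx else g.x_faces[nx]
            dxu = xr - xl
            diag = 0.0
            # axial diffusion (zero-gradient at outlet boundaries)
            if i < nx:
                c = mu * Ax[j] / dx[i]
                add(r, iu(i + 1, j), c)
                diag -= c
            if i > 0:
                c = mu * Ax[j] / dx[i - 1]
                add(r, iu(i - 1, j), c)
                diag -= c
            # radial diffusion (axis and outer symmetry: zero shear flux).
            # The two membrane surfaces are tangential no-slip faces: the
            # Brinkman screening depth sqrt(alpha) ~ nm is far below the cell
            # size, so axial velocity vanishes AT r1 and r2, not half a cell
            # beyond them.
            if j < nr - 1:
                if j + 1 == jm_lo and j >= 1:
                    # tube row under the membrane surface: one-sided
                    # quadratic wall gradient through (rc[j-1], rc[j], r1)
                    # keeps the discrete Poiseuille resistance second order
                    w, b, a = rf[j + 1], rstar[j], rstar[j - 1]
                    ca = (w - b) / ((a - b) * (a - w))
                    cb = (w - a) / ((b - a) * (b - w))
                    coef = mu * circ_f[j + 1] * dxu
                    add(r, iu(i, j - 1), coef * ca)
                    diag += coef * cb
                elif j + 1 in (jm_lo, jm_hi):
                    diag -= mu * circ_f[j + 1] * dxu / (rf[j + 1] - rstar[j])
                else:
                    coef = mu * circ_f[j + 1] * dxu
                    for jr, cf in grad_stencil[j + 1]:
                        if jr == j:
                            diag += coef * cf
                        else:
                            add(r, iu(i, jr), coef * cf)
            if j > 0:
                if j == jm_hi and j < nr - 1:
                    # shell row above the membrane surface: quadratic wall
                    # gradient through (r2, rc[j], rc[j+1]); force enters
                    # with the opposite sign on the inward-normal face
                    w, b, a = rf[j], rstar[j], rstar[j + 1]
                    ca = (w - b) / ((a - b) * (a - w))
                    cb = (w - a) / ((b - a) * (b - w))
                    coef = mu * circ_f[j] * dxu
                    add(r, iu(i, j + 1), -coef * ca)
                    diag -= coef * cb
                elif j in (jm_lo, jm_hi):
                    diag -= mu * circ_f[j] * dxu / (rstar[j] - rf[j])
                else:
                    coef = mu * circ_f[j] * dxu
                    for jr, cf in grad_stencil[j]:
                        if jr == j:
                            diag -= coef * cf
                        else:
                            add(r, iu(i, jr), -coef * cf)
            # Darcy drag (membrane rows only)
            diag -= drag_x[j] * Ax[j] * dxu if drag_x[j] else 0.0
            add(r, r, diag)
            # pressure gradient
            if i == 0:       # outlet at x=0 (shell rows)
                add(r, ip(0, j), -Ax[j])
                rhs[r] += -Ax[j] * op.p_out_shell
            elif i == nx:    # outlet at x=L (tube rows)
                add(r, ip(nx - 1, j), Ax[j])
                rhs[r] += Ax[j] * op.p_out_tube
            else:
                add(r, ip(i - 1, j), Ax[j])
                add(r, ip(i, j), -Ax[j])

    # ---------------- v-momentum ----------------
    for j in range(nr + 1):
        for i in range(nx):
            r = iv(i, j)
            if j == 0 or j == nr:  # axis / outer symmetry
                add(r, r, 1.0)
                continue
            touches_mem = (jm_lo <= j <= jm_hi)
            if impermeable and touches_mem:
                add(r, r, 1.0)
                continue
            drv = rc[j] - rc[j - 1]
            volv = circ_f[j] * drv * dx[i]
            diag = 0.0
            # radial diffusion
            c = mu * circ_c[j] * dx[i] / dr[j]
            add(r, iv(i, j + 1), c)
            diag -= c
            c = mu * circ_c[j - 1] * dx[i] / dr[j - 1]
            add(r, iv(i, j - 1), c)
            diag -= c
            # axial diffusion; boundary segments: no-slip (inlets/walls) or
            # zero-gradient (outlets)
            if i < nx - 1:
                c = mu * circ_f[j] * drv / (xc[i + 1] - xc[i])
                add(r, iv(i + 1, j), c)
                diag -= c
            elif rf[j] >= g.r1:  # x=L: shell inlet / membrane wall -> v=0
                diag -= mu * circ_f[j] * drv / (0.5 * dx[nx - 1])
            if i > 0:
                c = mu * circ_f[j] * drv / (xc[i] - xc[i - 1])
                add(r, iv(i - 1, j), c)
                diag -= c
            elif rf[j] <= g.r2:  # x=0: tube inlet / membrane wall -> v=0
                diag -= mu * circ_f[j] * drv / (0.5 * dx[0])
            # curvature term -mu v / r^2 (axisymmetric only)
            if axisym:
                diag -= mu * volv / rf[j] ** 2
            # Darcy drag, volume-weighted over the two half-CVs
            wl, wu = rf[j] - rc[j - 1], rc[j] - rf[j]
            dragv = (drag_r[j - 1] * wl + drag_r[j] * wu) / (wl + wu)
            diag -= dragv * volv if dragv else 0.0
            add(r, r, diag)
            # pressure gradient
            ar = circ_f[j] * dx[i]
            add(r, ip(i, j - 1), ar)
            add(r, ip(i, j), -ar)

    # ---------------- continuity ----------------
    for j in range(nr):
        if impermeable and jm_lo <= j < jm_hi:
            # solid membrane: all cell velocities are Dirichlet zero and the
            # pressure is decoupled; pin it to zero gauge
            for i in range(nx):
                r = ip(i, j)
                add(r, r, 1.0)
            continue
        for i in range(nx):
            r = ip(i, j)
            add(r, iu(i + 1, j), Ax[j])
            add(r, iu(i, j), -Ax[j])
            add(r, iv(i, j + 1), circ_f[j + 1] * dx[i])
            add(r, iv(i, j), -circ_f[j] * dx[i])

    A = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_u + n_v + n_p, n_u + n_v + n_p))
    # row equilibration: the saddle-point blocks span many orders of magnitude
    scale = 1.0 / np.maximum(np.abs(A).max(axis=1).toarray().ravel(), 1e-300)
    D = sp.diags(scale)
    sol = spla.spsolve((D @ A).tocsc(), scale * rhs)
    if not np.all(np.isfinite(sol)):
        raise SolverError("direct Stokes solve returned non-finite values")

    u = sol[:n_u].reshape(nx + 1, nr)
    v = sol[n_u:n_u + n_v].reshape(nx, nr + 1)
    p = sol[n_u + n_v:].reshape(nx, nr)

    # residual audit on the unscaled operator
    res = A @ sol - rhs
    div = res[n_u + n_v:]
    q_ref = max(abs(u_in_t) * Ax[:jm_lo].sum(), abs(u_in_s) * Ax[jm_hi:].sum(),
                1e-300)
    residuals = {
        "continuity_max": float(np.max(np.abs(div)) / q_ref),
        "momentum_max": float(np.max(np.abs(res[:n_u + n_v]))),
    }

    field_ = FlowField(grid=g, case=case, p=p, u=u, v=v, residuals=residuals)
    qt_in = field_.tube_flow_at(0)
    qt_out = field_.tube_flow_at(nx)
    residuals["tube_balance"] = abs(qt_in - qt_out - field_.filtrate_flow) / max(
        abs(qt_in), 1e-300)
    return field_
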