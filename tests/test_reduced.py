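"""Quasi-1D counter-current model: closures, conservation, cross-model check."""

import dataclasses
import math

import numpy as np
import pytest

import hollowfiber as hf
from hollowfiber.reduced import annular_shell_conductance



def test_annular_conductance_against_bvp_oracle():
    """Closed-form annulus conductance vs an independent finite-difference
    solve of mu (1/r)(r w')' = dp/dx with w(r2)=0, w'(r3)=0."""
    r2, r3, mu, G = 1.45e-4, 2.10e-4, 1e-3, -1.0
    n = 4000
    r = np.linspace(r2, r3, n + 1)
    h = r[1] - r[0]
    rf = 0.5 * (r[:-1] + r[1:])
    # tridiagonal FV: (r w')' = G r / mu
    main = np.zeros(n + 1)
    lower = np.zeros(n)
    upper = np.zeros(n)
    rhs = np.zeros(n + 1)
    main[0] = 1.0                     # w(r2) = 0
    for k in range(1, n):
        main[k] = -(rf[k - 1] + rf[k]) / h
        lower[k - 1] = rf[k - 1] / h
        upper[k] = rf[k] / h
        rhs[k] = G * r[k] * h / mu
    main[n] = 1.0 / h                 # w'(r3) = 0
    lower[n - 1] = -1.0 / h
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla
    A = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    w = spla.spsolve(A, rhs)
    Q = np.trapezoid(2 * math.pi * r * w, r)
    K_oracle = Q * mu / (-G)
    assert annular_shell_conductance(r2, r3) == pytest.approx(K_oracle, rel=1e-4)


def test_closed_membrane_gives_pure_poiseuille():
    case = hf.builtin_case("baseline_urea")
    mem = dataclasses.replace(case.membrane, Lp=0.0, K0=0.0, D0=0.0)
    case = dataclasses.replace(case, membrane=mem)
    prof = hf.solve_counter_current(case, n_stations=200)
    assert prof.clearance_mL_min == pytest.approx(0.0, abs=1e-10)
    # tube pressure: linear with total drop 8 mu L Q_f/(pi r1^4) ~ 2865 Pa
    g, op = case.geometry, case.operating
    dp_ref = 8 * op.mu * g.L * (op.QB_in / g.N) / (math.pi * g.r1**4)
    p_lin = dp_ref * (1 - prof.x / g.L)
    assert np.max(np.abs(prof.p_tube - p_lin)) < 1e-8 * dp_ref
    assert np.all(prof.Jv == 0.0)


def test_volume_balance_telescopes_exactly():
    case = hf.builtin_case("baseline_bilirubin")
    prof = hf.solve_counter_current(case, n_stations=200)
    g = case.geometry
    area = 2 * math.pi * 0.5 * (g.r1 + g.r2) * (g.L / 200)
    lost = prof.Q_tube[0] - prof.Q_tube[-1]
    assert lost == pytest.approx(np.sum(prof.Jv) * area, rel=1e-12)
    gained = -prof.Q_shell[0] - (-prof.Q_shell[-1])
    assert gained == pytest.approx(lost, rel=1e-12)


def test_solute_balance_closes():
    case = hf.builtin_case("baseline_bilirubin")
    n = 200
    prof = hf.solve_counter_current(case, n_stations=n)
    g = case.geometry
    area = 2 * math.pi * 0.5 * (g.r1 + g.r2) * (g.L / n)
    tube_in = prof.Q_tube[0] * case.solute.C_in
    tube_out = prof.Q_tube[-1] * prof.C_tube[-1]
    shell_out = -prof.Q_shell[0] * prof.C_shell[0]
    transferred = np.sum(prof.Js) * area
    assert tube_in - tube_out == pytest.approx(transferred, rel=1e-8)
    assert shell_out == pytest.approx(transferred, rel=1e-8)


def test_tmp_crosses_zero_exactly_once_at_baseline():
    case = hf.builtin_case("baseline_bilirubin")
    prof = hf.solve_counter_current(case)
    sign_changes = np.nonzero(np.diff(np.sign(prof.tmp)))[0]
    assert len(sign_changes) == 1
    assert 0.1 < prof.x_cross < 0.25


def test_pressure_profiles_linear_when_filtration_weak():
    case = hf.builtin_case("baseline_urea")
    prof = hf.solve_counter_current(case)
    for p in (prof.p_tube, prof.p_shell):
        coef = np.polyfit(prof.x, p, 1)
        resid = p - np.polyval(coef, prof.x)
        r2 = 1 - (resid**2).sum() / ((p - p.mean())**2).sum()
        assert r2 > 0.999


def test_cross_model_agreement_with_2d_solver(urea_coarse):
    """The Krogh-type reduction lands within 15% of the resolved 2D clearance."""
    case, grid, fl, cc = urea_coarse
    cls_2d = hf.clearance(fl, cc, case).CLS
    cls_1d = hf.solve_counter_current(case).clearance_mL_min
    assert abs(cls_1d - cls_2d) / cls_2d < 0.15
    # and both see the TMP sign change at the same location
    x1 = hf.solve_counter_current(case).x_cross
    x2 = hf.tmp_profile(fl, grid).x_cross
    assert x1 == pytest.approx(x2, rel=0.05)


def test_clearance_monotone_in_tube_flow_and_length():
    base = hf.builtin_case("baseline_bilirubin")
    ML = hf.config.ML_MIN
    cls_q = [hf.solve_counter_current(hf.rebuild(base, QB_in=q * ML),
                                      n_stations=200).clearance_mL_min
             for q in (200, 300, 400, 500, 600)]
    assert np.all(np.diff(cls_q) > 0)
    cls_L = [hf.solve_counter_current(hf.rebuild(base, L=L * 1e-3),
                                      n_stations=200).clearance_mL_min
             for L in (270, 324, 388.8, 466.56, 559.872)]
    assert np.all(np.diff(cls_L) > 0)


def test_too_few_stations_rejected():
    with pytest.raises(hf.DomainError):
        hf.solve_counter_current(hf.builtin_case("baseline_urea"), n_stations=5)
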