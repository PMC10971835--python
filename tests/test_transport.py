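"""Hindered convection-diffusion: conservation, boundedness, K-K closure."""

import dataclasses

import numpy as np
import pytest

import hollowfiber as hf
from hollowfiber.benchmarks import impermeable_membrane
from hollowfiber.grid import grid_for_case
from hollowfiber.transport import membrane_flux_audit

from conftest import coarse_case


def _solve(case):
    grid = grid_for_case(case)
    fl = hf.solve_flow(grid, case)
    return grid, fl, hf.solve_concentration(grid, fl, case)


class TestConservation:
    def test_zero_inlet_concentration_gives_zero_field(self):
        case = coarse_case("baseline_bilirubin")
        case = hf.rebuild(case, solute=dataclasses.replace(case.solute, C_in=0.0))
        _, _, cc = _solve(case)
        assert np.max(np.abs(cc.Cb)) == 0.0

    def test_impermeable_membrane_conserves_tube_stream(self):
        """With a closed membrane the feed leaves unchanged: zero clearance."""
        base = coarse_case("baseline_urea")
        case = dataclasses.replace(
            base, membrane=impermeable_membrane(base.geometry))
        grid, fl, cc = _solve(case)
        cl = hf.clearance(fl, cc, case)
        out_mixed = cc.boundary_fluxes["tube_outflow"] / fl.tube_flow_at(grid.nx)
        assert out_mixed == pytest.approx(case.solute.C_in, rel=1e-6)
        assert abs(cl.CLS) < 1e-6 * cl.QB_in

    @pytest.mark.parametrize("fixture", ["urea_coarse", "bilirubin_coarse",
                                         "bsa_coarse"])
    def test_solute_mass_balance_closes(self, fixture, request):
        _, _, _, cc = request.getfixturevalue(fixture)
        assert cc.mass_balance_residual < 1e-4

    def test_tube_inflow_splits_into_the_two_outlets(self, bilirubin_coarse):
        _, _, _, cc = bilirubin_coarse
        bf = cc.boundary_fluxes
        total_out = (bf["tube_outflow"] + bf["shell_outflow"]
                     + bf["shell_inlet_diffusive"])
        assert total_out == pytest.approx(bf["tube_inflow"], rel=1e-4)


class TestBoundedness:
    def test_discrete_maximum_principle_upwind(self, bilirubin_upwind_coarse):
        """The bounded scheme keeps 0 <= C <= C_in everywhere."""
        case, _, _, cc = bilirubin_upwind_coarse
        C_in = case.solute.C_in
        assert cc.Cb.min() >= -1e-12 * C_in
        assert cc.Cb.max() <= C_in * (1 + 1e-9)

    def test_station_mean_tube_concentration_decays_downstream(
            self, bilirubin_upwind_coarse):
        case, grid, fl, cc = bilirubin_upwind_coarse
        jt = slice(0, grid.nr_tube)
        mean = cc.Cb[:, jt].mean(axis=1)
        assert np.all(np.diff(mean) <= 1e-9 * case.solute.C_in)

    def test_concentration_falls_across_membrane_where_tmp_positive(
            self, bilirubin_coarse):
        case, grid, fl, cc = bilirubin_coarse
        tmp = fl.p[:, 0] - fl.p[:, -1]
        jm_lo, jm_hi = grid.j_mem_lo, grid.j_mem_hi
        pos = tmp > 0.05 * tmp.max()
        inner = cc.Cb[pos, jm_lo]       # first membrane row
        outer = cc.Cb[pos, jm_hi - 1]   # last membrane row
        assert np.all(inner >= outer)


class TestMembraneFluxAudit:
    def test_impermeable_membrane_zero_fluxes(self):
        base = coarse_case("baseline_urea")
        case = dataclasses.replace(
            base, membrane=impermeable_membrane(base.geometry))
        grid, fl, cc = _solve(case)
        assert np.max(np.abs(fl.transmembrane_velocity())) < 1e-20

    def test_resolved_flux_matches_kk_closure(self, bilirubin_coarse):
        """Station-wise K-K reconciliation within 10% over the central 80%."""
        case, grid, fl, cc = bilirubin_coarse
        audit = membrane_flux_audit(cc, fl, case.membrane)
        n = len(audit)
        central = audit.iloc[int(0.1 * n):int(0.9 * n)]
        assert central.rel_discrepancy.max() < 0.10

    def test_convective_sign_flip_collocated_with_tmp_crossing(
            self, bilirubin_coarse):
        case, grid, fl, cc = bilirubin_coarse
        audit = membrane_flux_audit(cc, fl, case.membrane)
        conv = (1 - case.membrane.sigma) * audit.Jv_mid * 0.5 * (
            audit.C_r1 + audit.C_r2)
        flips = np.nonzero(np.diff(np.sign(conv)))[0]
        x_cross = hf.tmp_profile(fl, grid).x_cross
        assert len(flips) == 1
        dx = grid.dx[0]
        assert abs(grid.xc[flips[0]] - x_cross) < 2 * dx


class TestConvectiveVsDiffusiveTransport:
    def test_macromolecule_clearance_dominated_by_convection(
            self, bilirubin_coarse, bsa_coarse):
        """Removing membrane diffusion (K0 = 0) barely affects BSA clearance
        but collapses bilirubin clearance."""
        drops = {}
        for name, bundle in (("bilirubin", bilirubin_coarse),
                             ("bsa", bsa_coarse)):
            case, grid, fl, cc = bundle
            full = hf.clearance(fl, cc, case).CLS
            mem0 = dataclasses.replace(case.membrane, D0=0.0, K0=0.0)
            case0 = dataclasses.replace(case, membrane=mem0)
            cc0 = hf.solve_concentration(grid, fl, case0)
            conv_only = hf.clearance(fl, cc0, case0).CLS
            drops[name] = (full - conv_only) / full
        assert drops["bsa"] < drops["bilirubin"]
        assert drops["bilirubin"] > 0.5      # bilirubin needs diffusion
        assert drops["bsa"] < 0.9            # BSA retains most of its clearance


class TestPreconditions:
    def test_unconverged_flow_rejected(self, bilirubin_coarse):
        case, grid, fl, _ = bilirubin_coarse
        bad = hf.FlowField(grid=grid, case=case, p=fl.p, u=fl.u, v=fl.v,
                           residuals={"continuity_max": 1.0})
        with pytest.raises(hf.PreconditionError):
            hf.solve_concentration(grid, bad, case)
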