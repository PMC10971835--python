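"""Clearance evaluation, TMP profiles, and sweep machinery."""

import dataclasses

import numpy as np
import pytest

import hollowfiber as hf
from hollowfiber.analysis import clearance_formula, run_sweep

from conftest import coarse_case


class TestClearanceFormula:
    def test_unchanged_stream_has_zero_clearance(self):
        assert clearance_formula(300.0, 300.0, 1.0, 1.0) == 0.0

    def test_direct_evaluation(self):
        # flow-weighted definition: (300*1 - 290*0.9)/1
        assert clearance_formula(300.0, 290.0, 1.0, 0.9) == pytest.approx(39.0)

    def test_zero_inlet_concentration_rejected(self):
        with pytest.raises(hf.DomainError):
            clearance_formula(300.0, 290.0, 0.0, 0.0)


class TestClearanceFromFields:
    def test_bounded_by_feed_flow(self, bilirubin_coarse):
        case, grid, fl, cc = bilirubin_coarse
        cl = hf.clearance(fl, cc, case)
        assert 0 <= cl.CLS <= cl.QB_in
        assert cl.QB_in == pytest.approx(300.0, rel=1e-6)

    def test_small_molecule_clears_faster_than_macromolecule(
            self, bilirubin_coarse, bsa_coarse):
        cl_b = hf.clearance(bilirubin_coarse[2], bilirubin_coarse[3],
                            bilirubin_coarse[0])
        cl_a = hf.clearance(bsa_coarse[2], bsa_coarse[3], bsa_coarse[0])
        assert cl_b.CLS > cl_a.CLS

    def test_zero_inlet_concentration_rejected(self, bilirubin_coarse):
        case, grid, fl, cc = bilirubin_coarse
        bad = hf.rebuild(case, solute=dataclasses.replace(case.solute,
                                                          C_in=0.0))
        with pytest.raises(hf.DomainError):
            hf.clearance(fl, cc, bad)


class TestTMPProfile:
    def test_no_flow_has_flat_zero_profile(self):
        case = hf.rebuild(coarse_case("baseline_urea"), QB_in=0.0, QD_in=0.0)
        from hollowfiber.grid import grid_for_case
        grid = grid_for_case(case)
        fl = hf.solve_flow(grid, case)
        tmp = hf.tmp_profile(fl, grid)
        assert np.all(tmp.dp == 0.0)
        assert tmp.x_cross is None

    def test_baseline_crossing_location(self, bilirubin_coarse):
        """Counter-current baseline: TMP changes sign near 2/3 of the length."""
        case, grid, fl, _ = bilirubin_coarse
        tmp = hf.tmp_profile(fl, grid)
        assert tmp.x_cross == pytest.approx(0.175, rel=0.10)
        assert tmp.max_positive > 0
        assert tmp.dp[0] > 0 > tmp.dp[-1]


class TestRunSweep:
    @pytest.fixture(scope="class")
    def tiny_base(self):
        # very coarse: sweeps do one full solve per value
        case = hf.builtin_case("baseline_bilirubin")
        solver = dataclasses.replace(case.solver, nx=60, nr_tube=6, nr_mem=4,
                                     nr_shell=6)
        return dataclasses.replace(case, solver=solver)

    def test_tube_flow_sweep_monotone_clearance_and_tmp(self, tiny_base):
        table = run_sweep(tiny_base, "tube_flow", [200, 400, 600])
        assert list(table.value) == [200, 400, 600]
        assert (table.error == "").all()
        assert np.all(np.diff(table.CLS) > 0)
        assert np.all(np.diff(table.max_TMP) > 0)

    def test_shell_flow_sweep_shrinks_filtration_region(self, tiny_base):
        """More dialysate flow raises shell pressure: the TMP sign change
        moves toward the feed inlet and the positive-TMP area shrinks."""
        table = run_sweep(tiny_base, "shell_flow", [100, 500, 900])
        assert np.all(np.diff(table.x_cross) < 0)
        assert np.all(np.diff(table.tmp_positive_area) < 0)

    def test_length_sweep_values_and_monotonicity(self, tiny_base):
        lengths = [270, 324, 388.8, 466.56, 559.872]   # ratio 1.2 ladder
        table = run_sweep(tiny_base, "length", lengths)
        assert np.allclose(table.value, lengths)
        assert np.all(np.diff(table.CLS) > 0)

    def test_failures_recorded_and_sweep_continues(self, tiny_base):
        table = run_sweep(tiny_base, "tube_flow", [-100, 300])
        assert table.error.iloc[0] != ""
        assert np.isnan(table.CLS.iloc[0])
        assert table.error.iloc[1] == "" and table.CLS.iloc[1] > 0

    def test_unknown_parameter_rejected(self, tiny_base):
        with pytest.raises(hf.DomainError):
            run_sweep(tiny_base, "porosity", [0.1])
        with pytest.raises(hf.DomainError):
            run_sweep(tiny_base, "tube_flow", [])
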