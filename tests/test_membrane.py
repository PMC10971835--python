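"""TCPDM coefficients, hindrance factors, and Kedem-Katchalsky fluxes.

Frozen expected values were computed with independent arithmetic (direct
evaluation of the closed-form expressions at the baseline membrane/solute
parameters) before being asserted here.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hollowfiber as hf
from hollowfiber.membrane import darcy_permeability

RP = 19.75e-9      # pore radius (m), from 39.5 nm pore diameter
EPS, PSI, DELTA, MU = 0.1, 2.27, 45e-6, 1.0e-3
RS_BSA, RS_BILI = 3.61e-9, 0.5e-9


class Solute:
    def __init__(self, rs, Ds):
        self.rs, self.Ds = rs, Ds


class TestDiffusivityCorrelation:
    @pytest.mark.parametrize("MW, expected", [
        (584.66, 4.810e-10),    # bilirubin
        (67000.0, 3.5117e-11),  # BSA
    ])
    def test_reproduces_published_values(self, MW, expected):
        assert hf.diffusivity_from_MW(MW) == pytest.approx(expected, rel=5e-4)

    def test_unit_molecular_weight(self):
        # MW**-0.552 = 1, so the value is the bare prefactor in m^2/s
        assert hf.diffusivity_from_MW(1.0) == pytest.approx(1.62e-8)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(hf.DomainError):
            hf.diffusivity_from_MW(0.0)


class TestHindranceFactors:
    def test_point_solute_limit(self):
        h = hf.hindrance_factors(0.0, RP)
        assert h.q == 0.0 and h.Fq == 1.0 and h.SD == 1.0

    @pytest.mark.parametrize("rs, q, Fq, SD", [
        (RS_BSA, 0.182785, 0.62776, 0.66784),
        (RS_BILI, 0.0253165, 0.94674, 0.95001),
    ])
    def test_baseline_solutes(self, rs, q, Fq, SD):
        h = hf.hindrance_factors(rs, RP)
        assert h.q == pytest.approx(q, rel=1e-4)
        assert h.Fq == pytest.approx(Fq, rel=1e-4)
        assert h.SD == pytest.approx(SD, rel=1e-4)

    def test_excluded_solute(self):
        with pytest.raises(hf.DomainError, match="excluded"):
            hf.hindrance_factors(RP, RP)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(1e-6, 0.999))
    def test_factors_bounded(self, q):
        h = hf.hindrance_factors(q * RP, RP)
        assert 0 < h.Fq <= 1
        assert 0 < h.SD <= 1

    def test_strictly_decreasing_in_q(self):
        qs = np.linspace(1e-4, 0.99, 200)
        Fq = [hf.hindrance_factors(q * RP, RP).Fq for q in qs]
        SD = [hf.hindrance_factors(q * RP, RP).SD for q in qs]
        assert np.all(np.diff(Fq) < 0)
        assert np.all(np.diff(SD) < 0)


class TestReflectionCoefficient:
    def test_point_solute(self):
        assert hf.reflection_coefficient(0.0, RP) == 0.0

    @pytest.mark.parametrize("rs, sigma", [
        (RS_BSA, 0.065703),
        (RS_BILI, 0.0012811),  # "very small" for small solutes in ~20 nm pores
    ])
    def test_baseline_solutes(self, rs, sigma):
        assert hf.reflection_coefficient(rs, RP) == pytest.approx(sigma, rel=1e-3)

    def test_strictly_increasing_in_q(self):
        qs = np.linspace(1e-4, 0.99, 200)
        sig = [hf.reflection_coefficient(q * RP, RP) for q in qs]
        assert np.all(np.diff(sig) > 0)

    def test_alternative_form_differs(self):
        quad = hf.reflection_coefficient(RS_BSA, RP, form="quadratic")
        lin = hf.reflection_coefficient(RS_BSA, RP, form="linear_defect")
        assert lin == pytest.approx(1 - (1 - 0.182785) ** 2, rel=1e-4)
        assert lin > quad  # the alternative form rejects far more strongly


class TestMembraneCoefficients:
    def test_baseline_hydraulic_permeability(self):
        mem = hf.membrane_coefficients(RP, EPS, PSI, DELTA,
                                       Solute(RS_BILI, 4.810e-10), MU)
        assert mem.Lp == pytest.approx(4.7732e-11, rel=1e-4)
        assert mem.alpha == pytest.approx(2.1479e-18, rel=1e-4)

    def test_bilirubin_effective_diffusivity(self):
        mem = hf.membrane_coefficients(RP, EPS, PSI, DELTA,
                                       Solute(RS_BILI, 4.810e-10), MU)
        assert mem.D0 == pytest.approx(1.9058e-10, rel=1e-3)
        assert mem.K0 == pytest.approx(4.2351e-6, rel=1e-3)

    def test_straight_pore_point_solute_limit(self):
        mem = hf.membrane_coefficients(RP, EPS, 1.0, DELTA,
                                       Solute(0.0, 4.810e-10), MU)
        assert mem.D0 == pytest.approx(4.810e-10)
        assert mem.Lp == pytest.approx(RP**2 * EPS / (8 * MU * DELTA))

    def test_effective_diffusivity_below_bulk(self):
        for rs in (0.0, RS_BILI, RS_BSA):
            for psi in (1.0, 1.5, 2.27, 5.0):
                if rs == 0.0 and psi == 1.0:
                    continue
                mem = hf.membrane_coefficients(RP, EPS, psi, DELTA,
                                               Solute(rs, 4.810e-10), MU)
                assert mem.D0 < 4.810e-10

    def test_lp_scaling_over_parameter_lattice(self):
        base = hf.membrane_coefficients(RP, EPS, PSI, DELTA,
                                        Solute(RS_BILI, 4.810e-10), MU)
        for k in (0.5, 2.0, 3.0):
            assert hf.membrane_coefficients(
                RP, k * EPS if k * EPS <= 1 else EPS, PSI, DELTA,
                Solute(RS_BILI, 4.810e-10), MU).Lp == pytest.approx(
                    base.Lp * (k if k * EPS <= 1 else 1), rel=1e-12)
            assert hf.membrane_coefficients(
                np.sqrt(k) * RP, EPS, PSI, DELTA,
                Solute(RS_BILI, 4.810e-10), MU).Lp == pytest.approx(
                    base.Lp * k, rel=1e-12)
            assert hf.membrane_coefficients(
                RP, EPS, k * PSI, DELTA,
                Solute(RS_BILI, 4.810e-10), MU).Lp == pytest.approx(
                    base.Lp / k, rel=1e-12)
            assert hf.membrane_coefficients(
                RP, EPS, PSI, k * DELTA,
                Solute(RS_BILI, 4.810e-10), MU).Lp == pytest.approx(
                    base.Lp / k, rel=1e-12)

    def test_darcy_slab_consistency_with_lp(self):
        """Darcy flow through the slab equals Lp*dp to machine precision."""
        mem = hf.membrane_coefficients(RP, EPS, PSI, DELTA,
                                       Solute(RS_BILI, 4.810e-10), MU)
        dp = 2865.0
        v_darcy = mem.alpha * dp / (MU * DELTA)
        assert v_darcy == pytest.approx(mem.Lp * dp, rel=1e-12)

    def test_impermeable_limit(self):
        assert darcy_permeability(RP, EPS, 1e12) < 1e-29


class TestFluxLaws:
    def test_volumetric_flux_zero_and_sign(self):
        assert hf.volumetric_flux(4.773e-11, 0.0) == 0.0
        assert hf.volumetric_flux(4.773e-11, -100.0) < 0

    def test_volumetric_flux_magnitude(self):
        # Lp at baseline times the largest reported TMP
        assert hf.volumetric_flux(4.773e-11, 5389.02) == pytest.approx(
            2.572e-7, rel=1e-3)

    def test_solute_flux_decomposition(self):
        Jv, sigma, Cm, K0, dC = 2.572e-7, 0.001281, 0.05, 4.235e-6, 0.1
        expected = (1 - sigma) * Cm * Jv + K0 * dC  # independent arithmetic
        assert expected == pytest.approx(4.364e-7, rel=1e-3)
        assert hf.solute_flux(Jv, sigma, Cm, K0, dC) == pytest.approx(expected)

    def test_full_rejection_leaves_diffusion_only(self):
        assert hf.solute_flux(1e-7, 1.0, 0.05, 4.235e-6, 0.1) == pytest.approx(
            4.235e-7)

    def test_zero_drivers(self):
        assert hf.solute_flux(0.0, 0.1, 0.05, 4.235e-6, 0.0) == 0.0

    def test_negative_mean_concentration_rejected(self):
        with pytest.raises(hf.DomainError):
            hf.solute_flux(1e-7, 0.1, -0.05, 4.235e-6, 0.1)
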