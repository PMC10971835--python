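"""Membrane transport coefficients and transmembrane flux laws.

This module is the single home of the phenomenological membrane physics:

* the Kedem-Katchalsky flux pair for a porous membrane,

  .. math::

      J_v = L_p\\,\\Delta p, \\qquad
      J_s = (1-\\sigma)\\,C_m\\,J_v + K_0\\,\\Delta C,

  where the osmotic term ``sigma*R*T*dC`` in :math:`J_v` is dropped because the
  reflection coefficient is tiny for pores of ~20 nm radius and larger;

* the tortuous-capillary pore-diffusion closure (TCPDM) that expresses the
  membrane coefficients through pore radius :math:`r_p`, porosity
  :math:`\\varepsilon`, tortuosity :math:`\\psi` and thickness
  :math:`\\Delta\\delta`:

  .. math::

      L_p = \\frac{r_p^2 \\varepsilon}{8 \\psi \\mu \\Delta\\delta}, \\qquad
      D_0 = \\frac{D_s F(q) S_D}{\\psi}, \\qquad
      K_0 = \\frac{D_0}{\\Delta\\delta},

  with hindrance factors evaluated at the size ratio :math:`q = r_s/r_p`;

* the Stokes-Einstein-type molecular-weight correlation for the bulk
  diffusivity of biomolecules, ``D = 1.62e-4 * MW**-0.552`` in cm^2/s.

All quantities are strict SI internally (m, s, Pa, mol/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "HindranceFactors",
    "MembraneSpec",
    "diffusivity_from_MW",
    "hindrance_factors",
    "reflection_coefficient",
    "membrane_coefficients",
    "darcy_permeability",
    "volumetric_flux",
    "solute_flux",
]


@dataclass(frozen=True)
class HindranceFactors:
    """Steric/hydrodynamic hindrance of a solute in a cylindrical pore.

    Attributes
    ----------
    q : float
        Solute-to-pore size ratio ``rs/rp`` (dimensionless, ``0 <= q < 1``).
    Fq : float
        Wall-friction coefficient (Haberman-Sayre polynomial), ``0 < Fq <= 1``.
    SD : float
        Steric hindrance (partition) factor at the pore mouth,
        ``SD = (1 - q)**2``.
    """

    q: float
    Fq: float
    SD: float


@dataclass(frozen=True)
class MembraneSpec:
    """A porous membrane plus its derived transport coefficients.

    The geometric pore description (``rp``, ``eps``, ``psi``, ``delta``) is
    configuration input; everything else is derived via TCPDM for one solute.

    Attributes
    ----------
    rp : float
        Pore radius (m).
    eps : float
        Porosity (dimensionless, 0-1).
    psi : float
        Pore tortuosity (dimensionless, >= 1).
    delta : float
        Membrane thickness (m).
    Lp : float
        Hydraulic permeability (m Pa^-1 s^-1).
    D0 : float
        Effective in-pore diffusivity of the solute (m^2/s).
    K0 : float
        Diffusive mass-transfer coefficient ``D0/delta`` (m/s).
    sigma : float
        Reflection coefficient of the solute (dimensionless, [0, 1)).
    alpha : float
        Darcy permeability of the membrane ``rp^2 eps/(8 psi)`` (m^2).
    C2 : float
        Inertial (Forchheimer) drag coefficient; zero for creeping flow.
    """

    rp: float
    eps: float
    psi: float
    delta: float
    Lp: float
    D0: float
    K0: float
    sigma: float
    alpha: float
    C2: float = 0.0


def diffusivity_from_MW(MW: float) -> float:
    """Bulk diffusivity of a biomolecule from its molecular weight.

    Evaluates ``D = 1.62e-4 * MW**-0.552`` (cm^2/s) and converts to m^2/s.
    The correlation's native unit is cm^2/s; it reproduces published
    diffusivities of bilirubin and BSA only after the 1e-4 conversion.

    Parameters
    ----------
    MW : float
        Molecular weight in Da.

    Returns
    -------
    float
        Diffusivity in m^2/s.
    """
    if MW <= 0:
        raise DomainError(f"molecular weight must be positive, got {MW}")
    return 1.62e-4 * MW ** (-0.552) * 1e-4


def hindrance_factors(rs: float, rp: float) -> HindranceFactors:
    """Friction and steric hindrance of a solute of Stokes radius rs in a pore rp.

    ``Fq`` is the centerline drag-correction polynomial in ``q = rs/rp``;
    ``SD = (1-q)^2`` is the steric partition factor at the pore entrance.
    Both tend to 1 as ``q -> 0`` (point solute) and decrease monotonically.
    """
    if rs < 0 or rp <= 0:
        raise DomainError(f"radii must satisfy rs >= 0, rp > 0 (rs={rs}, rp={rp})")
    if rs >= rp:
        raise DomainError(
            f"solute excluded from pore: rs={rs} >= rp={rp}"
        )
    q = rs / rp
    Fq = (
        1.0 - 2.1050 * q + 2.0865 * q**3 - 1.7068 * q**5 + 0.72603 * q**6
    ) / (1.0 - 0.75857 * q**5)
    SD = (1.0 - q) ** 2
    return HindranceFactors(q=q, Fq=Fq, SD=SD)


def reflection_coefficient(rs: float, rp: float, form: str = "quadratic") -> float:
    """Staverman reflection coefficient of a solute in a cylindrical pore.

    The default (Anderson-type) form is ``sigma = 1 - (1 - q^2)^2``, which
    stays very small for small solutes in ~20 nm pores.  The alternative
    published form ``sigma = 1 - (1 - q)^2`` is available as
    ``form="linear_defect"`` for sensitivity studies.
    """
    if rs < 0 or rp <= 0:
        raise DomainError(f"radii must satisfy rs >= 0, rp > 0 (rs={rs}, rp={rp})")
    if rs >= rp:
        raise DomainError(f"solute excluded from pore: rs={rs} >= rp={rp}")
    q = rs / rp
    if form == "quadratic":
        sigma = 1.0 - (1.0 - q * q) ** 2
    elif form == "linear_defect":
        sigma = 1.0 - (1.0 - q) ** 2
    else:
        raise DomainError(f"unknown reflection-coefficient form {form!r}")
    # numerical guard only; both forms already lie in [0, 1) for 0 <= q < 1
    return min(max(sigma, 0.0), 1.0 - 1e-15)


def darcy_permeability(rp: float, eps: float, psi: float) -> float:
    """Darcy permeability of the tortuous-capillary membrane, ``rp^2 eps/(8 psi)`` (m^2).

    Constructed so that a Darcy slab of thickness ``delta`` has exactly the
    TCPDM hydraulic permeability: ``alpha/(mu*delta) == Lp``.
    """
    if rp <= 0 or not (0 < eps <= 1) or psi < 1:
        raise DomainError(
            f"invalid pore description rp={rp}, eps={eps}, psi={psi}"
        )
    return rp * rp * eps / (8.0 * psi)


def membrane_coefficients(
    rp: float,
    eps: float,
    psi: float,
    delta: float,
    solute,
    mu: float,
    sigma_form: str = "quadratic",
) -> MembraneSpec:
    """Assemble the full TCPDM coefficient set for one membrane/solute pair.

    Parameters
    ----------
    rp, eps, psi, delta : float
        Pore radius (m), porosity, tortuosity, membrane thickness (m).
    solute : object
        Any record with attributes ``rs`` (Stokes radius, m) and ``Ds``
        (bulk diffusivity, m^2/s) -- typically a
        :class:`hollowfiber.config.SoluteSpec`.
    mu : float
        Dynamic viscosity of the permeating fluid (Pa s).
    sigma_form : str
        Reflection-coefficient form, see :func:`reflection_coefficient`.
    """
    if delta <= 0 or mu <= 0:
        raise DomainError(f"delta and mu must be positive (delta={delta}, mu={mu})")
    h = hindrance_factors(solute.rs, rp)
    sigma = reflection_coefficient(solute.rs, rp, form=sigma_form)
    alpha = darcy_permeability(rp, eps, psi)
    Lp = alpha / (mu * delta)
    D0 = solute.Ds * h.Fq * h.SD / psi
    K0 = D0 / delta
    return MembraneSpec(
        rp=rp, eps=eps, psi=psi, delta=delta,
        Lp=Lp, D0=D0, K0=K0, sigma=sigma, alpha=alpha, C2=0.0,
    )


def volumetric_flux(Lp: float, dp) -> float:
    """Transmembrane volumetric flux ``Jv = Lp * dp`` (m/s).

    Positive ``dp`` (tube pressure above shell pressure) drives filtration
    tube -> shell; the sign of ``Jv`` follows the sign of ``dp``.
    """
    return Lp * dp


def solute_flux(Jv, sigma: float, Cm, K0: float, dC) -> float:
    """Transmembrane solute flux ``Js = (1-sigma)*Cm*Jv + K0*dC`` (mol m^-2 s^-1).

    ``Cm`` is the mean solute concentration inside the membrane (arithmetic
    mean of the two membrane-face concentrations in this package's closure);
    ``dC`` is the tube-minus-shell face concentration difference.
    """
    import numpy as _np

    if _np.any(_np.asarray(Cm) < 0):
        raise DomainError("mean membrane concentration Cm must be non-negative")
    return (1.0 - sigma) * Cm * Jv + K0 * dC
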