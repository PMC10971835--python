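"""Case definition: geometry, operating conditions, solutes, solver settings.

A simulation case describes one Krogh-type representative unit of a
hollow-fiber module: a single fiber lumen (tube side, ``0 <= r <= r1``), the
porous membrane annulus (``r1 <= r <= r2``) and the proportional share of
shell space (``r2 <= r <= r3``), of length ``L``, with plasma/solution fed at
``x = 0`` and dialysate (pure water) fed counter-currently at ``x = L``.
Module-scale flow rates are divided equally over the ``N`` identical fibers.

Internally everything is strict SI (m, s, Pa, mol/m^3).  Configuration files
use the unit conventions common in the dialyzer literature -- mm for lengths,
mL/min for flow rates, nm for pore diameter, mol/L for concentrations -- with
explicit, documented conversion at load time (see ``_SCHEMA`` below).
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ConfigError, DomainError, ValidationError
from .membrane import MembraneSpec, diffusivity_from_MW, membrane_coefficients

__all__ = [
    "ModuleGeometry",
    "OperatingConditions",
    "SoluteSpec",
    "SolverSettings",
    "SimulationCase",
    "load_case",
    "builtin_case",
    "builtin_case_names",
    "case_to_toml",
    "per_fiber_inlet_velocity",
    "rebuild",
]

ML_MIN = 1e-6 / 60.0  # m^3/s per mL/min


@dataclass(frozen=True)
class ModuleGeometry:
    """Representative-unit geometry.

    r1, r2, r3 : inner fiber radius, outer fiber radius, shell unit radius (m)
    L : fiber length (m);  N : number of fibers in the module.
    delta : membrane thickness, always ``r2 - r1`` (m).
    """

    r1: float
    r2: float
    r3: float
    L: float
    N: int
    delta: float = field(init=False)

    def __post_init__(self):
        if not (0 < self.r1 < self.r2 < self.r3):
            raise ValidationError(
                f"geometry invariant 0 < r1 < r2 < r3 violated: "
                f"r1={self.r1}, r2={self.r2}, r3={self.r3}"
            )
        if self.L <= 0:
            raise ValidationError(f"geometry invariant L > 0 violated: L={self.L}")
        if self.N < 1 or int(self.N) != self.N:
            raise ValidationError(f"geometry invariant N >= 1 violated: N={self.N}")
        object.__setattr__(self, "delta", self.r2 - self.r1)

    @property
    def tube_area(self) -> float:
        """Lumen cross-section pi r1^2 (m^2)."""
        return math.pi * self.r1**2

    @property
    def shell_area(self) -> float:
        """Shell annulus cross-section pi (r3^2 - r2^2) (m^2)."""
        return math.pi * (self.r3**2 - self.r2**2)


@dataclass(frozen=True)
class OperatingConditions:
    """Module-scale operating point.

    QB_in / QD_in : tube-side and shell-side module flow rates (m^3/s).
    p_out_tube / p_out_shell : outlet gauge pressures (Pa); only pressure
    differences matter, so both default to zero.
    mu, rho : fluid viscosity (Pa s) and density (kg/m^3); both streams are
    treated as water.  T, R : temperature (K) and gas constant (J/mol/K) --
    retained for completeness although the osmotic term that would use them
    is dropped from the volumetric flux law.
    """

    QB_in: float
    QD_in: float
    p_out_tube: float = 0.0
    p_out_shell: float = 0.0
    mu: float = 1.0e-3
    rho: float = 1000.0
    T: float = 310.0
    R: float = 8.314

    def __post_init__(self):
        if self.QB_in < 0:
            raise ValidationError(f"invariant QB_in >= 0 violated: {self.QB_in}")
        if self.QD_in < 0:
            raise ValidationError(f"invariant QD_in >= 0 violated: {self.QD_in}")
        if self.mu <= 0 or self.rho <= 0 or self.T <= 0:
            raise ValidationError(
                f"invariant mu, rho, T > 0 violated: mu={self.mu}, "
                f"rho={self.rho}, T={self.T}"
            )


@dataclass(frozen=True)
class SoluteSpec:
    """One permeating species.

    MW : molecular weight (Da); rs : Stokes radius (m);
    Ds : bulk diffusivity (m^2/s), auto-filled from the molecular-weight
    correlation when not supplied; C_in : tube-side inlet concentration
    (mol/m^3).
    """

    name: str
    MW: float
    rs: float
    C_in: float
    Ds: float | None = None

    def __post_init__(self):
        if self.MW <= 0 or self.rs <= 0:
            raise ValidationError(
                f"invariant MW > 0, rs > 0 violated: MW={self.MW}, rs={self.rs}"
            )
        if self.C_in < 0:
            raise ValidationError(f"invariant C_in >= 0 violated: {self.C_in}")
        if self.Ds is None:
            object.__setattr__(self, "Ds", diffusivity_from_MW(self.MW))
        elif self.Ds <= 0:
            raise ValidationError(f"invariant Ds > 0 violated: {self.Ds}")


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the 2D solvers.

    nx, nr_tube, nr_mem, nr_shell : cell counts (axial; radial per band).
    stretch : geometric refinement ratio toward the membrane interfaces.
    scheme : convection scheme for solute transport, "central" (second order)
    or "upwind" (bounded, first order).
    anisotropy_factor : ratio of axial to radial Darcy drag coefficient
    inside the membrane (axial flow through the membrane is suppressed).
    sigma_form / cm_closure : reflection-coefficient form and mean membrane
    concentration closure (see the membrane module).
    axisymmetric : solve with cylindrical 2*pi*r metrics (False gives a
    planar debugging mode).
    """

    nx: int = 800
    nr_tube: int = 40
    nr_mem: int = 8
    nr_shell: int = 40
    stretch: float = 1.15
    scheme: str = "central"
    anisotropy_factor: float = 1000.0
    sigma_form: str = "quadratic"
    cm_closure: str = "arithmetic"
    axisymmetric: bool = True
    mass_balance_tol: float = 1e-4

    def __post_init__(self):
        if self.scheme not in ("central", "upwind"):
            raise ValidationError(f"unknown convection scheme {self.scheme!r}")
        if self.cm_closure not in ("arithmetic", "log"):
            raise ValidationError(f"unknown Cm closure {self.cm_closure!r}")
        if self.stretch < 1.0:
            raise ValidationError(f"invariant stretch >= 1 violated: {self.stretch}")
        if min(self.nx, self.nr_tube, self.nr_mem, self.nr_shell) < 2:
            raise ValidationError("all cell counts must be >= 2")


@dataclass(frozen=True)
class SimulationCase:
    """A fully derived, validated simulation case (counter-current by construction)."""

    geometry: ModuleGeometry
    operating: OperatingConditions
    solute: SoluteSpec
    membrane: MembraneSpec
    solver: SolverSettings = field(default_factory=SolverSettings)

    @classmethod
    def make(cls, geometry, operating, solute, rp, eps, psi,
             solver: SolverSettings | None = None) -> "SimulationCase":
        """Build a case from pore-level membrane inputs, deriving all coefficients."""
        solver = solver or SolverSettings()
        mem = membrane_coefficients(
            rp=rp, eps=eps, psi=psi, delta=geometry.delta,
            solute=solute, mu=operating.mu, sigma_form=solver.sigma_form,
        )
        return cls(geometry=geometry, operating=operating, solute=solute,
                   membrane=mem, solver=solver)

    @property
    def tube_inlet_velocity(self) -> float:
        return per_fiber_inlet_velocity(
            self.operating.QB_in, self.geometry.N, "tube", self.geometry)

    @property
    def shell_inlet_velocity(self) -> float:
        return per_fiber_inlet_velocity(
            self.operating.QD_in, self.geometry.N, "shell", self.geometry)

    @property
    def reynolds_tube(self) -> float:
        """Tube-side Reynolds number rho v (2 r1) / mu."""
        op, g = self.operating, self.geometry
        return op.rho * self.tube_inlet_velocity * 2 * g.r1 / op.mu


def per_fiber_inlet_velocity(Q_module: float, N: int, region: str,
                             geometry: ModuleGeometry) -> float:
    """Mean (plug) inlet axial velocity in one representative unit.

    The module flow is apportioned equally over the N identical fibers and
    divided by the region cross-section: ``pi r1^2`` for the lumen,
    ``pi (r3^2 - r2^2)`` for the shell annulus.
    """
    if Q_module < 0:
        raise DomainError(f"flow rate must be non-negative, got {Q_module}")
    if region == "tube":
        area = geometry.tube_area
    elif region == "shell":
        area = geometry.shell_area
    else:
        raise DomainError(f"unknown region {region!r}")
    return (Q_module / N) / area


def rebuild(case: SimulationCase, *, geometry=None, operating=None,
            solute=None, solver=None, **geometry_ops) -> SimulationCase:
    """Return a new case with some records replaced, re-deriving the membrane.

    Keyword shortcuts (``L=...``, ``QB_in=...`` etc.) patch fields of the
    geometry/operating records directly; membrane coefficients are recomputed
    because they depend on the membrane thickness, viscosity and solute.
    """
    geo = geometry or case.geometry
    op = operating or case.operating
    geo_fields = {"r1", "r2", "r3", "L", "N"}
    op_fields = {"QB_in", "QD_in", "p_out_tube", "p_out_shell", "mu", "rho", "T", "R"}
    geo_patch = {k: v for k, v in geometry_ops.items() if k in geo_fields}
    op_patch = {k: v for k, v in geometry_ops.items() if k in op_fields}
    unknown = set(geometry_ops) - geo_fields - op_fields
    if unknown:
        raise ConfigError(f"unknown case override(s): {sorted(unknown)}")
    if geo_patch:
        geo = dataclasses.replace(geo, **geo_patch)
    if op_patch:
        op = dataclasses.replace(op, **op_patch)
    return SimulationCase.make(
        geometry=geo, operating=op, solute=solute or case.solute,
        rp=case.membrane.rp, eps=case.membrane.eps, psi=case.membrane.psi,
        solver=solver or case.solver,
    )


# --------------------------------------------------------------------------
# TOML schema:  section -> key -> (required, converter-to-SI or None for str)
# Units are spelled out in the key names used in the files themselves.
# --------------------------------------------------------------------------
_MM = 1e-3
_NM = 1e-9
_SCHEMA = {
    "geometry": {
        "r1_mm": True, "r2_mm": True, "r3_mm": True, "L_mm": True, "N": True,
    },
    "operating": {
        "tube_flow_mL_min": True, "shell_flow_mL_min": True,
        "p_out_tube_Pa": False, "p_out_shell_Pa": False,
        "mu_Pa_s": False, "rho_kg_m3": False, "T_K": False,
    },
    "solute": {
        "name": True, "MW_Da": True, "rs_nm": True, "C_in_mol_L": True,
        "Ds_m2_s": False,
    },
    "membrane": {
        "pore_diameter_nm": True, "porosity": True, "tortuosity": True,
    },
    "solver": {
        "nx": False, "nr_tube": False, "nr_mem": False, "nr_shell": False,
        "stretch": False, "scheme": False, "anisotropy_factor": False,
        "sigma_form": False, "cm_closure": False, "axisymmetric": False,
        "mass_balance_tol": False,
    },
}


def _check_sections(data: dict, source: str) -> None:
    for sec in ("geometry", "operating", "solute", "membrane"):
        if sec not in data:
            raise ConfigError(f"{source}: missing required section [{sec}]")
    for sec, content in data.items():
        if sec not in _SCHEMA:
            raise ConfigError(f"{source}: unknown section [{sec}]")
        schema = _SCHEMA[sec]
        for key in content:
            if key not in schema:
                raise ConfigError(f"{source}: unknown key {key!r} in [{sec}]")
        for key, required in schema.items():
            if required and key not in content:
                raise ConfigError(f"{source}: missing required key {key!r} in [{sec}]")


def _case_from_dict(data: dict, source: str) -> SimulationCase:
    _check_sections(data, source)
    g, o, s, m = data["geometry"], data["operating"], data["solute"], data["membrane"]
    geometry = ModuleGeometry(
        r1=g["r1_mm"] * _MM, r2=g["r2_mm"] * _MM, r3=g["r3_mm"] * _MM,
        L=g["L_mm"] * _MM, N=int(g["N"]),
    )
    operating = OperatingConditions(
        QB_in=o["tube_flow_mL_min"] * ML_MIN,
        QD_in=o["shell_flow_mL_min"] * ML_MIN,
        p_out_tube=o.get("p_out_tube_Pa", 0.0),
        p_out_shell=o.get("p_out_shell_Pa", 0.0),
        mu=o.get("mu_Pa_s", 1.0e-3),
        rho=o.get("rho_kg_m3", 1000.0),
        T=o.get("T_K", 310.0),
    )
    solute = SoluteSpec(
        name=s["name"], MW=s["MW_Da"], rs=s["rs_nm"] * _NM,
        C_in=s["C_in_mol_L"] * 1e3,  # mol/L -> mol/m^3
        Ds=s.get("Ds_m2_s"),
    )
    solver = SolverSettings(**data.get("solver", {}))
    return SimulationCase.make(
        geometry=geometry, operating=operating, solute=solute,
        rp=m["pore_diameter_nm"] * _NM / 2.0, eps=m["porosity"],
        psi=m["tortuosity"], solver=solver,
    )


def load_case(config_path) -> SimulationCase:
    """Load and validate a simulation case from a TOML file.

    Unknown sections/keys are rejected with :class:`ConfigError` naming the
    offender; invariant violations raise :class:`ValidationError` naming the
    invariant.
    """
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: TOML parse error: {exc}") from exc
    return _case_from_dict(data, str(path))


def builtin_case_names() -> list[str]:
    """Names of the configuration files shipped with the package."""
    pkg = resources.files("hollowfiber") / "cases"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".toml"))


def builtin_case(name: str) -> SimulationCase:
    """Load one of the shipped baseline cases, e.g. ``baseline_urea``."""
    pkg = resources.files("hollowfiber") / "cases" / f"{name}.toml"
    if not pkg.is_file():
        raise ConfigError(
            f"no builtin case {name!r}; available: {builtin_case_names()}")
    data = tomllib.loads(pkg.read_text())
    return _case_from_dict(data, f"builtin:{name}")


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    return repr(value)


def case_to_toml(case: SimulationCase) -> str:
    """Serialize a case back to the TOML schema (round-trips through load)."""
    g, o, s, m, sv = (case.geometry, case.operating, case.solute,
                      case.membrane, case.solver)
    lines = [
        "[geometry]",
        f"r1_mm = {_fmt(g.r1 / _MM)}",
        f"r2_mm = {_fmt(g.r2 / _MM)}",
        f"r3_mm = {_fmt(g.r3 / _MM)}",
        f"L_mm = {_fmt(g.L / _MM)}",
        f"N = {g.N}",
        "",
        "[operating]",
        f"tube_flow_mL_min = {_fmt(o.QB_in / ML_MIN)}",
        f"shell_flow_mL_min = {_fmt(o.QD_in / ML_MIN)}",
        f"p_out_tube_Pa = {_fmt(o.p_out_tube)}",
        f"p_out_shell_Pa = {_fmt(o.p_out_shell)}",
        f"mu_Pa_s = {_fmt(o.mu)}",
        f"rho_kg_m3 = {_fmt(o.rho)}",
        f"T_K = {_fmt(o.T)}",
        "",
        "[solute]",
        f"name = {_fmt(s.name)}",
        f"MW_Da = {_fmt(s.MW)}",
        f"rs_nm = {_fmt(s.rs / _NM)}",
        f"C_in_mol_L = {_fmt(s.C_in / 1e3)}",
        f"Ds_m2_s = {_fmt(s.Ds)}",
        "",
        "[membrane]",
        f"pore_diameter_nm = {_fmt(2.0 * m.rp / _NM)}",
        f"porosity = {_fmt(m.eps)}",
        f"tortuosity = {_fmt(m.psi)}",
        "",
        "[solver]",
        f"nx = {sv.nx}",
        f"nr_tube = {sv.nr_tube}",
        f"nr_mem = {sv.nr_mem}",
        f"nr_shell = {sv.nr_shell}",
        f"stretch = {_fmt(sv.stretch)}",
        f"scheme = {_fmt(sv.scheme)}",
        f"anisotropy_factor = {_fmt(sv.anisotropy_factor)}",
        f"sigma_form = {_fmt(sv.sigma_form)}",
        f"cm_closure = {_fmt(sv.cm_closure)}",
        f"axisymmetric = {_fmt(sv.axisymmetric)}",
        f"mass_balance_tol = {_fmt(sv.mass_balance_tol)}",
    ]
    return "\n".join(lines) + "\n"


def parse_case_string(text: str, source: str = "<string>") -> SimulationCase:
    """Parse a case from TOML text (used by the round-trip machinery and tests)."""
    return _case_from_dict(tomllib.loads(text), source)
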