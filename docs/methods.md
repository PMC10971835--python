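# Methods

## The model

The package simulates steady solute clearance in one representative unit of
a hollow-fiber membrane module of the kind used in hemodialysis and
non-biological artificial-liver support.  The module's fiber bundle is
uniform, so a single fiber plus its proportional share of shell space — a
Krogh-type cylinder — represents the whole device: lumen `0 ≤ r ≤ r1`,
porous membrane annulus `r1 ≤ r ≤ r2`, shell channel `r2 ≤ r ≤ r3`, length
`L`, with symmetry conditions on the axis and on the outer radius shared
with the neighbouring unit.  The feed (plasma/solution carrying the solute)
enters the lumen at `x = 0`; dialysate (pure water) enters the shell at
`x = L`, so the unit operates counter-currently.  Module flows are divided
equally over the `N` identical fibers and per-fiber results are scaled back
by `N`.

Three coupled pieces:

1. **Flow.**  Incompressible creeping flow.  At the baseline operating
   point the lumen Reynolds number is ≈ 2.7, so the momentum equations are
   linearized to Stokes form; the inertial correction to a fully developed
   laminar resistance is `O(Re·r1/L) ~ 10⁻³`, far below every tolerance
   used here.  The membrane is a resolved porous band with isotropic-in-r
   Darcy drag `−(μ/α) v`, `α = rp²ε/(8ψ)`, and an axial drag 1000× larger
   (configurable `anisotropy_factor`; pores run through the wall, not along
   it).  The Forchheimer (inertial) term is zero in creeping flow.

2. **Membrane transport coefficients** (tortuous-capillary pore-diffusion
   closure).  With pore radius `rp`, porosity `ε`, tortuosity `ψ` and
   thickness `Δδ = r2 − r1`:

   - hydraulic permeability `Lp = rp²ε/(8ψμΔδ)` — constructed so a Darcy
     slab of permeability `α` and thickness `Δδ` satisfies `Jv = Lp Δp`
     identically;
   - hindrance at size ratio `q = rs/rp`: friction polynomial
     `F(q) = (1 − 2.1050q + 2.0865q³ − 1.7068q⁵ + 0.72603q⁶)/(1 − 0.75857q⁵)`
     and steric partition `S_D = (1 − q)²`;
   - effective in-pore diffusivity `D0 = Ds·F·S_D/ψ` and diffusive
     mass-transfer coefficient `K0 = D0/Δδ` (no extra porosity factor:
     the superficial-velocity formulation already carries ε through `α`
     and `Lp`, and double-counting it in `K0` would halve every diffusive
     clearance);
   - reflection coefficient `σ = 1 − (1 − q²)²` (Anderson-type).  The
     alternative `1 − (1 − q)²` form is available via
     `sigma_form = "linear_defect"`; the default keeps σ very small for
     small solutes in ~20 nm pores (σ ≈ 1.3·10⁻³ for bilirubin), which is
     also why the osmotic term `σRTΔC` is dropped from the volumetric flux:
     `Jv = Lp·Δp`.
   - bulk diffusivity, when not supplied: `Ds = 1.62·10⁻⁴·MW^−0.552`
     in cm²/s (the correlation's native unit), converted to m²/s.

3. **Solute transport.**  Steady convection–diffusion on the frozen flow
   field.  In the lumen and shell the diffusivity is `Ds`; inside the
   membrane it is `D0` and the advecting species velocity is the superficial
   fluid velocity scaled by `(1 − σ)`.  In the thin-membrane limit this
   reproduces the Kedem–Katchalsky solute flux
   `Js = (1 − σ)·Cm·Jv + K0·ΔC`, which is verified station-by-station by
   `membrane_flux_audit` (agreement within 10% over the central 80% of the
   length at production resolution; the residual discrepancy is the
   cylindrical-metric and finite-thickness correction to the planar K-K
   formula).  `Cm` is closed as the arithmetic mean of the two
   membrane-face concentrations (a log-mean switch exists for sensitivity
   checks).

Clearance uses the standard flow-weighted definition
`CLS = (Q_B,in·C̄_in − Q_B,out·C̄_out)/C̄_in` with mixed-cup averages —
Eq.-level consistency requires flow weighting, not area averaging, because
the definition multiplies concentrations by flow rates.  The transmembrane
pressure profile is approximated by `Δp(x) = p_axis(x) − p_outer(x)`
(pressure is radially flat within each stream to ~10⁻⁵ of the axial drop),
and the reported "maximum positive TMP" is `Δp` extrapolated to the
tube-inlet end `x = 0`, where counter-current profiles peak.

## Numerics

**Flow.**  Finite volumes on a staggered (MAC) grid with full axisymmetric
`2πr` metrics: pressure at cell centres, `u` on constant-x faces, `v` on
constant-r faces.  The staggered arrangement is inf-sup stable (no
checkerboard modes, no Rhie–Chow interpolation), and since the creeping-flow
problem is linear the entire saddle-point system is solved by one sparse LU
factorization after row equilibration — there are no relaxation factors or
iteration counts, and "convergence" is audited by evaluating the discrete
operators directly (continuity residuals ~10⁻¹²).

Two discretization details matter and were chosen deliberately:

- *Membrane surfaces are tangential no-slip faces.*  The Brinkman screening
  depth `√α ≈ 1.5 nm` is five orders below the cell size, so the axial
  velocity vanishes at `r1` and `r2` themselves; coupling the lumen shear
  to the (drag-suppressed) membrane-cell velocity instead would move the
  effective wall half a cell into the membrane and bias the lumen
  resistance by ~10%.
- *Exact discrete Poiseuille resistance.*  `u`-rows are sampled at the
  quadratic-mean ring radius `r* = √((r_in² + r_out²)/2)` — where the ring
  average of any quadratic profile equals its point value — and radial face
  gradients use three-point Lagrange derivatives evaluated at the face
  (one-sided quadratics at the membrane walls).  The developed discrete
  Poiseuille solution is then nodally exact: the closed-membrane benchmark
  reproduces `Δp = 8μLQ/(πr1⁴)` to round-off, and the net filtrate changes
  by < 0.1% under a global grid refinement.

**Solute.**  Cell-centred finite volumes with the mass-conserving staggered
face fluxes.  Schemes: first-order upwind (an M-matrix; discrete maximum
principle holds, used for boundedness tests) and second-order central
interpolation (production default).  The faces adjacent to the two inflow
Dirichlet boundaries are always upwinded — central interpolation there
excites the classic two-cell oscillation against a fixed boundary value;
the fix is local and preserves second-order convergence (observed orders on
the Graetz benchmark: ≈ 1.3–1.7 upwind, ≈ 1.8–2.7 central).  The linear
system is solved by sparse LU with row equilibration plus one
iterative-refinement step; the boundary-flux audit then closes the solute
balance to ~10⁻¹⁵, against an acceptance threshold of 10⁻⁴.

With `σ > 0` the species advection next to the membrane surface is
deliberately non-solenoidal — that imbalance *is* the rejected convective
flux, and it produces genuine concentration polarization: for strongly
rejected solutes the wall concentration may slightly exceed the inlet
value.  The maximum-principle bound `0 ≤ C ≤ C_in` is therefore asserted
for the small-σ solutes the model targets.

**Grid.**  Structured, axially uniform; radial faces conform exactly to
`r1` and `r2`; tube and shell bands geometrically refined toward the
membrane (ratio 1.15), membrane band uniform.  Production resolution
`nx = 800`, `nr = (40, 8, 40)` was fixed by the refinement criterion: the
maximum tube-outlet concentration of the baseline bilirubin case
(extrapolated to the axis, where the maximum sits) changes by 0.0097%
under one global 2× refinement (criterion < 0.01%).  Getting under that
bar is what motivated the log-mean conductances and `r*` sampling above —
the convergence study exposed each first-order error component in turn
(membrane interface conductance, ring-average quadrature, inflow-face
interpolation).  Clearances are far less grid-sensitive than this scalar
(< 0.1% across every grid tried).  A full production solve takes a few
seconds on one CPU; the test suite runs all published-value comparisons at
this resolution and all qualitative property checks on a 120×20 grid that
reproduces production clearances to ~0.1%.

**Reduced model.**  A quasi-1D counter-current station model closes the
same membrane physics over the mid-surface perimeter `2π(r1+r2)/2`, with
axial pressure drops from exact Poiseuille resistances — the lumen
`8μ/(πr1⁴)` and the closed-form concentric-annulus conductance with no slip
at `r2` and zero shear at `r3`:
`K = −π[(r3⁴−r2⁴)/8 + (r3²−r2²)²/4 − (r3⁴/2)ln(r3/r2)]`,
verified against a finite-difference boundary-value oracle.  Volume and
solute balances telescope to round-off.  Because the reduction carries no
lumen/shell film resistance it overestimates clearance where boundary
layers matter: +6% vs the 2D solver for urea (asserted within the 15%
cross-model tolerance), +24% for bilirubin, documented here rather than
asserted.  It is a cross-check and a screening tool, not the production
path.

## Verification strategy

The reference outputs this model is compared against are themselves the
outputs of a closed-source commercial CFD code, so all solver trust is
anchored to analytic benchmarks first: closed-membrane Hagen–Poiseuille
flow (round-off agreement), a no-flow diffusion slab (nodally exact), and
the Graetz problem, whose mixed-cup decay rate is checked against the
leading Sturm–Liouville eigenvalue computed by an independent shooting
method (agreement 0.3%; the eigenvalue itself reproduces the classical
asymptotic Nusselt number 3.657).

Against the published model outputs, at a 10% comparison tolerance: the
urea validation clearances (262–351 mL/min over 300–500 mL/min feed),
bilirubin clearances at the baseline, high-flow and long-fiber points, the
maximum positive TMP at 600 mL/min, and the TMP zero-crossing location
(0.1751 m vs ≈ 0.175 m) all reproduce.  The BSA (macromolecule) clearances
do not: the published values are ~2× what the stated parameter set can
deliver — with a 19.75 nm pore radius the TCPDM hydraulic permeability
caps gross ultrafiltration near 7 mL/min at the baseline, while a
convection-dominated BSA clearance of 42 mL/min would require several
times that.  The published low-flow TMP shows the same signature (its
growth with feed flow is super-linear, which a laminar model can only
produce through much stronger transmembrane flow diversion).  No single
reading of the published parameters reconciles all printed values; this
package follows the stated equations and parameters and reports the
discrepancy rather than fitting to it.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `r1, r2, r3` | 0.1, 0.145, 0.21 | mm | unit geometry; `Δδ = r2−r1` |
| `L` | 270 | mm | fiber length |
| `N` | 12000 | – | fiber count (equal flow apportionment) |
| `QB, QD` | 300, 500 | mL/min | module feed / dialysate flows |
| `dp` (pore) | 39.5 | nm | pore diameter; `rp = dp/2` |
| `ε, ψ` | 0.1, 2.27 | – | porosity, tortuosity |
| `μ, ρ, T` | 10⁻³, 1000, 310 | Pa·s, kg/m³, K | water at both sides (not stated by the reference; overridable) |
| `C_in` | 1 (urea), 10⁻⁴ (bilirubin), 5.97·10⁻⁴ (BSA) | mol/L | feed concentrations |
| `nx, nr, stretch` | 600, (16,8,16), 1.15 | – | production grid |
| `anisotropy_factor` | 1000 | – | axial/radial membrane drag ratio |

Both outlet gauge pressures default to zero; only pressure differences
enter the model.

## Degenerate inputs and tie-breaks

Zero feed and dialysate flow yields the identically zero flow state (the
system is linear with zero data).  A closed membrane (`α = 0`) is handled
exactly — membrane velocities pinned, membrane pressures decoupled and
gauged to zero — rather than through a large-drag limit.  Zero inlet
concentration yields the zero field; clearance is undefined there and
raises `DomainError`.  The TMP zero crossing is located by linear
interpolation between the two straddling stations; if the profile does not
change sign, `x_cross` is `None`.

## Known limitations

- No membrane fouling/adsorption, no protein–toxin binding equilibria, no
  charge effects, no non-Newtonian rheology, no transient dynamics: the
  model is a steady, dilute, Newtonian description of one idealized unit.
- The equal-apportionment representative unit ignores bundle-scale flow
  maldistribution; real modules show shell-side channelling.
- Fluid properties of both streams are water at one temperature; plasma
  viscosity would roughly double lumen pressure drops and TMP.
- The quasi-1D model omits film resistances by construction (see above).
- Pore-size is single-valued; real membranes have a distribution, which
  mainly softens the sieving curve near the molecular-weight cut-off.
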