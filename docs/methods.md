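# Methods

`bottlesim` models the storage of water-ethanol beverages in semi-rigid
polymer (PET) containers: what pressure builds up in the sealed bottle,
how fast water and ethanol cross the walls, when the regulatory
shelf-life criteria are violated, and how container shape and wall
thickness trade plastic mass against shelf-life. This note records the
models, their assumptions, the numerical choices, and what the synthetic
study conditions do and do not represent.

## Binary thermodynamics

The beverage is reduced to the water-ethanol binary; its strength is the
EU legal *alcoholic strength by volume* (abv), the 20 degC volume ratio of
pure ethanol to total beverage, held as a fraction in [0, 1] everywhere in
the library.

**Saturation pressures.** Water follows a modified Goff-Gratch
correlation referenced to the normal boiling point (373.15 K,
101 324.6 Pa); it reproduces standard steam-table values at 20-50 degC to
0.1 %. Ethanol follows an Antoine correlation (A = 8.20417,
B = 1642.89, C = 230.3, T in degC, valid -57..80 degC) with a
log10(101325/760) offset converting mmHg to Pa; it reproduces the normal
boiling point of ethanol (78.3 degC) to 0.1 %.

**Density.** The density of the mixture rho(T, w_e) is the international
alcoholometric polynomial (OIML R22, revised Bettin-Spieweck
coefficients), embedded as constants and checked against standard
anchors (998.2012 kg/m3 at 20 degC for water, 789.24 for ethanol,
913.77 at 50 % mass). The polynomial is fitted on -20..40 degC; above
40 degC the same polynomial form is evaluated as a smooth extrapolation
(the boiling point of ethanol prevents direct measurement there; the
extrapolation deviates < 1 kg/m3 from literature pure-component values
at 70 degC). Compressibility at atmospheric pressure (< 0.01 %) is
neglected. Converting abv to mass fraction requires the mixture density
at 20 degC, which itself depends on composition; a damped fixed point
resolves the pair (w_e, rho) to machine precision. A regular
(T, abv) grid export of the polynomial ships as a versioned CSV resource
(`bottlesim/data/density_w_e_v1.csv`).

**Activity coefficients.** Non-ideality is computed by original UNIFAC
with the standard published group parameters (ethanol = CH3 + CH2 + OH,
water = H2O; alkane/OH/H2O main-group interactions). The choice of the
original parameter table (rather than a modified revision) was settled by
comparison with measured water/ethanol activities of typical beverages at
35 degC, which the model reproduces within 0.001 over abv 0.08-0.70.
Partial pressures follow Raoult's modified law `p_i = x_i gamma_i p_sat,i`.
The binary shows positive deviation (gamma >= 1 on both branches), so the
ethanol activity of even a wine-strength beverage (a_e ~ 0.24 at
abv 0.15) is far larger than its mole fraction.

## Headspace equilibration

A sealed bottle is treated as rigid (constant total volume), with an
ideal-gas headspace containing incondensable, insoluble, initially dry
air plus water and ethanol vapor. Oxygen/nitrogen exchange with the
liquid is neglected (< 0.02 % pressure effect). Equilibrium couples
three relations: vapor inventories from the activity model, liquid
density from the alcoholometric polynomial, and the ideal-gas law.

The solver nests two loops. Inner: for a trial headspace volume, a fixed
point on the liquid ethanol mole fraction (tolerance 1e-10) accounts for
the vapor inventory. Outer: golden-section minimization of the density
residual |rho_thermo - rho_mass-balance| over the headspace volume
(bracket 1e-3 V_head0 to V_bottle - 1 mm3, absolute tolerance 1e-12 m3);
convergence requires a residual below 1e-3 kg/m3. Liquid thermal
expansion enters only through rho(T, abv) - no separate expansion
coefficient. The ideal-gas identity P V = n R T holds exactly at the
returned state, and species totals are conserved to 1e-12 relative.

## Geometry

Containers are reduced to a dense vertical sampling of internal
cross-section area, wetted perimeter (slant-corrected) and wall
thickness; internal volume, wetted area and plastic mass follow by
trapezoidal quadrature (800 samples by default; doubling changes volume
and mass by < 0.01 %). Two constructors exist: measured axisymmetric
profiles (z, r, l), and a parametric family whose body cross-section is a
superellipse W x D (exponent 2 = ellipse, default 4 = rounded rectangle)
blending into a circular neck of diameter d over a shoulder of height h.
The blend interpolates half-axes and exponent with a C1 smoothstep -
any area-continuous C1 blend is acceptable here, and the choice is
recorded in the geometry metadata. For W = D and exponent 2 the
parametric bottle degenerates to a body of revolution and matches the
profile constructor to 0.1 %.

Mass uses the thin-shell approximation on the inner surface
(error O(l/r) < 1 % for these bottles) with flat-disk caps. A top-cap
thickness of zero denotes an open mouth sealed by an impermeable closure
(heat-sealed foil); it is excluded from the transport area and the mass.

For transport, the wall is decomposed into n vertical sections carrying
the area-weighted mean thickness and radius of their z-range; base and
top caps become separate planar sections by default, because their
thickness differs strongly from the adjacent lateral wall and folding
them into a mean thickness would misstate the flux (the folding variant
remains available). Sections partition the wetted area exactly.

## Wall transport

Mass transfer through each section is one-dimensional radial diffusion
in a cylindrical shell (the wall is three orders of magnitude thinner
than the bottle is tall), with concentration-independent, uniform
diffusivities per species - polymer relaxation, plasticization and
mutual diffusion coupling are deliberately neglected as second-order for
PET in this range. Sorption at both surfaces follows the linear isotherm
`C = a C_sat(T) rho_PET`, so the solver works in activity units; fluxes
between layers are continuous in activity, which makes two-layer walls
(shrink sleeves) a plain extension of the radial grid with a
harmonic-mean interface. A film conductance h (default 1e-2 m/s,
configurable) converts the vapor-side driving force `a_liquid - a_surface`
into a boundary flux scaled by `h p_sat M / (R T)`; at the default the
wall resistance dominates by four orders of magnitude, so results are
insensitive to h until it is lowered below ~1e-5 m/s.

Material anchors (PET, ~32 % crystallinity, rho = 1335 kg/m3):

| property | 35 degC | 50 degC |
|---|---|---|
| D_w (m2/s) | 1.5e-12 | 2.6e-12 |
| D_e (m2/s, abv 0.15/0.4/0.7) | 5.5/6.3/8.9e-16 | 2.4e-15 (abv 0.7) |
| C_w,sat (kg/kg) | 0.0118 | 0.0107 |
| C_e,sat (kg/kg) | 0.0208 | 0.0224 |

Water diffusivity interpolates between its two anchors with a two-point
Arrhenius law (effective activation energy ~30 kJ/mol implied by the
pair); ethanol interpolates log-linearly in composition at 35 degC and
scales in temperature with the 54 kJ/mol apparent activation energy that
reproduces the 50 degC anchor to 1.5 %. Saturation concentrations
interpolate linearly in T. Outside 15-60 degC properties are
extrapolated with a warning and a flag; the 25 degC design studies use
this extrapolation knowingly.

Walls start in equilibrium with the pre-storage atmosphere (default
50 % RH at 20 degC): ethanol-free, water at `(RH0/100) C_w,sat(T0)`.
External boundary activities are RH/100 for water and 0 for ethanol
(ventilated storage).

**Discretization.** Conservative finite volumes, 20 radial nodes per
wall layer by default (6 per sleeve layer), backward-Euler time stepping
with fluxes evaluated at the new time level, so each species satisfies
beverage + wall + permeated = constant to solver precision (checked to
1e-9 relative at every step). The time step grows geometrically
(factor 1.25 from 30 s) capped at 0.5 day and by a per-step abv change
of 1e-5, which bounds the operator-splitting error of the
beverage-wall coupling; the beverage and headspace are one well-mixed
equilibrated reservoir for composition. Halving the step and doubling
the nodes changes a 150-day mass loss by < 0.5 %. The solver reproduces
closed forms to: steady slab flux 0.05 %, permeation time lag L2/6D
0.03 %, same-material sleeve flux reduction l/(l+l_s) 0.01 %.

Mass loss is reported in the *permeation* definition (beverage plus
packaging, i.e. cumulative mass permeated to the exterior) - the
definition used for the weighing of sealed bottles - alongside the
*content* definition (beverage only); the two differ by the water and
ethanol held in the walls. With 0.8 mm walls the ethanol permeation lag
L2/6D is 3.8 years at 35 degC and 1.4 years at 50 degC, so ethanol
*permeation* is negligible on storage timescales while ethanol
*sorption* into the walls is not.

## Shelf-life

Two criteria end shelf-life: a relative mass loss of 1.5 % (the EU
tolerable negative error for prepackaged liquids of 1 L and more) and an
absolute abv drift of 0.003 (the +/-0.3 % vol labeling tolerance);
crossing times t_m and t_a are found by linear interpolation between
output steps, infinite when censored. abv is always evaluated at the
20 degC legal reference state. For smaller capacities the mass criterion
scales by the ratio of tolerable negative errors - 9 %/1.5 % = 6x for a
50 mL miniature - while the abv criterion is capacity-independent:
`shelf_life = floor(min(factor * t_m, t_a))`, floored to whole days at
the end only. The full EU capacity-class table (5 mL to 10 L) is
embedded; capacities outside it raise an error listing supported classes.

## Design optimization

The design problem fixes capacity (bottle 160 mL, beverage 150 mL),
beverage (abv 0.4) and storage (25 degC, 50 % RH), and for each body
section (W, D) solves two nested line searches: golden-section on the
height H to match the internal volume (tolerance 2 um on H, residual
below 10 mm3), then bisection on the body wall thickness to the smallest
value granting 180 days of shelf-life (tolerance 1 um; the returned
thickness is boundary-tight - 2 um less fails). Only the body thickness
is released; neck, top and bottom stay fixed at 2.0 mm, an
injection-grade choice sized so the fixed regions are secondary
resistances over most of the design space (for extreme flat designs the
caps are the main faces and the target can be unreachable; such nodes
are flagged infeasible, not fatal). Shelf-life evaluations inside the
searches use a coarse solver preset (4 sections, 10 nodes, per-step abv
change 1e-4, early exit at the first crossing); an optional confirmation
re-evaluates the returned design on a finer grid and records the
coarse/fine bias, which stays below ~0.5 %. Everything is deterministic:
identical inputs give bit-identical designs.

Sweeping (W, D) on a uniform grid and keeping the non-dominated subset
under (mass minimized, shelf-life maximized) yields the Pareto front;
domination is checked exhaustively. Near-square sections minimize
surface-to-volume and weight; flat shapes are feasible only with thick
walls and form a second, roughly twice-heavier family. An interesting
non-linearity: thin-walled designs lose ethanol fast enough for its loss
to offset the water-driven abv rise, so required thickness grows
slightly faster than the demanded shelf-life.

## Study conditions and the synthetic fixture

The reference container is a 55 mL injection-blown PET miniature
emulated as a deterministic axisymmetric profile: 0.80 mm body walls,
thicker base (1.6 mm cap), shoulder and neck (1.6 mm), 18 mm mouth
closed by an impermeable foil. The body radius is solved so the internal
volume is exactly 55 mL; the resulting plastic mass is 10.7 g,
consistent with weighed bottles (10.4 +/- 0.2 g). An optional seeded
Gaussian thickness noise emulates bottle-to-bottle scatter; it is off by
default and requires an explicit seed. Storage presets cover four
beverages (abv 0.7/0.4/0.15/0) and five conditions (20 degC/50 %,
50 degC/10 %, 35 degC/75 %, 35 degC/20 %, and 35 degC/20 % with a 60 um
sleeve over the body), filled with 44 mL at 20 degC and 101.325 kPa.

What the fixture does not represent: the real bottles' measured radius
and thickness profiles (published only graphically), lid leaks (the
dominant experimental failure mode), filling-volume scatter, and
blow-molding thickness distributions. Passing tests therefore validate
the transport and thermodynamic machinery and the order of magnitude of
the kinetics, not a bottle-exact reconstruction. Within one storage
condition the ratios between criterion times are geometry-independent
and reproduce the reference simulations to ~1 %; the absolute S3-condition
(35 degC) times run ~30 % faster than the reference values, which is
traceable to an internal inconsistency between the published 35 degC
water diffusivity anchor and the reference shelf-life table (the table's
condition ratios imply D_w(35) ~ 1.07e-12 m2/s instead of the tabulated
1.5e-12). This package follows the tabulated anchors.

## Problem sizes and runtime

Default simulations resolve the miniature with 10 lateral sections plus
the base cap and 20 radial nodes, integrating 40-150 days in a few
thousand steps (seconds on one CPU). The design sweep used in the tests
is 10 x 10 (the full published exploration is 30 x 30 and runs the same
code path; a single design optimizes in ~3 s, so 900 designs are a
~45 min batch). These sizes are the package's test defaults, chosen so
the whole suite runs comfortably on a laptop.

## Known limitations

- Binary beverage only: sugars, extracts, CO2 and aroma compounds are
  out of scope (the solver's species list is extensible in principle).
- Rigid walls: panel deformation and collapse mechanics are not modeled,
  only flagged via the pressure balance.
- No lid permeation or leak model; the closure is ideal.
- Isothermal storage; temperature transients are not integrated.
- Polymer state is frozen: no plasticization, relaxation, or
  crystallinity changes during storage.
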