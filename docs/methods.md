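# Methods

This note documents the models, discretizations and design choices behind
`ciliaflow`: a simulator of cerebrospinal-fluid (CSF) flow and solute
transport in the brain ventricles of the embryonic zebrafish (2 days
post-fertilization), driven by motile-cilia wall traction and cardiac
pressure pulsations.

## Physical model

**Flow.** CSF is water-like (density ρ = 1000 kg/m³, dynamic viscosity
μ = 0.7 mPa·s) and the Reynolds number of the observed flow is
Re = ρUL/μ ≈ 0.004 (U ≈ 28 µm/s, L ≈ 110 µm), so inertia is negligible and
the flow obeys the time-dependent incompressible Stokes equations

    ρ ∂u/∂t − ∇·σ = 0,   ∇·u = 0,   σ = 2µε(u) − pI.

Three boundary condition types appear:

* **cilia traction** on three wall patches (anterior chamber, dorsal and
  ventral middle chamber): u·n = 0 with tangential stress
  τ(x) = τ λ(x) P_n(r), where P_n is the tangential projection, r = ±(1,0,1)
  encodes the beat direction (rostrocaudal + dorsoventral), λ ≥ 0 a spatial
  weight (default 1), and τ = 0.65 mPa the calibrated amplitude.  The
  dorsal-middle patch drives +x (rostrocaudal); the ventral-middle and
  anterior patches drive −x, producing the observed recirculation vortices.
* **normal pressure** on flat anterior/posterior end caps:
  (µ∇u − pI)n = p̃(t)n with p̃ = 0 anteriorly and p̃ = −A sin(ωt)
  posteriorly; A = 1.5 mPa, cardiac frequency f = 2.22 Hz.
* **free slip** on the remaining walls: u·n = 0, zero tangential traction.

Flow scenarios: *baseline* (cilia + cardiac), *cilia-only* (caps become
slip walls; steady state), *cardiac-only* (no traction; the in-silico analog
of motile-cilia-mutant fish) and *regional paralysis* (traction removed from
a named patch subset).

A note on ω: the calibration data quote f = 2.22 Hz alongside
ω = 6.97 rad/s, which is not 2πf (= 13.95).  `ciliaflow` treats f as authoritative and, for
time stepping, uses ω = 2π/(20·Δt) with Δt = 0.023 s so the forcing is
exactly periodic over the stored 20-step cycle (effective f = 2.17 Hz, ~2 %
below nominal; the printed Δt and f are themselves only consistent to that
level).

**Transport.** A photoconverted solute with concentration c obeys

    ∂c/∂t + ∇·(c u − D ∇c) = 0,

one-way coupled to the flow (the stored cardiac cycle is replayed
periodically, one snapshot per transport step).  Walls are impermeable
(total flux zero).  On the pressure caps the diffusive flux is zero; the
advective inflow re-injects the previous step's total outflow so that the
solute leaving with one cardiac half-stroke returns with the next
(approximate periodicity; the embryonic ventricular system is closed).
Photoconversion is modeled by prescribing

    c(x, t) = log(1 + t/a) / log(1 + T/a),  a = 65 s,

on the tagged cell set (ROI 1, dorsal middle chamber), matching the
experimental fluorescence rise; T is the final simulation time.

**Solutes.** Diffusivities (m²/s): extracellular vesicles
D₁ = 2.17×10⁻¹² (Stokes–Einstein with R = 150 nm, k_B T at 310 K, µ as
above), STM-GFP D₂ = 5.75×10⁻¹¹ (cube-root mass scaling of measured GFP
diffusivity, 26.9 → 93.1 kDa), Dendra2 D₃ = 1.15×10⁻¹⁰ (measured).  Global
Péclet numbers with L_p = 600 µm and U_p = Ū = 2.4 µm/s are 664, 25 and 13:
advection-dominated at the geometry scale, but diffusion controls transport
to distal chambers (advective timescale over 200 µm: 83 s; diffusive:
1.8×10⁴ s, 696 s, 348 s).

Two commonly quoted reference values do not reproduce from their own
formulas and are flagged rather than matched: a force density of 2.5 mPa
spread over a 15 µm cilia array is quoted as 169 N/m³ (the quotient is
166.7; 169 and the companion value 507 N/m³ at 5 µm imply an unrounded
stress ≈ 2.535 mPa), and the vesicle diffusion timescale over 200 µm is
quoted as 24 500 s ((200 µm)²/D₁ = 1.84×10⁴ s).

## Discretizations

**Stokes: facet-based nonconforming P1 velocity + P0 pressure.**  The
velocity is discretized with Crouzeix–Raviart elements (vector DOFs at facet
midpoints = facet means) and cellwise-constant pressure.  This pair was
chosen as the numpy/scipy-implementable discretization that preserves the
properties the application needs:

* the impermeability constraint u·n = 0 is imposed *strongly* by rotating
  wall-facet DOFs into a normal/tangential frame and eliminating the normal
  component;
* testing continuity with P0 makes the cellwise divergence vanish to solver
  precision (two sweeps of iterative refinement keep it at ~10⁻¹³ of the
  natural u/h scale);
* the facet-mean normal fluxes are single-valued, so an exact lowest-order
  Raviart–Thomas (H(div)) reconstruction u(x) = Σ_F σ_F q_F (x−p_F)/(3|K|)
  exists per cell.  Transport consumes this reconstruction: its normal
  component is facet-constant and continuous, and its divergence is exactly
  the cellwise divergence — which makes a uniform concentration an exact
  steady state of the advection operator and global mass conservation exact.

The viscous form uses the symmetric gradient 2µε(u):ε(v).  Nonconforming P1
does not satisfy a discrete Korn inequality under that form, so the full
inter-element jump is penalized with γµ/h_F per interior facet (γ = 10).
Penalizing only the tangential jump is *not* sufficient: piecewise rigid
"hinge" rotations jump purely in the facet-normal direction and are
invisible both to the elementwise strain and to a tangential penalty (their
facet-mean normal jump vanishes by construction of the element), which
renders the operator singular.  The penalty is consistent (it vanishes for
the exact solution) and its energy share on the test fixtures is a few
percent, vanishing under refinement.

Time stepping is implicit Euler (Δt = 0.023 s, 20 steps per cardiac cycle);
the system starts at rest, runs a configurable number of startup cycles
(default 3; the viscous timescale µ/ρL² ≈ (70 s)⁻¹ makes the transient die
within one step, and consecutive cycles are verified to agree to 10⁻⁶), and
stores one cycle of snapshots.  Pressure gauge: with pressure caps present
the natural boundary condition fixes the pressure; for closed domains one
pressure DOF is pinned (sparsity-preserving; the dropped continuity row is
implied by the others) and the mean is subtracted afterwards.  Linear
solves use sparse LU (SuperLU) on the saddle system.

**Transport: modal DG(2) + SIPG + upwinding + BDF2.**  Concentration lives
in a discontinuous, cellwise-polynomial space (quadratic by default).  The
basis is built from shifted scaled monomials *orthonormalized per cell*
(Cholesky of the local Gram matrix); this keeps the local mass matrix equal
to the identity and the solvers well-conditioned on the less-regular cells a
carved mesh contains, and leaves the first mode proportional to the
constant, so prescribing the photoconversion value touches exactly one
coefficient per cell.  Diffusion uses the symmetric interior penalty method
with σ_F = α D k²/h_F, α = 50, k the polynomial degree.  Advection uses
upwind fluxes; with the H(div) velocity the facet normal velocity q_F/|F| is
single-valued and constant per facet, making the upwind side unambiguous.
Time integration is BDF2 with the flow's Δt.

The two starting levels required by BDF2 come from the prescribed smoothing
procedure: implicit-Euler diffusion solves with D̃ = D×10⁵ for one and two
steps, the photoconversion cells held at one (pure zero-data diffusion would
be identically zero), each field normalized by its maximum and scaled by the
photoconversion curve at Δt and 2Δt.

Linear systems are solved with preconditioned flexible GMRES (relative
tolerance 10⁻¹⁰).  The preconditioner is the sparse LU of the full operator
evaluated at the *cycle-averaged* fluxes, restricted to the unconstrained
DOFs; only the oscillating cardiac component of the advection is left to
the Krylov iteration, which then needs ~5–10 products per step.

**Periodic-flux bookkeeping.**  After each step the total advective outflow
rate through the caps is recorded; the next step imposes a single uniform
inflow concentration chosen to re-inject that amount.  Two guards make this
robust: when the instantaneous inflow capacity is negligible the amount
accumulates instead of being imposed, and the imposed value is capped
(default 2, i.e. twice the physical ceiling) with the shortfall accumulated
— near flow reversal the inflow rate passes through zero and an uncapped
quotient would inject unbounded boundary values (a numerically unstable
feedback).  Domain mass plus the accumulated reservoir is conserved by
construction; the domain mass alone is conserved to ≲10⁻⁸ per cardiac cycle
once the cycle-periodic regime is reached (the first cycle carries a
one-step offset from the lagged re-injection, ~10⁻⁴ relative at the test
scale; this is the approximation inherent in the lagged condition, not a
leak).

## Synthetic geometry

The generator emulates the 2-dpf ventricular system: three ellipsoidal
chambers (anterior ~150×140×90 µm, middle ~220×280×110 µm — the 110 µm
height matching the Reynolds length — posterior ~150×160×100 µm) joined by
two x-aligned cylindrical ducts (radii 22 and 25 µm), blended by a smooth
union of approximate signed distances (blend width 15 µm), truncated by
flat planes at the rostral/caudal tips that become the pressure caps.  The
rostrocaudal extent is ~600 µm, lateral ~300 µm, dorsoventral ~110 µm.
Chamber positions follow from the duct lengths (85 µm each).  Duct radii,
patch extents and all ROI positions are parameters; the duct radii are this
package's own choice of a realistic scale (the imaging-derived meshes the
model was developed on do not prescribe them).

Meshing carves a structured Freudenthal tetrahedral grid against the
implicit function (cells kept when the centroid is inside), keeps the
largest connected component, strips spike cells with ≥3 boundary facets,
then Newton-projects boundary vertices onto the zero level set.  Projection
backs off wherever a cell would lose more than 80 % of its volume: strongly
degenerate slivers would otherwise destroy the conditioning of every solver
downstream (in particular, roundoff amplified through the per-cell
orthonormalization can break the provable dissipativity of the upwind
advection operator).  Local refinement near the photoconversion centre is
achieved with a smooth radial grading map (spacing reduced by the
`refine_factor` within the refinement radius), which preserves conformity.
Resolution is set by the target edge length (default 12 µm; ~30 000 cells
at full scale).

Geometry variants mimic interindividual morphology differences: 66 %
cross-section reduction of the anterior–middle duct (area factor 0.34),
33 % of the middle–posterior duct (0.67), 43 % lateral shrinkage of the
middle chamber (0.57), and all three combined.  (An alternative
assignment permuting the two smaller percentages circulates; the mapping
above is the one adopted here, and every factor is configurable.)  Factors
are set absolutely, so variants are idempotent.

ROI defaults: six disjoint balls of radius 15 µm — ROI 1 dorsal middle
chamber (= the photoconversion region, by construction the same cell set),
ROIs 2–4 elsewhere in the middle chamber (posterior-dorsal, ventral,
anterior), ROI 5 anterior chamber, ROI 6 posterior chamber.

**What the generator does not emulate:** the real ventricles' asymmetric,
lobed shapes, wall roughness, spatially heterogeneous cilia coverage, and
the exact patch outlines (not precisely characterized in vivo).  Green
tests on this geometry establish that the solvers and the quantification
layer behave correctly and that the *directional* physics (recirculation,
paralysis and constriction effects, diffusivity ordering) is reproduced;
they do not certify the quantitative concentration curves of the
image-derived geometry.

## Quantities of interest

ROI means are exact volume-weighted integrals of the DG field.
Time-to-threshold is the first discrete sample time whose mean strictly
exceeds the ROI's threshold (0.25 for ROIs 1–4, 0.10 for ROIs 5–6, both
configurable), without interpolation; "never exceeded" is reported as
infinity.  The cilia force on a patch is F = ∫|τ| ds with τ evaluated per
facet.  Reporting precision mirrors the field's conventions: Péclet numbers
to the nearest integer, Reynolds to one significant figure, diffusivities
to three significant figures.

## Desk-scale testing policy

Full-length simulations on image-derived ventricle meshes (~140 000 cells,
1900 cardiac cycles ≈ 856 s) are supported but out of scope for CI.  The test suite
runs the same code paths on a reduced world: the synthetic geometry at
0.35× scale with ~10 µm edges (~2100 cells) and 50 cardiac cycles (23 s,
with the photoconversion curve normalized to that horizon).  Directional
claims (vortex structure, paralysis effect, diffusivity ordering of
times-to-threshold, constriction delays) are asserted on this world; the
probe threshold for the anterior chamber in the constriction comparison is
0.02, chosen once as a level reachable within the scaled horizon.

## Numerical choices and degenerate inputs

* Quadrature: collapsed (Duffy) Gauss rules on simplices, with the point
  count chosen for exactness at the polynomial degrees that appear; all
  operators are therefore assembled exactly up to roundoff.
* Tie-breaks: upwind side at exactly zero normal velocity defaults to the
  facet's first adjacent cell (the flux is zero, so the choice is inert).
* Degenerate cells (non-positive volume) raise with the cell index;
  unlabeled boundary facets raise with their count; non-manifold carves
  raise a generation error suggesting a finer edge length.
* DG over/undershoot: the scheme is not monotonicity-limited; bounds
  violations beyond 10⁻³ are logged.  They stay ≈10⁻³ for the protein-scale
  diffusivities and grow to ~0.2 locally for the nearly pure-advection
  vesicle case, as expected for unlimited high-order DG.
* Determinism: the pipeline contains no sampling; identical configurations
  give bit-identical outputs.

## Known limitations

* First-order velocity accuracy (by design — the same order as the
  H(div)-conforming scheme this pair stands in for); the pressure is
  cellwise constant.
* The nonconforming velocity pair needs the jump penalty for well-posedness
  (see above); the penalty parameter is not tuned per mesh.
* The approximate-periodic cap condition redistributes returning solute
  uniformly over the inflow facets (a flux-weighted option exists) and
  conserves mass only up to the one-step lag.
* No fluid–structure interaction, wall permeability, CSF secretion, or
  Lagrangian particle transport.
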