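# Methods

## Scope and model problem

`anisofem` solves quasi-static finite-strain elasticity for fiber-reinforced,
nearly or fully incompressible soft tissue (artery wall, myocardium) with
low-order mixed finite elements.  The displacement field u on a reference
domain Ω₀ minimizes (stationarizes) a two-field perturbed-Lagrangian
functional

    Π(u, p) = ∫_Ω₀ [ Ψ̄(C̄) + p Θ(J) − p²/(2κ) ] dX + Π_ext(u),

where F = I + Grad u, J = det F, C = FᵀF, and C̄ = J^{−2/3} C is the
isochoric (unimodular) part of C.  The pressure p is a Lagrange multiplier
for the volumetric constraint Θ(J) = 0, penalized by the bulk modulus κ;
the fully incompressible limit is the exact constraint 1/κ = 0, which the
stabilized element technologies support directly.  Θ is either J − 1 or
ln J; both satisfy Θ(1) = 0, Θ′(1) = 1, so p has the meaning of an applied
hydrostatic pressure near the reference state.

Stationarity gives the total second Piola–Kirchhoff stress

    S = p π(J) C⁻¹ + J^{−2/3} Dev(S̄),   S̄ = 2 ∂Ψ̄/∂C̄,   π(J) = J Θ′(J),

with Dev(A) = A − (A : C)/3 · C⁻¹ the Lagrangian deviatoric projection.
The consistent tangent splits into

    ℂ = ℂ_isc + p ℂ_vol,   ℂ_vol = k(J) C⁻¹⊗C⁻¹ − 2π(J) C⁻¹⊙C⁻¹,

with k(J) = J²Θ″ + JΘ′ and ⊙ the symmetrized dyadic.  ℂ_isc is derived by
the exact chain rule through C̄(C): with the projection tensor
P = ∂C̄/∂C = J^{−2/3}(𝕀 − C⊗C⁻¹/3),

    ℂ_isc = Pᵀ : ℂ̄ : P
            + (2/3) J^{−2/3} (S̄:C) [ C⁻¹⊙C⁻¹ − C⁻¹⊗C⁻¹/3 ]
            − (2/3) [ C⁻¹⊗S_isc + S_isc⊗C⁻¹ ].

All stresses and tangents are implemented analytically and gated in the
test suite by central-difference oracles (stress vs energy < 1e−6
relative; tangent vs stress < 1e−5; element and global tangents vs
residuals < 1e−6).

## Material families

All stress-like parameters are in kPa; exponents are dimensionless.

* **Isotropic neo-Hooke** — Ψ̄ = μ/2 (Ī₁ − 3).
* **Artery (matrix + two symmetric fiber families)** — neo-Hookean matrix
  plus k₁/(2k₂) Σ_{i=f,s} [exp(k₂⟨I₄ᵢ − 1⟩²) − 1].  The fiber families lie
  at ±40° to the circumferential axis in the tube benchmark.  The fourth
  invariants are floored at 1 by default (`floor_fibers`), i.e. collagen
  fibers bear load only in extension.  This is the standard tension-field
  convention for arterial collagen; it also matters numerically: without it
  the family compressed by the torsional part of the benchmark load makes
  the element tangent indefinite, and Newton needs heavy step cutting
  instead of the 2–4 iterations per step observed with the floor.
* **Holzapfel–Ogden (orthotropic myocardium)** — a/(2b)[exp(b(Ī₁−3))−1]
  plus exponential fiber and sheet-normal families with invariants floored
  at 1 (compressed-fiber exclusion) and an I₈fs interaction term.
* **Dispersed fiber (Gültekin-type)** — like Holzapfel–Ogden with fiber
  and sheet families driven by the dispersion pseudo-invariant
  I₄ᵢ* = κᵢ I₁ + (1 − 3κᵢ) I₄ᵢ, κᵢ ∈ [0, 1/3] (κᵢ = 0 recovers perfectly
  aligned fibers; κᵢ = 1/3 is isotropic).
* **Fung–Guccione (transversely isotropic)** — Ψ̄ = a/2 (exp 𝒬 − 1) with 𝒬
  a quadratic form in the isochoric Green–Lagrange strain Ē = (C̄ − I)/2
  expressed in the fiber frame.  Ē is not meaningful on an unsplit C in
  this construction, so this family admits no WAS mode (see below).

**AS vs WAS.**  The anisotropic part can be evaluated on C̄ (anisotropic
split, AS) or on the unsplit C (WAS); in WAS mode the anisotropic stress
2∂Ψ_aniso(C)/∂C is added directly, without deviatoric projection.  For the
dispersion pseudo-invariant both ingredients (I₁ and I₄) are taken from the
same argument — barred under AS, unbarred under WAS — which keeps each mode
a clean hyperelastic energy of its argument.

**Active stress.**  A prescribed scalar S_a(t) enters as the additive
tensor S_a [ κ_f/(1−2κ_f) C⁻¹ + (1−3κ_f)/(1−2κ_f) (f₀·C f₀)⁻¹ f₀⊗f₀ ]
with fiber dispersion κ_f ∈ [0, 1/2).  Cellular activation models that
would generate S_a(t) are out of scope; the schedule is configuration.

## Element technologies

All four use P1 (tet) or Q1 (hex) displacements.

* `p0_penalty` — per-cell constant pressure, statically condensed:
  p_K = κ ∫_K Θ(J) dX / |K|, giving a displacement-only penalty kernel
  K_eff = K_uu + (κ/|K|) k kᵀ.  Requires finite κ (the incompressible
  limit is a configuration error).  Prone to volumetric locking and
  checkerboard stresses; kept as the baseline.
* `equal_order` — P1/Q1 pressures with no stabilization.  Violates the
  inf-sup condition; retained deliberately so the pressure-oscillation
  contrast with the stabilized pair can be demonstrated.
* `projection` — equal-order pair stabilized by the pressure-projection
  term s_h(p, q) = Σ_K (1/μ*) ∫_K (p − Π_h p)(q − Π_h q) dX with Π_h the
  elementwise mean and μ* = |K|^{1/3} (|K| the reference cell volume in
  mm³; the constant's nominal units are harmless since μ* is fixed per
  cell).  s_h is integrated over the reference configuration.  Supports
  1/κ = 0.
* `mini` — equal-order pair enriched with interior displacement bubbles:
  the quartic 256 ξηζ(1−ξ−η−ζ) on the tetrahedron, and on the hexahedron
  the two functions (1−ξ²)(1−η²)(1−ζ²)·N_α for the body-diagonal vertex
  pair (α, β) = (1, 7) in VTK ordering (any body-diagonal pair works; the
  choice fixes the ordering convention).  The bubbles are kept exactly as
  printed, unnormalized at the center except for the tet factor 256;
  normalization would only rescale the condensed dofs.  Bubble dofs are
  eliminated per element by a Schur complement before assembly and their
  increments recovered after each global solve.  Because bubbles vanish on
  element boundaries, pressure boundary (follower) terms contribute no
  bubble rows, so condensation needs no special treatment for them.

Quadrature defaults: degree-2 rules for linear elements (4-point tet,
2×2×2 hex), degree-4 (conical-product) for MINI-tet and 3×3×3 for
MINI-hex — the lowest rules that integrate the bubble-coupled blocks
without rank deficiency.  Tet rules of degree ≥ 3 are built by the Stroud
conical product from Gauss–Jacobi nodes, so polynomial exactness holds by
construction (and is asserted against symbolic integrals in the tests).

## Loads and boundary conditions

Dirichlet data are nodal ramps g(X, t); the artery's top-surface ramp
composes an exact rotation about the z-axis with an axial translation
(rotation of coordinates, not its linearization).  Follower pressures are
integrated on the deformed surface: the traction −p_ext J F^{−T} N dS is
evaluated as −p_ext (a₁ × a₂) dξ with a_i the deformed facet tangent
vectors, and the exact (nonsymmetric) load stiffness follows by
differentiating the cross product.  For facet-interpolated displacements
this is algebraically identical to the two standard linearization terms of
the boundary form and passes the finite-difference gate at 1e−6.  Pressures
given in mmHg are converted with 1 mmHg = 0.1333224 kPa.  A constant body
force per unit reference volume is supported and defaults to zero.

The cavity-volume operator V = (1/3)∮ J (X+u)·F^{−T} N dS is evaluated by
facet quadrature of the deformed-surface form x·(a₁×a₂); it is exact for
polyhedral surfaces and reproduces reference volumes at machine precision.

## Solver

Global systems are assembled sparse over free dofs (Dirichlet dofs are set
to their step values up front and eliminated), and solved with a direct
sparse LU factorization — appropriate at desk scale; an iterative backend
would slot behind the same `linear_solve` interface.  Newton iterates until
the free-dof residual norm (including the pressure block) drops below 1e−6
of its step-initial value (configurable; some tests tighten it to 1e−10 or
below to expose closed-form agreement).  Two standard robustness devices
are layered on top:

* a backtracking line search (up to 5 halvings) that rejects trial states
  with inverted elements or non-finite/increased residuals — necessary
  because the exponential fiber energies overflow for far-field trial
  states;
* a secant continuation predictor that warm-starts each load step by
  extrapolating the two previous converged states (pressures and bubble
  dofs extrapolate with the displacements).

Load steps that still fail are halved, up to 4 times per nominal step.
With these defaults the artery benchmark at level 1 converges in 2–4
Newton iterations per step, consistent with a total linear-solve count of
the order of 80–100 for 25 steps.

## Benchmarks and the synthetic geometry

**Artery (extension–inflation–torsion).**  Structured hexahedral tube,
R₁ = 8 mm, R₂ = 10 mm, H = 10 mm, subdivisions (24ℓ, 10ℓ, 4ℓ) in
(θ, z, r) at refinement level ℓ — the unique factorization reproducing the
published mesh-statistics table (960ℓ³ hexes; 24ℓ(10ℓ+1)(4ℓ+1) nodes; the
6-tet subdivision gives exactly 6× the hex count).  Cross-sections are
polygonal (nodes exactly on the radii), so the reference volume equals the
24ℓ-gon annulus prism in closed form.  Hex-to-tet subdivision cones each
cell from its minimum-global-index vertex with far faces fanned from their
own minimum vertex; every face is then split by the diagonal through the
face's minimum global vertex, which makes the subdivision conforming and
also handles the degenerate (wedge) apex cells of the ellipsoid mesh with
the same rule.  Loading: bottom clamped; top ramped to 2 mm axial
displacement + 60° torsion; inner-wall follower pressure ramped to
500 mmHg; 25 linear load steps by default.  Material: artery family with
μ = 10, k₁ = 500, k₂ = 2; κ = 5000 kPa for the penalty elements, 1/κ = 0
for projection/MINI.  The mesh-convergence probe points are taken as
A = (R₁, 0, H/2) and B = (R₂, 0, H/2) — inner and outer wall at
mid-height; this is this package's convention for points that the source
figures show only graphically.

**Idealized ventricle.**  Tetrahedral mesh of the wall between two prolate
ellipsoids (defaults r_s = 7/10 mm, r_l = 17/20 mm endo/epi) truncated by
the base plane z = 5 mm; these dimensions are configuration, not
constants.  Per-cell fiber triads rotate linearly across the wall between
configurable endo/epi helix angles (defaults +90°/−90°); the sheet
direction is transmural.  Passive endocardial inflation is followed by an
optional prescribed active-stress ramp (first/second half of the pseudo-
time schedule).  The benchmark's published pressure magnitude and active-
tension trace live in a companion reference, so the driver exposes them as
configuration with mild desk-scale defaults (1 kPa inflation, no active
stress) rather than inventing constants silently.

Both drivers guard desk-scale limits (artery level ≤ 3, ellipsoid
≤ 100k cells) behind an `allow_large` flag.

## What the synthetic geometry does and does not emulate

The generators reproduce the geometric and constitutive setting of the
benchmarks exactly (dimensions, fiber architecture, loads, parameters) but
are idealized: perfectly cylindrical/ellipsoidal surfaces, uniform
structured meshing, noise-free fiber fields, and deterministic loading.
Passing tests therefore demonstrate correctness of the discretization and
solver on these conditions — locking contrasts, incompressibility
satisfaction, stabilization behavior — not robustness to anatomical
meshes, imaging-derived fibers, or contact/pericardial constraints, which
are outside this package's scope.

## Numerical choices and degenerate inputs

* Voigt order (11, 22, 33, 12, 23, 13); fourth-order tensors are kept full
  (3,3,3,3) internally and collapsed only at the API surface.
* Fiber flooring uses the one-sided derivative at I₄ = 1: stress and
  stiffness contributions vanish identically at and below the floor.
* det F ≤ 0 (or non-finite) at any quadrature point raises an
  inverted-state error that the solver catches for line-search
  backtracking or step cutting; singular linear systems raise a
  diagnostic naming the offending dof.
* The volume-weighted mean of det F reported by the postprocessor is exact
  for the incompressible saddle-point formulations by construction (the
  constant pressure test function enforces ∫ Θ(J) dX = 0), so the
  benchmark's near-unity mean is a meaningful check only through the
  nonlinear solve, not the statistic.
* Stress fields are reported element-wise (quadrature-averaged per cell),
  unsmoothed; cylindrical stress components use the deformed-configuration
  cylindrical basis at cell centroids by default (a flag selects the
  reference basis).
* Probing locates tets by barycentric coordinates (best-violation
  argmin with 1e−9 tolerance) and hexes by Newton inversion of the
  trilinear map seeded from nearest centroids.

## Problem sizes used in the shipped checks

The automated checks run the artery benchmark at refinement level 1
(5760 tets, 1320 nodes) with a 10-step schedule — a scaled-down variant of
the 25-step default — plus a reduced-load 2-vs-4-step pair for the
path-independence property, and small cube/tube fixtures elsewhere.  The
level-1..7 mesh statistics are exercised as counts only.

## Known limitations

* Direct solves only at desk scale; no preconditioned Krylov path, no MPI.
* No viscoelasticity, growth, contact, or 0D circulatory coupling (the
  cavity-volume operator is provided, the coupled solves are not).
* The unstabilized equal-order pair is intentionally inf-sup unstable.
* Gmsh `.msh` serialization drops per-cell fiber fields (the format has no
  natural slot); VTU round-trips everything bit-identically.
* MINI condensation assumes an invertible bubble block; for degenerate
  (sliver) cells this raises rather than regularizes.
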