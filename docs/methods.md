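# Methods

This note documents the models, numerical choices and limitations behind
`vertfrac`.  Units are N / mm / MPa throughout; densities are g/cm³.

## Synthetic phantom

The vertebral body is approximated as an elliptic cylinder (default
semi-axes 24 × 18 mm, height 30 mm) with a cortical shell (default 2 mm)
and a trabecular core.  World coordinates are mm with the origin at the
body centroid; +x is patient-left, +y anterior, +z cranial.  Voxel
(i, j, k) has its center at `origin + (i+½, j+½, k+½)·spacing` with
0-based indices, where `origin` is the minimum grid corner.

Expected HU values are 923 for cortical voxels (the cortical mean of the
calibration chain) and 200 for trabecular voxels — a typical healthy
trabecular vertebral value; both must respect the 700 HU
cortical/trabecular split so labels stay consistent.  Gaussian noise
(default SD 25 HU, truncated at ±4 SD by clipping) is added after
labelling, emulating CT noise without flipping region labels.  Voxels
outside the body carry −1000 HU (air).

Two screw cylinders (radius 2.5 mm, depth 30 mm) enter from the
posterior surface at ±8 mm lateral offset, converging 5° mediolaterally
and tilting 5° craniocaudally — a transpedicular-trajectory analogue.
The bone–screw interface is bonded by shared mesh nodes.  Screws are
optional; the phantom has no true pedicles or posterior elements.

Lesions are *not* burned into HU: they act purely on the material field,
which is how a metastasis alters constitutive properties rather than the
reconstructed geometry.

What the phantom does not emulate: scanner physics (beam hardening,
partial-volume blur beyond the mean-fill correction), anatomic posterior
elements, endplate curvature, intra-trabecular heterogeneity beyond
i.i.d. noise.  Property tests passing on the phantom therefore verify
the *mechanics pipeline*, not anatomical fidelity.

## Calibration chain

* Region labels are frozen from the raw HU at the 700 threshold before
  any smoothing, and select the modulus branch and the compressive
  stress-limit law throughout.
* HU correction: voxels outside the body are replaced by the mean HU of
  cortical-range voxels (computed over HU ≥ 700); the grid is then
  smoothed with a moving-average filter.  The kernel width and boundary
  policy are free choices here: default 3×3×3 with nearest-edge
  replication, both configurable.  When a volume has no outside voxels
  (verification blocks) the fill step — and hence the cortical mean — is
  not needed and is skipped.
* ρ_app = 1.9·HU/HU_max with HU_max = 1109 by default; a config flag
  recomputes HU_max as the volume maximum instead.  Negative HU clamps
  to zero density.
* Moduli: E_T = 4730·ρ^1.56, E_C = −892.5·ρ^−2.491 + 14360 (MPa).  The
  cortical law is singular at ρ = 0 (an error) and negative below
  ρ ≈ 0.33; bone moduli are floored at 1 MPa to keep the stiffness
  matrix well conditioned for near-zero-density voxels.  Lesion-blended
  and killed elements may go far below that floor by design (down to
  the 10⁻⁶ MPa clamp).
* ρ_ash = 0.551·ρ_app − 0.00478, floored at 0.
* ν = 0.3 uniformly for bone and lesions; screws are 110 GPa, ν = 0.4.

## Lesion blend

E(x) = E_CT(x) + Σ_j B_j k_j (E_m,j − E_CT(x)) evaluated at element
centroids (deterministic and mesh-consistent; the evaluation point is
otherwise a free choice).  The sphere boundary is inclusive (B = 1 at
distance exactly R).  E_m is homogeneous within each lesion; spatial
heterogeneity enters only through the blend.  Because bone and lesion
share ν = 0.3, blending the scalar E reproduces the blended elasticity
tensor exactly (verified against a tensor-blended element-stiffness
oracle).

Contributions of multiple lesions sum *relative to E_CT*, not
sequentially.  Overlapping osteolytic spheres can drive the sum
negative; the result is clamped at 10⁻⁶ MPa (the killed-element value)
and every clamped element is logged.  The additive rule gives no
guidance for overlaps, so the clamp is a declared design decision.
Lesions never override screw elements; a lesion that overlaps no bone
element is a warning, not an error.

## FE core

One trilinear hexahedron per in-body voxel (2×2×2 Gauss stiffness,
centroid strain recovery).  Voxel meshes suit HU grids directly and make
progressive damage cheap: every element shares the same geometry, so
K_e = E_e·K₀(ν) and re-assembly after element kill only rescales data in
a frozen sparsity pattern.  Quadratic tetrahedra would converge faster
per element on smooth geometry but buy nothing on voxel data.

The reduced system is SPD.  The default solver is Jacobi-preconditioned
CG (rtol 1e-13) with an automatic fall-back to a direct sparse LU
(COLAMD) — the diagonal scaling absorbs the 10¹¹ stiffness contrast
introduced by killed elements, and the damage loop warm-starts CG from
the previous displacement state scaled by the load ratio.  A solve is
accepted only if the true relative residual is ≤ 1e-8; anything else is
a structured non-convergence signal.  Verification: exact patch test
under uniform uniaxial stress, dense-solve equivalence below 300 dofs,
Euler–Bernoulli tip deflection within 10 % on a slender cantilever, and
frame objectivity under a quarter turn.

Loading: the inferior end plate (exposed bottom faces) is fully fixed.
The compressive resultant goes 80 % to the vertebra and 20 % to the
screws (100 % to the vertebra when screws are absent, logged).  The body
share splits 70/30 between the superior end plate and a facet analogue —
the posterior 25 % band of the top surface (the split within the body
share and the band width are config-exposed; no quantitative guidance
exists for them).  Plate loads are distributed by tributary face area.
The 4.7 N·m moment (about x for extension, y for lateral bending) is a
statically equivalent linearly varying nodal traction over the end
plate: nodal forces along the load direction proportional to the lever
arm about the weighted end-plate centroid, giving zero net force and the
exact resultant moment.  The moment is held constant while the
compressive force ramps.

The reaction f_r is the internal nodal force (K u) summed over the
superior end-plate set along the load direction — the discrete analogue
of integrating reaction tractions over the end plate; under force
control it equals the end-plate share of the applied load at every
converged step.  u_top is |mean| top-plate displacement along the load
direction.

## Failure and progressive damage

σ⁺ = max{0, σ₁, σ₂, σ₃}, σ⁻ = −min{0, σ₁, σ₂, σ₃} (strains analogous);
failure is strict inequality against the limits, so boundary states
survive and ties cannot occur.  Stress limits use the element's frozen
region label; strain limits are density-independent.  Killing sets
E = 10⁻⁶ MPa exactly and relabels the element `failed`; ν is untouched.
Screw and already-failed elements are never tested.

The load ramp f_{k+1} = f_k + γ·Δf starts at Δf (default 100 N).  The
printed adaptive rule γ = n/n̄ (total over newly fractured elements) is
undefined at n̄ = 0 and enormous otherwise, so the default is γ = 1
(`gamma_mode="fixed"`); `"adaptive"` applies n/n̄ only when n̄ ≥ 1,
capped (default 10).  Within a step the same external load is re-solved
after each kill until no further element fails.

Termination — any of: solver non-convergence, inner kill-loop budget
exhausted (default 50), or an abrupt displacement increase.  "Abrupt" is
operationalised as the new point's incremental compliance Δu/Δf
exceeding 10× (configurable) the median incremental compliance of the
prior curve; the first step is vacuously safe.  On termination the
offending step is discarded and the fracture load is the last converged
reaction.  A run that never fractures ends at `max_steps`
(`step_budget_exhausted`) or at an optional load cap (`completed`).

A note on monotonicity: killing elements cannot stiffen the structure,
so under pure proportional loading the secant compliance u/f is
non-decreasing step to step (asserted in the tests on a moment-free
ramp).  With the constant superimposed moment the secant acquires a
load-independent offset, and steps that kill elements record a secant
across the softening event; neither u/f nor the per-step Δu/Δf is then
exactly monotone, which is why the invariant is tested in the
proportional regime.

## Study design

52 runs: the 2×2×2×3×2 grid (load case × criterion × lesion type ×
position × radius) plus four multiple-lesion combinations (P1+P2,
P1+P3, P2+P3, P1+P2+P3; osteolytic, R = 10 mm, lateral bending, strain
criterion).  Default positions are scaled to the phantom's semi-axes —
P1 (−0.5a, 0, 0), P2 (−0.35a, 0.4b, 0), P3 (0, 0.45b, 0) at mid-height —
analogues of lateral-right / anterior-right / anterior placements.
Absolute fracture loads depend on the phantom's geometry and density, so
the study targets structure and ordering (radius up ⇒ osteolytic
fracture load down; combined lesions no stronger than their weakest
constituent), not patient-specific values.

## Problem sizes

The default phantom at 2 mm voxels yields ≈5100 elements / 18k dofs; a
full progressive-damage run takes on the order of a minute.  The test
suite runs its fracture-property cases on a down-scaled phantom (3 mm
voxels, ≈450 elements) with coarser load increments (Δf 1–4 kN, chosen
so runs resolve the fracture load in 5–15 steps), plus one
full-resolution run; these sizes are the package's own verification
choices and are configurable.

## Known limitations

Small-strain linear elasticity with isotropic laws; no contact, thread
geometry, poroelasticity, fatigue or mixed lytic/blastic lesions.
Hex8 elements are stiff in bending at coarse resolution; fracture loads
converge from above as the mesh refines.  The abrupt-displacement
factor, smoothing kernel and facet split are declared defaults, not
empirically identified constants.
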