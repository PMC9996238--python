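# Methods

## Volume-conductor model

The package solves the quasi-static conduction problem
∇·(σ∇f) = 0 on a voxelized torso segment around the spinal cord.
Quasi-statics is the standard assumption for stimulation frequencies well
below the dielectric relaxation scales of tissue: capacitive and inductive
effects are neglected and the potential field follows the injected currents
instantaneously. Tissue conductivities are axis-aligned diagonal tensors in
S/m (full tensors are out of scope); white matter (0.083, 0.083, 0.6) and
muscle (0.08, 0.08, 0.5) conduct several-fold better along the cord (z)
than transversely, which is what makes the anisotropic treatment matter:
longitudinal current spreads preferentially along the dorsal columns.

The anatomy is deliberately reduced to concentric circular shells extruded
along z — grey matter ⊂ white matter ⊂ CSF ⊂ epidural fat, wrapped by
vertebral bone, muscle, general thorax, subcutaneous fat and skin — with
air (modeled as a perfectly insulating exterior) beyond the skin. Default
outer radii in mm: grey 1.5, white 4.0, CSF 6.0, epidural fat 9.0, bone
12.0, muscle 15.0, thorax 17.0, fat 18.5, skin 19.5. These are
representative thoracic dimensions chosen once for the default scenario;
every radius, the shell list itself, and optional periodic inter-vertebral
disc bands are configurable. Two leads (radius 0.6 mm) run through the
dorsal epidural fat at x = ±separation/2 (default separation 3 mm, one of
the three clinical lead-spacing settings) and y = 8 mm, each carrying 8
cylindrical contacts of 2 mm length at 4 mm pitch; lead B may be staggered
longitudinally in 0.5 mm steps. Contacts are near-perfect conductors
(4×10⁶ S/m) treated as equipotential Dirichlet node sets; the lead body is
a near-perfect insulator (10⁻¹⁶ S/m).

What the phantom does *not* emulate: vertebral geometry (bone is an
annulus, discs optional bands), dural layers and rootlets, fascicle-level
cord structure, curved or angulated leads, frequency-dependent or
patient-specific properties. Passing tests therefore demonstrate the
correctness and the qualitative steering behavior of the method — current
concentrating on the target, engagement following target position,
graceful handling of disconnected contacts — not quantitative accuracy for
any individual anatomy.

## Discretization and units

The grid is a single uniform structured voxel grid (default spacing
0.5 × 0.5 × 1.0 mm; coarser axially because the field varies slowly along
the cord and contacts stay ≥ 2 voxels long). Voxel centers sit at
(i + ½)h from the domain corner; the grid is sized symmetrically so a
mid-sagittal configuration is exactly mirror-symmetric in x.

The operator is a flux-conservative 7-point finite-volume stencil: the face
between two conduction-domain voxels carries the harmonic mean of their
axis-component conductivities times face area over spacing. Harmonic
averaging is the physically consistent choice for layered media (it is
exact for series resistances, so a face-aligned tissue interface is
resolved exactly) and it keeps metal/tissue faces bounded by the tissue
conductivity. Conductivities are converted to S/mm internally so that with
mm lengths all face conductances are in siemens and electrode currents in
amperes; the two-layer-slab test pins this dimensional convention to the
series-resistor closed form. Faces to the exterior or the grid boundary are
omitted, which is the natural zero-flux (insulating) condition. The
assembled matrix is exactly symmetric with zero row sums, positive
semidefinite with only the constant vector in its null space before
electrodes are pinned.

## Linear solves

All basis fields share one system matrix, so the factorization or
preconditioner is cached on the operator. Systems up to 60k free nodes use
a sparse LU; larger ones use symmetric-mode ILU (drop tolerance 1e-4, fill
factor 10) on the Jacobi-scaled matrix as a preconditioner for BiCGSTAB.
BiCGSTAB is used rather than CG because the incomplete factors are not
exactly symmetric; the iteration is capped at 50·(n_free)^(1/3) and every
solve verifies the true free-node relative residual against rtol = 1e-10,
raising on failure rather than returning a degraded field. Dirichlet values
are exact by construction. The discrete maximum principle (solutions
bounded by the extreme electrode voltages) holds because the stencil is an
M-matrix; the test suite asserts it to 1e-8.

Electrode currents use the matrix-reaction method: apply the assembled
operator to the full solution and sum over an electrode's Dirichlet rows.
This is discretely exact with respect to the assembled system, so
Kirchhoff's current law holds to solver tolerance on every solve. The
conductance matrix Y is built column-wise from the basis fields,
symmetrized by averaging (the observed asymmetry, typically ~1e-12
relative, is recorded and must stay below 1e-4), and its residual
row/column sums — pure solver noise, since the exact Schur complement of
the assembled operator satisfies Y·1 = 0 identically — are deflated to
zero. The deflation is what keeps the net optimal current at machine
precision instead of solver noise amplified by the eigenvector's arbitrary
common mode.

## Energy matrices and current density

C and C0 are assembled from the basis-field current densities:
C_pq = Σ_target (σ∇φ_p)·(σ∇φ_q)·voxel volume, and C0 likewise over the rest
of the conductive tissue, so VᵀCV is exactly the integrated squared current
density of the superposed field in the target. Gradients use central
differences where both axis neighbors are in the domain and one-sided
differences at domain boundaries. Two deliberate choices:

* Integration runs over *tissue* voxels only. A pointwise σ∇f at a metal
  contact voxel multiplies 4×10⁶ S/m by a finite one-voxel potential
  difference — a discretization artifact (the contact cluster is
  equipotential), which would otherwise dominate C0; the lead body carries
  essentially no current by construction. Current density inside the
  implant is not tissue stimulation, so both labels are excluded.
* `current_density` returns J = σ∇f (the sign of the potential gradient;
  the physical current density is its negative). Only ‖J‖² enters the
  optimization, and the sign convention is stated on the function.

The off-target integral covers the full tissue complement of the target,
not a truncated neighborhood.

The target is a cylinder (default diameter 0.5 mm — about half the
internodal distance of a large myelinated fiber — and length equal to the
diameter, giving an isotropic target at the stated scale) with membership
by voxel-center-in-cylinder test. A cylinder smaller than one voxel falls
back to the single nearest grey/white-matter voxel (ties to the lowest
flat index); the fallback is deterministic but can sit up to half a voxel
off the requested center, which slightly breaks exact mirror symmetry —
use a target at least one voxel wide when symmetry matters.

## Optimization

**Two-sided.** The top eigenpair of C V = λ C0 V via `scipy.linalg.eigh`.
If C0 is near-singular (condition > 1e12, or any non-positive eigenvalue) a
ridge of 1e-10·trace(C0)/N is added for the solve; the returned vector is
renormalized against the *unridged* C0 so V*ᵀC0V* = 1 exactly. Because a
constant voltage drives no current and no current density, the common mode
of the eigenvector is physically meaningless; it is projected out
(zero-mean gauge) whenever doing so leaves the Rayleigh quotient unchanged
to 1e-6 relative, which keeps voltages well scaled. The eigenvector sign is
inherently ambiguous; the convention is to orient the solution so the
working electrode nearest the target carries cathodic (negative) current —
the physiologically conventional reading, recorded in every output. A
degenerate top eigenvalue (multiplicity within 1e-10 relative) is resolved
deterministically by maximizing the current magnitude at that nearest
electrode within the eigenspace. The relative gap between the top two
eigenvalues is reported and solutions with gap < 1e-6 are flagged unstable
rather than post-processed.

**Floating electrodes.** B_w is the orthonormal null-space basis of the
floating rows of Y, obtained from a full QR factorization of Y_fᵀ (the SVD
null space serves as the independent oracle in the tests); the reduced pair
D = B_wᵀCB_w, D0 = B_wᵀC0B_w is solved as above and mapped back by
V* = B_w α*. Floating currents vanish to machine precision by construction.
At most N − 2 electrodes may float.

**One-sided.** For each ground/source partition of the working electrodes,
grounded entries are fixed at 0 V (their rows/columns of C and C0 drop),
non-working electrodes are floated through the same null-space reduction,
and the quotient is maximized subject to nonnegative *source* currents.
The nonnegativity applies to source electrodes only: grounds must sink the
return current, whose split among them is governed by the anatomy, so
constraining them would make every partition infeasible. The sign-
constrained problem is non-convex; each partition is solved by SLSQP from
5 starts — the unconstrained eigenvector (sign-corrected or projected onto
the feasible cone) plus 4 pseudo-random feasible points from a fixed seed
(default 20230223) — keeping the best feasible local optimum, and the best
partition wins. Ground sets are enumerated up to 4 electrodes by default
(configurable) to keep the enumeration tractable; with 8 working
electrodes that is 162 subproblems, each a few milliseconds. The reported
"gap" for this variant is the margin to the runner-up partition.

**Selection and percentages.** The clinical rule keeps the k/2 contacts per
lead nearest the target (default k = 8), ties to the lower contact index,
and floats the rest. Percentages are per polarity: positive currents are
normalized by the total sourced current, negative by the total sunk
current, each rounded half-away-from-zero to integers, so each polarity
sums to 100 up to one count per electrode of rounding slack; this matches
the programmer-UI convention of reporting source and sink splits
separately.

## Activating function

The stimulation readout is the classical activating function: the second
difference (f_{k−1} − 2f_k + f_{k+1})/h² of the extracellular potential
sampled by trilinear interpolation along a fiber path, default a z-aligned
dorsal-column line through the target at 1 mm node spacing (twice the
0.5 mm half-internodal scale). Positive values indicate depolarization
drive. Note a structural consequence of the objective: the optimum builds a
longitudinal current dipole through the target, so the potential is
antisymmetric about the target plane and the activating function crosses
zero exactly there, peaking at the flanking cathodic contacts. The full
cable-model derivation (and any neuron model) is out of scope; the second
difference is used as an indicator only.

## Problem sizes

The default scenario is an 80×80×40 grid (~192k free nodes, 16 contacts),
which runs the full pipeline in a few minutes on one CPU; the test suite
exercises the same code paths on a compressed phantom (56×56×24, 8
contacts, direct solver) plus analytic slabs and toy systems, keeping the
suite at about half a minute. The acceptance script uses the full default
scenario.

## Known limitations

Local (not global) optimality for the one-sided variant; relative current
distributions only (absolute amplitude titration is a clinical step);
structured grids only, with no adaptive refinement; diagonal conductivity
tensors; no neuron-model thresholding. Near-degenerate optima can flip
between voxel-symmetric patterns under discretization perturbations — the
eigen-gap flag exists precisely to surface those cases.
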