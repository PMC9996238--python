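# cordsteer

Current-steering optimization for targeted spinal cord stimulation (SCS).

Multi-electrode epidural leads can focus stimulation on a chosen region of
the spinal cord — but only if the current sourced and sunk through each
contact is chosen well. `cordsteer` computes that optimal electrode
excitation pattern on a synthetic spine volume-conductor phantom. It is
aimed at neural-engineering researchers and stimulation-device engineers
who want a transparent, scriptable reference implementation of
eigenvalue-based current steering: phantom in, per-electrode current
percentages out.

## The method

The extracellular potential f obeys the quasi-static anisotropic Poisson
equation over the body domain Ω,

    ∇·(σ(x) ∇f(x)) = 0,   x ∈ Ω,

with Dirichlet conditions on the electrode contacts and an insulating outer
boundary. Discretizing Ω as a labeled voxel grid (grey/white matter, CSF,
epidural fat, bone, muscle, thorax, fat, skin — white matter and muscle are
anisotropic along the cord) and solving one unit-voltage basis field φ_q per
electrode gives, by superposition, the field of any excitation V =
(v_1 … v_N)ᵀ. Three derived objects drive the optimization:

* **Y** — the N×N electrode conductance matrix, I = Y V, with Y symmetric
  (reciprocity) and Y·1 = 0 (charge conservation);
* **C, C0** — symmetric PSD matrices such that VᵀCV and VᵀC0V are the
  integrated squared current density ∭‖σ∇f‖² inside the cylindrical target
  region Ω_T and in the rest of the tissue Ω−Ω_T.

Steering maximizes the Rayleigh quotient

    max_V  VᵀCV / VᵀC0V      ⇔      C V = λ C0 V,

whose top generalized eigenpair (λ*, V*) is the optimum, normalized to
V*ᵀC0V* = 1; the currents are I* = Y V* and are reported as per-polarity
integer percentages, the convention used by clinician programmers. Two
constrained variants are included:

* **disconnected (floating) electrodes** — zero current through a broken
  contact is enforced by restricting V to the null space of the floating
  rows of Y (orthonormal basis B_w via QR), giving the reduced problem
  D α = λ D0 α with D = B_wᵀ C B_w;
* **one-sided (anodic-only) sources** — hardware with only current sources
  requires grounded return contacts and nonnegative source currents; every
  ground/source partition of the working electrodes is enumerated, the
  grounded rows/columns of C and C0 are deleted, and each sign-constrained
  problem is solved by multistart SLSQP (the constraint breaks the
  eigenstructure, so optima are local).

A clinical selection rule keeps at most the k = 8 contacts (4 per lead)
nearest the target active and floats the rest, and an activating-function
readout (second spatial difference of the potential along a dorsal-column
fiber, in V/mm²) indicates where depolarization is driven.

## Worked example

Configs are plain JSON with `geometry`, `materials`, `leads`, `target`,
`solver` and `steering` sections; every key has a sensible default. A
compact two-lead scenario (4 contacts per lead, target on the mid-plane
between the leads in dorsal white matter):

```json
{
  "geometry": {"spacing": [0.5, 0.5, 1.0], "z_length": 24.0,
               "shells": [["grey_matter", 1.0], ["white_matter", 2.5],
                          ["csf", 4.0], ["epidural_fat", 6.0],
                          ["vertebral_bone", 8.0], ["muscle", 10.0],
                          ["thorax", 11.5], ["fat", 12.5], ["skin", 13.5]]},
  "leads":  {"separation": 3.0, "depth_y": 5.0, "n_electrodes": 4},
  "target": {"center": [0.0, 2.0, 0.0], "diameter": 1.2}
}
```

```bash
cordsteer steer example_config.json -o steer_out
```

prints (actual output):

```
variant: two_sided   lambda* = 7.26778e-05
lead A        lead B
A4  +  24%    B4  +  24%
A3  +  26%    B3  +  26%
A2  -  26%    B2  -  26%
A1  -  24%    B1  -  24%
legend: + source  - sink  G ground  . floating
```

λ* is the optimal target/off-target energy ratio; the signs say contacts
A3/B3 and A4/B4 above the target act as anodic sources while A1/B1 and
A2/B2 below it sink the return current, forming a longitudinal dipole
focused on the target, and the percentages split each polarity's total
current (sources sum to 100, sinks sum to 100). The mirror symmetry between
leads A and B reflects the mid-plane target. `steer_out/` additionally
holds the solution JSON, the serialized Y/C/C0 matrices, and an
activating-function profile; `--vtk` exports potential and current-density
volumes as legacy VTK for visual inspection.

Other verbs: `cordsteer phantom` (label volume export), `solve` (field for
explicit voltages), `activation` (fiber profile), `report` (re-render a
saved solution). The library API (`cordsteer.run_pipeline`,
`solve_two_sided`, `solve_with_floating`, `solve_one_sided`, …) exposes
every intermediate object, and the optimizer also accepts matrices loaded
from the serialized JSON, so it can steer from externally computed field
solutions.

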