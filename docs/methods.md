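# Methods

## Model

Illumination is decomposed into direct light and an indirect remainder; only
the indirect part is modeled here, as smooth low-frequency ambient light that
is independent of the camera. The physical motivation is the shadowless
surgical lamp: when the emitting area is large enough relative to an
occluder, the umbra vanishes, and a spherically symmetric arrangement of many
such sources makes the angular dependence of the illumination cancel. The
renderer then adds a per-ray transmitted-light term so that images keep
directional contrast without any per-frame global-illumination work.

Both stages operate on a transfer-function classified volume: a scalar grid
(e.g. CT in HU) plus a piecewise-linear map intensity → (r,g,b,α). Opacity α
is the only material property the photon physics sees; color enters at
fusion time only, which is why the ambient field is scalar.

## Precompute stage

**Light rig.** Directions come from a spherical Fibonacci lattice (72 by
default), rotated rigidly by a seeded rotation so different seeds decorrelate
placement without changing uniformity. Each light is a circular disk
centered on the circumscribed sphere of the volume (radius = half the box
diagonal), facing the center, with disk radius 1.05× the sphere radius —
strictly wider so the parallel beam covers the entire dataset, which is the
condition for shadow-free coverage. Intensities are equal, summing to 1.

**Photon transport.** Rays start at stratified positions on each disk
(jittered sqrt-radial/golden-angle spiral, seeded per light via a seed
sequence so light order is irrelevant) and march at 0.5× the smallest voxel
spacing. An interaction happens at every sample whose α > 0. The energy
split per interaction is transmitted `E(1−α)`, reflected `E·min(F, α)` with
Schlick reflectance `F = F0 + (1−F0)(1−cos θ)^5` about the local
intensity-gradient normal, and the remainder deposited into the field cell
(nearest voxel) containing the sample. Clamping the reflectance at α keeps
deposits non-negative; a further max(·, 0) guards the one-ulp negative that
floating point can produce when the clamp binds. Where the gradient
magnitude is below 1e-6 intensity/mm no normal is defined, so the would-be
reflected share folds into the deposit — this keeps the energy ledger exact
in homogeneous regions. Reflected children carry depth+1 and are traced with
an explicit stack; children below ε or deeper than the cap are dropped. The
transmitted continuation does not increase depth: depth counts mirror
bounces, and the straight-through chain is already geometrically bounded by
the box and ε.

**Accounting.** Every trace returns (deposited, exited, dropped); their sum
equals the launch energy to better than 1e-9 (measured ~1e-15). The field
total is therefore bounded by the total emission (1.0), and the per-run
ledger is stored in the field's provenance together with the
transfer-function hash, the full config and the seed.

## Rendering stage

One ray per pixel (orthographic by default, with pixel pitch defaulting to
the voxel pitch so image resolution matches the data; perspective is
available). Per sample with α > 0: classify the trilinear intensity, read
the ambient field, update the transmitted energy `L_CT = E·α`,
`E ← E(1−α)` (no refraction on the view ray — its effect on transmitted
light is negligible and it would double the per-sample cost), and accumulate
`C·α·(L_interp·dim1 + L_CT·dim2)`. Marching stops when the accumulated
opacity reaches 1 or the ray exits; the "accumulated transparency greater
than 1" stopping phrase is implemented as accumulated *opacity* ≥ 1, the
only physically meaningful reading. The pixel is the plain sum of fused
contributions clamped to [0,1] at the end — deliberately not front-to-back
over-compositing, so the image is exactly linear in (dim1, dim2); rays that
never meet material show the background color.

**Ambient interpolation.** Inverse-distance weighting over the 8 field cells
surrounding the sample (weights 1/D_i, normalized; a query within 1e-9 mm of
a cell center returns that cell exactly). Because deposits are sparse,
neighborhoods legitimately contain zero-valued cells; distance weighting
blends across them smoothly instead of treating them as hard holes. A plain
trilinear mode is selectable for comparison.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `n_lights` | 72 | — | dense enough that angular banding on a sphere is < 10 % |
| `rays_per_light` | 1024 | — | ~15 deposits per surface voxel of a 64³ phantom |
| `epsilon` | 1e-3 | energy fraction | bounds the split tree; ≤ 0.1 % of a photon ignored |
| `max_depth` | 8 | bounces | reflected cascades below ε long before this in practice |
| `f0` | 0.04 | — | conventional dielectric normal-incidence reflectance |
| `gradient_threshold` | 1e-6 | intensity/mm | below it a surface normal is numerically meaningless |
| `step` | 0.5 | × min voxel spacing | Nyquist-ish sampling of the classified volume |
| `disk_radius_factor` | 1.05 | × R_radius | strictly wider than the circumsphere → full coverage |
| `dim1`, `dim2` | 0.5, 0.5 | — | free brightness knobs; the field stores raw energy, so a display-scale dim1 is ~1/max(field) |

The ambient field is deliberately *unnormalized* deposited energy: its
absolute scale depends on photon count and geometry, and `dim1` absorbs it.
The transmitted term starts at E = 1 per ray, with `dim2` as its scale.

## Field geometry

The field is voxel-aligned by default: one cell per voxel, same spacing and
origin, so cell (i,j,k) sits on voxel (i,j,k). An alternative "physical"
mode re-expresses the z extent on the in-plane pixel pitch
(`Vpz = (Vz−1)·Ps`), useful when slices are much thicker than pixels;
`field_dimensions` exposes both. All physical coordinates are millimetres
with the voxel-center convention (voxel i at `origin + i·spacing`; the box
extends half a voxel beyond the outer centers).

## Synthetic data

The phantom generator emulates the *geometric* situations that matter for
this pipeline — occluding solids (sphere), hollow structures (shell),
material interfaces (two-material block), and a one-voxel column whose
photon trace is hand-computable — with exact analytic ground truth
(inside-predicates, voxel counts, projected silhouettes). It is
deterministic from (spec, dims, spacing, seed); Gaussian intensity noise is
opt-in and off by default. It does **not** emulate anatomy, partial-volume
ramps, CT reconstruction artifacts, beam hardening, or realistic tissue
histograms. Passing tests therefore demonstrate the correctness of the
transport, accounting, interpolation and rendering machinery on resolvable
geometry — not clinical image quality, which additionally depends on
transfer-function design and data characteristics the phantoms idealize
away.

## Numerical choices

- Double precision throughout the transport; the compiled (numba) inner
  loops mirror the pure-Python primitives operation-for-operation, and a
  naive exhaustive enumeration of the full split tree agrees with the
  compiled tracer per-cell to ~1e-16 on small volumes.
- Rays are clipped to the box by the slab method and sampled at
  `t_enter + (s+0.5)·step`, so the first sample is strictly inside and a
  tangent ray yields no samples.
- Trilinear sampling clamps fractional indices into the half-voxel margin;
  outside the box it returns 0 under the renderer's clamp flag (exiting rays
  carry no material).
- Deposits go to the nearest cell (no splatting): splatting would smear the
  oracle comparison and the coverage counts; smoothness is instead provided
  by the inverse-distance gather at render time.
- The gradient uses central differences of the trilinear interpolant one
  voxel spacing apart (one-sided at faces) — exact for axis-linear fields.
- Ties and degenerate cases: undefined normals fold reflection into the
  deposit; a zero-length reflected vector cannot occur (the mirror of a unit
  vector is unit); cameras reject parallel view/up; volumes reject any
  dimension < 2, non-positive spacing, or non-finite intensities.

## Design choices that were genuinely open

- **Coverage-vs-radius study with nested apertures.** Growing the source
  disk while holding the ray count fixed confounds the geometric claim
  (bigger sources reach more of the volume) with sampling density (the same
  rays spread over 16× the area). `coverage_experiment` therefore generates
  each light's ray set once at the largest radius and lets smaller apertures
  emit the subset of rays inside them: a smaller disk is then literally a
  masked version of the larger one, and illuminated coverage grows
  monotonically with radius as a property of the geometry, not of luck.
- **Reflection direction** is the mirror about the normalized gradient; the
  split itself does not prescribe one, and mirroring is the standard
  surface-like choice consistent with using Schlick at the same interface.
- **Depth counts only reflections**, so translucent media are not
  artificially truncated after a few straight-through interactions.
- **Per-event α** is the transfer function of the sampled intensity, with no
  step-length opacity correction: the split is defined per interaction
  event, making `step` a resolution knob (finer steps → more, smaller
  events), documented rather than hidden.

## Known limitations

- No direct/key-light term and no hard shadows: the renderer is ambient +
  transmitted only; contrast comes from the transmitted arm.
- The plain summed accumulation (rather than over-compositing) can saturate
  bright translucent stacks; values are clamped, not tone-mapped.
- Nearest-cell deposition aliases on thin structures at low photon counts;
  raise `rays_per_light` rather than the step.
- The precompute must be redone whenever the transfer function changes; the
  provenance hash enforces this (a stale field refuses to render).
- Single-threaded by design for bit-reproducibility; per-light partial
  fields are summed in a fixed order, so a parallel driver would need the
  same deterministic reduction.
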