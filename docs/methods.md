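# Methods

## Problem and scope

Clinical evaluation of the external ear (auricle) uses a small set of
aesthetic parameters: length and width of the pinna, its protrusion from
the head, the auriculocephalic (AC) opening angle, the inclination of
its long axis, and the bilateral position difference of the two ears.
Manual measurement — calipers on the patient or landmark clicks on a 3-D
model — is imprecise because it depends on a handful of operator-chosen
points.  This package implements a landmark-free, surface-based
alternative: all parameters are derived automatically from a triangulated
head surface (measured directly on a mesh, or reconstructed from a CT
volume), each one supported by hundreds to thousands of surface points.

## Pipeline

### Surface reconstruction from CT (`segmentation`)

1. **Bone step** — region growing (26-connected component above
   +500 HU from a seed) followed by morphological closing with a
   spherical element (default radius 10 mm, large enough to seal orbit,
   sinus and ear-canal openings at clinical voxel sizes) plus a fill of
   fully enclosed background cavities (6-connected components not
   touching the volume border; the 26/6 connectivity pairing avoids the
   classic tunnel paradox).  The closing is computed with two Euclidean
   distance transforms, which is exact for a ball and fast at any radius.
2. **Soft-tissue step** — region growing above −500 HU, *without*
   closing, so fine relief of the auricle is not smeared shut.  The head
   mask is the union of the closed bone and the soft tissue.
3. **Level-set refinement** — the mask's signed distance function
   (positive outside) is evolved for 20 iterations with outward speed
   proportional to −∇²(G₁ₘₘ ∗ I): the Laplacian of the Gaussian-smoothed
   volume changes sign across an intensity edge, so the front expands
   while still inside the bright tissue, contracts outside it, and
   settles on the Laplacian zero crossing.  An upwind (Osher–Sethian)
   scheme advances the front; a ∇²φ term (equal to κ|∇φ| for a
   distance-like φ, weight 0.2) regularizes against noise; the time step
   obeys both the CFL bound (0.45·h) and the explicit-diffusion bound
   (h²/8D).  Updates are restricted to a band of ±3 mm around the initial
   surface, so the refined contour cannot drift away from the
   initialization; with 0 iterations the signed distance is returned
   unchanged.  Volumes with more than 5 % spacing anisotropy are
   resampled to isotropic spacing first so the smoothing SD is isotropic
   in mm.
4. **Meshing** — marching cubes at the zero level, in world millimetres.
   When grid nodes fall exactly on the level the level is nudged by a
   relative 1e-4 (micrometre scale) to avoid degenerate triangles.  The
   global face orientation is fixed by the sign of the enclosed volume.

### Anatomical frame (`frame`)

The coordinate system needs no landmarks:

* **Mid-sagittal plane** — the plane (longitude, latitude, offset)
  minimizing the trimmed mean nearest-neighbour distance between the head
  vertices and their mirror image.  Distances above mean + 0.5·SD
  (population SD, recomputed at every cost evaluation) are discarded, so
  moderate asymmetry — including a missing auricle — does not bias the
  plane.  Because reflection is an isometry of the same vertex set, the
  original→mirrored and mirrored→original distance multisets are
  identical; one KD-tree on the original vertices serves every cost
  evaluation.
* **Cranio-caudal axis** — a six-parameter cylinder (axis direction,
  axis point, radius) fitted by the same trimmed cost against a sampled
  cylinder mesh of 250 vertices spanning the head's axial extent.  The
  cost is the exact distance to that faceted surface (per-sector chord
  distance, closed form), with the facets straddling the nominal radius
  so the chordal error has zero mean and the fitted radius is unbiased.
* **Optimization** — Nelder–Mead (tolerances 1e-4, ≤500 iterations,
  initial steps 2°/2 mm), started from principal-axis candidates: the
  trimmed cost deliberately tolerates local asymmetry, so each principal
  axis is briefly descended and the best becomes the start.  Because the
  trimmed cost is only piecewise smooth (the trimmed subset changes with
  the parameters), the simplex can stall on plateaus; two fresh-simplex
  restarts, a deterministic 0.25°-grid rescan over the two orientation
  angles, and a compass-search polish make convergence reproducible.
  Meshes above 20 000 vertices are subsampled (seeded) for cost
  evaluation; final costs are reported on the full vertex set.
* **Frame assembly** — x̂ is the sagittal normal oriented toward the left
  ear (chirality cannot be inferred from geometry; a `left_hint` from
  scanner orientation metadata is mandatory), ŷ the cylinder axis
  Gram–Schmidt-orthogonalized against x̂ and pointing cranially (world +y
  convention, or an explicit `cranial_hint`), ẑ = x̂ × ŷ, and the origin
  is the vertex centroid projected into the sagittal plane.

### Auricle extraction (`extraction`)

A box aligned with the frame encloses each auricle.  Parallel lines
(0.3 mm spacing, running medial→lateral) are cast through the box; a
line crossing the surface at least twice *inside the box* passes through
the free-standing pinna (elsewhere the scalp is crossed once), and its
most-lateral crossing lies on the outer auricle surface.  Because all
lines are parallel, the intersection test is a scanline rasterization:
each triangle is projected onto the box face and evaluated only at the
grid nodes inside its footprint, so no spatial index is needed even at
350 k lines.  Kept grid points are triangulated cell-wise (two triangles
per complete 2×2 cell, one for three-corner cells) and a total-least-
squares plane through them — the SVD of the centered coordinates — is
the *auricle plane* (normal oriented laterally).

The *mastoid outline* is obtained by projecting the hull of the
in-plane auricle points (convex by default; a concave-outline variant
sits behind a config flag) into the sagittal plane and casting each hull
point back laterally onto the head.  A qualifying hit must be farther
than ε = 0.5 mm from every selected auricle point *and* be an exit
crossing (outward face normal along the ray): the mastoid skin faces
laterally, while the back of the auricle faces medially.  Up to 20 % of
rays may fail (concave geometry) before an error is raised.  A
least-squares plane through the mastoid points is the *mastoid plane*.

### Parameters (`parameters`)

With the auricle points projected into the auricle plane (in-plane basis
aligned with the projection of ŷ):

* **AC angles** — angle between laterally-oriented normals of the
  auricle plane and the sagittal plane, and of the auricle plane and the
  mastoid plane.
* **Protrusion** — maximum signed distance of the selected points from
  the mastoid plane.
* **Length/width, diameter variant** — the largest in-plane point-pair
  distance is the length (line L; ties broken by the lexicographically
  smallest index pair); the extent of all points projected perpendicular
  to L is the width (line W through the point farthest from L).
* **Length/width, PCA variant** — the planar inertia tensor
  [[Σv², −Σuv], [−Σuv, Σu²]] of the centered points is
  eigen-decomposed; the smallest-inertia eigenvector is the elongation
  axis, and the bounding-rectangle extents along the two eigenvectors are
  length and width.  Near-equal eigenvalues (relative gap < 1e-9) fall
  back to the coordinate axes and set an isotropy flag.  For strongly
  non-convex point sets the variance and extent orderings can disagree;
  the axes are then relabeled so width ≤ length always holds (a no-op
  for auricle-like shapes).
* **Inclination** — the 3-D length axis (PCA eigenvector lifted to 3-D,
  or the segment between L's unprojected endpoints) is projected into
  the sagittal plane; the angle to ŷ, sign-invariant in [0°, 90°], is
  the inclination.  A signed variant (positive when the cranial end
  leans posteriorly) is available behind a flag.
* **Position** — the selection-box centers represent the auricle
  centers; projected into the sagittal plane, the left-minus-right
  differences along ẑ and ŷ are the posterior–anterior and
  superior–inferior position differences.

Values are serialized with three decimals; sub-micrometre digits carry
no measurement meaning.

### Statistics (`precision`)

Long-format tables (specimen, side, method, observer_or_repeat, scanner,
dose, parameter, value) are analyzed with: sample SDs per condition
(precision), classic Levene tests (mean centering; Brown–Forsythe median
centering behind a flag) comparing variability between methods, one-way
ANOVA with Tukey-HSD post hoc for mean differences, per-parameter OLS on
dummy-coded method/scanner/dose factors, and error percentages of each
method's mean against the caliper reference (rounded to whole percent).
Observers and rounds are pooled into repeats by default; no
multiple-testing correction is applied across parameters (per-parameter
reporting), with Holm adjustment available as an option.  "Multivariate"
regression is implemented as per-parameter multiple regression, not a
multivariate-response model.

## Synthetic phantoms (`synthetic`)

No study scans are publicly available, so validation uses phantoms whose
ground truth is exact by construction:

* **Head with ears** — a superellipsoid head (default semi-axes
  78 × 95 × 72 mm; superellipse exponent 3.5 along ŷ gives the
  barrel-like cranium that makes the cylinder axis well conditioned; an
  "egg" factor 0.05 elongates the front, breaking antero-posterior
  symmetry the way a face does, so the symmetry-plane search is
  unambiguous) with flat lateral faces at 0.9·a — the exact mastoid
  planes.  Each ear is a thin elliptical prism whose *lateral face*
  realizes the requested parameters exactly: the long axis lies in the
  wall plane at `inclination`° from ŷ (its sagittal projection is then
  itself, so the measured inclination equals the requested one), the
  face is tilted `ac_angle`° about that axis, and the whole flap floats
  `protrusion − width·sin(ac_angle)` lateral of the wall so its far edge
  sits at exactly `protrusion`.  The prism is extruded medially *along
  the projection-line direction*, so its shadow equals its lateral face
  and grid lines can never select a side-wall point; a slanted stem
  whose shadow lies strictly inside the flap's welds it to the head for
  connectivity in voxel space.  The head tessellation carries a seeded
  0.3 mm tangential jitter applied mirror-symmetrically: it emulates
  surface-reconstruction roughness and removes the sampling resonances
  of a regular tessellation while keeping the head exactly bilaterally
  symmetric.
* **Wall + flap** — a slab plus disc flap with analytic truth for the
  mastoid plane, protrusion (= offset + radius·sin(tilt)) and both AC
  angles; the unit-test fixture for the extraction geometry.
* **CT voxelization** — crossing-parity rasterization of the watertight
  phantom onto a CT grid (soft tissue 40 HU, an interior bone core at
  1200 HU, air −1000 HU) with seeded Gaussian noise of SD
  `noise_sd/√dose`; scanner presets (high-end 10 HU, low-end 25 HU at
  dose 1) are invented instrument emulations, not measured values.
  Repeat-scan simulation draws an independent seeded rigid repositioning
  (rotation ≤ 10°, translation ≤ 20 mm) and fresh noise per repeat.

What the phantoms do **not** emulate: the folded relief of a real pinna
(helix, antihelix, concha), beam hardening and scatter, partial-volume
effects beyond simple voxel averaging, and soft-tissue deformation
between scans.  Passing tests therefore demonstrate that the geometry
pipeline measures what it claims on surfaces whose truth is known — not
that a real auricle's clinically reported values would be reproduced.

## Validation conditions and problem sizes

The default head phantom (ears 60 × 35 mm, inclination 20°, protrusion
18 mm, AC 30°, one ear offset by (2, 3) mm) is measured end-to-end with
a derived frame; recovery is within 1 mm / 1° on every parameter and
invariant under arbitrary rigid repositioning to within the same
tolerance.  The repeated-scan study uses a half-scale head
(40 × 50 × 45 mm, ears 30 × 18 mm, protrusion 13 mm — keeping a 4 mm
air gap behind the flap, which must exceed the voxel size or the gap
fuses shut in voxel space) at 0.6 mm voxels with the high-end noise
preset and 20 repeats; these sizes keep the full study at desk scale
while leaving dozens of voxels across every measured feature.
Segmentation fidelity is checked at 0.5 mm voxels against spheres and
the half-scale head.

On these conditions the repeat study reproduces the method-comparison
structure expected from the measurement design: the PCA-based width and
inclination are more precise than the diameter-based variants (the
diameter rests on two extreme grid points and inherits the full
discretization error, the inertia tensor averages over thousands), and
the AC angle against the sagittal plane is more precise than against the
mastoid plane (the sagittal plane is supported by the whole head
surface, the mastoid plane by a small outline).

## Numerical choices and edge cases

* Ray–mesh hits closer than 1e-6 mm along the line are merged so shared
  triangle edges do not break crossing parity.
* Collinear inputs to plane fits, hulls and inertia axes raise
  degenerate-geometry errors; a length axis parallel to x̂ (no sagittal
  projection) raises a degenerate-inclination error; a cylinder axis
  within 10° of the sagittal normal raises a degenerate-frame error.
* Optimizer non-convergence raises a convergence error carrying the best
  parameters found.
* All randomness (jitter, noise, repositioning, subsampling) flows
  through seeded NumPy generators; identical seeds give bit-identical
  phantoms and reports.

## Known limitations

* The selection principle requires the pinna to stand clear of the
  scalp by more than the CT voxel size; flush or taped-back ears leave
  too few two-crossing lines.
* The mastoid plane degrades when the auricle hull projects onto
  strongly concave skin (ε-exclusion then rejects most rays); the
  pipeline reports the failure instead of guessing.
* Left/right and cranial/caudal orientation must come from scan
  metadata or the user; geometry alone cannot provide chirality.
* The cylinder axis of a nearly spherical head is ill-conditioned; the
  fit is robust for head-like aspect ratios but degenerates gracefully
  (larger reported cost) otherwise.
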