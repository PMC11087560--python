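# auriclometry

Automated, surface-based 3-D measurement of human auricle (external ear)
parameters from head-surface meshes — optionally reconstructed from CT
volumes — for plastic-surgery planning, otoplasty evaluation and
craniofacial morphometry research.

Manual auricle measurements (calipers, or landmark clicks on a 3-D
model) rest on a handful of operator-chosen points and are notoriously
variable.  This package measures the clinically used parameters from the
*whole* auricle surface instead:

| parameter | definition used here |
|---|---|
| length, width | extents of the auricle points projected into the least-squares **auricle plane**, either from the largest point-pair distance *L* and the extent perpendicular to it (**diameter** variant) or from the bounding rectangle along the planar **inertia-tensor** eigenvectors (**PCA** variant) |
| protrusion | largest perpendicular distance from the **mastoid plane** (fit to the skin behind the auricle) to any auricle point |
| auriculocephalic angle | angle between the auricle-plane normal and the mid-sagittal-plane normal (or the mastoid-plane normal), both oriented laterally |
| inclination | angle between the sagittal projection of the length axis and the cranio-caudal ŷ axis |
| position (P–A, S–I) | left-minus-right difference of the auricle centers projected into the sagittal plane, along ẑ and ŷ |

The anatomical frame itself is landmark-free: x̂ is the normal of the
mid-sagittal symmetry plane (found by minimizing the outlier-trimmed
mean nearest-neighbour distance between the head and its mirror image,
Nelder–Mead over longitude/latitude/offset), ŷ is the axis of a cylinder
fitted to the head by the same trimmed cost, and the origin is the head
centroid projected into the sagittal plane.  The auricle surface is
selected by a dense grid (0.3 mm) of medial→lateral projection lines: a
line that crosses the surface at least twice inside the selection box
passes through the free-standing pinna, and its most-lateral crossing
lies on the outer auricle surface.

CT volumes are turned into head surfaces by a two-step segmentation
(bone > 500 HU with cavity closing, soft tissue > −500 HU without),
refined by a band-limited Laplacian level set on the 1 mm
Gaussian-smoothed volume (20 iterations) and meshed with marching cubes.

Because no clinical scans ship with the package, a synthetic phantom
generator produces heads with ear flaps whose length, width,
inclination, protrusion, AC angle and bilateral offsets are realized
*exactly*, plus voxelized CT volumes with dose-dependent noise and
repeat-scan repositioning — every stage is validated against analytic
ground truth.  A statistics harness (per-condition SDs, Levene variance
tests, ANOVA + Tukey, per-parameter regression on method/scanner/dose,
caliper-relative error percentages) reproduces the analyses of a
repeated-measurement precision study.

## Worked example

```python
from auriclometry import EarSpec, make_head_with_ears, measure_all

# a head phantom whose left ear is 60 x 35 mm, inclined 20 deg,
# protruding 18 mm at a 30 deg AC angle, shifted (2, 3) mm vs the right
mesh, truth = make_head_with_ears(EarSpec(center_offset=(2.0, 3.0)), EarSpec())

result = measure_all(
    mesh, truth.left.box, truth.right.box,
    left_hint=[1, 0, 0], cranial_hint=[0, 1, 0],   # from scan orientation
)
left = result.left.to_dict()
for key in ("length_pca_mm", "width_pca_mm", "protrusion_mm",
            "ac_angle_sagittal_deg", "ac_angle_mastoid_deg", "inclination_pca_deg"):
    print(f"{key:24s} {left[key]}")
print("position", result.position.to_dict())
```

prints

```
length_pca_mm            59.874
width_pca_mm             34.953
protrusion_mm            17.984
ac_angle_sagittal_deg    30.0
ac_angle_mastoid_deg     30.0
inclination_pca_deg      19.427
position {'delta_pa_mm': 3.0, 'delta_si_mm': 2.0}
```

Every value is recovered from the mesh alone — the frame is re-derived,
not taken from the construction — within a few tenths of a millimetre or
degree of the built-in truth (60 / 35 / 18 / 30 / 20, position 3 / 2);
the residuals reflect the 0.3 mm selection grid and the phantom's
simulated surface roughness.

## Command line

```bash
auriclometry segment scan.nii.gz -o head.ply            # CT -> surface
auriclometry frame head.ply -o frame.json --left-hint 1,0,0
auriclometry extract head.ply --frame frame.json --box left_box.json -o auricle.ply
auriclometry measure head.ply --left-box L.json --right-box R.json -o params.json
auriclometry synth head -o phantom.ply --truth truth.json
auriclometry synth ct phantom.ply -o scan.nii.gz --scanner high_end --dose 0.5
auriclometry study measurements.csv -o report.json
```

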