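"""Synthetic phantoms with exact analytic ground truth.

Three families of phantoms support testing without any scan data:

* **wall+flap micro-phantoms** — a slab ("mastoid" wall) with a thin disc
  flap in front of it; exact truth for the mastoid plane, protrusion and
  both auriculocephalic angles.
* **parametric heads with ears** — a truncated ellipsoid head whose flat
  lateral faces play the mastoid surface, with a thin elliptical ear flap
  per side hinged just lateral of the face.  Every requested ear
  parameter (length, width, inclination, protrusion, AC angle, bilateral
  offsets) is realized exactly on the flap's lateral face, so the truth
  record simply echoes the specification.
* **voxelized CT volumes** — crossing-parity rasterization of a watertight
  phantom onto a CT grid (soft tissue 40 HU over −1000 HU air, an
  interior bone core at 1200 HU) with seeded Gaussian noise whose SD
  scales as ``noise_sd/√dose``, and repeat-scan simulation with random
  rigid repositioning between scans.

Ear construction: the flap's long axis (the hinge) lies *in* the lateral
wall plane at ``inclination`` degrees from the cranio-caudal ŷ axis;
because that axis stays parallel to the sagittal plane, its sagittal
projection is itself and the measured inclination equals the requested
one exactly.  The flap plane is tilted ``ac_angle`` about the hinge, and
the whole flap floats ``g0 = protrusion − width·sin(ac_angle)`` lateral
of the wall so its far edge sits at exactly ``protrusion``.  A slanted
stem, whose lateral shadow lies strictly inside the flap's shadow (so it
can never be selected as a most-lateral point), welds the flap to the
head for connectivity in voxel space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .errors import ArgumentError, ConstructionError
from .extraction import SelectionBox
from .frame import AnatomicalFrame
from .geometry import Plane, parallel_grid_intersections
from .parameters import PositionDifference
from .segmentation import CTVolume

__all__ = [
    "EarSpec",
    "ScanSpec",
    "EarTruth",
    "HeadTruth",
    "WallFlapTruth",
    "SCANNER_NOISE_SD_HU",
    "make_wall_flap_phantom",
    "make_head_with_ears",
    "voxelize_to_ct",
    "simulate_repeat_scans",
]

# invented instrument presets (baseline noise SD in HU at dose factor 1)
SCANNER_NOISE_SD_HU = {"high_end": 10.0, "low_end": 25.0}

_X = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class EarSpec:
    """Ground-truth ear parameters realized by :func:`make_head_with_ears`.

    Defaults are a plausible adult auricle: 60 × 35 mm, 20° inclination,
    18 mm protrusion, 30° auriculocephalic angle, centered on the lateral
    face.  ``center_offset`` shifts the ear (Δy cranial, Δz posterior).
    """

    length_mm: float = 60.0
    width_mm: float = 35.0
    inclination_deg: float = 20.0
    protrusion_mm: float = 18.0
    ac_angle_deg: float = 30.0
    center_offset: tuple = (0.0, 0.0)

    def __post_init__(self):
        if not self.length_mm > self.width_mm > 0:
            raise ArgumentError("need length > width > 0")
        if not 0 <= self.inclination_deg < 90:
            raise ArgumentError("inclination must be in [0, 90)")
        if not 0 <= self.ac_angle_deg < 90:
            raise ArgumentError("AC angle must be in [0, 90)")


@dataclass(frozen=True)
class ScanSpec:
    """CT acquisition emulation: voxel grid, noise level and repositioning.

    Noise SD scales as ``noise_sd_hu / sqrt(dose_factor)`` — halving the
    dose inflates the noise SD by √2.  Repositioning draws a random rigid
    transform (rotation ≤ ``max_rotation_deg``, translation ≤
    ``max_translation_mm``) per repeat.
    """

    voxel_mm: tuple = (0.46, 0.46, 0.45)
    noise_sd_hu: float = 10.0
    dose_factor: float = 1.0
    max_rotation_deg: float = 10.0
    max_translation_mm: float = 20.0
    pad_mm: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_mm) or self.dose_factor <= 0:
            raise ArgumentError("voxel sizes and dose factor must be positive")

    @classmethod
    def from_scanner(cls, scanner: str, dose_factor: float = 1.0, seed: int = 0, **kw):
        return cls(
            noise_sd_hu=SCANNER_NOISE_SD_HU[scanner],
            dose_factor=dose_factor,
            seed=seed,
            **kw,
        )


@dataclass
class EarTruth:
    side: str
    plane: Plane  # the auricle (flap lateral face) plane, normal lateral
    mastoid_plane: Plane  # the flat lateral head face, normal lateral
    length_mm: float
    width_mm: float
    inclination_deg: float
    protrusion_mm: float
    ac_angle_sagittal_deg: float
    ac_angle_mastoid_deg: float
    center: np.ndarray  # flap center, frame coordinates
    apex: np.ndarray  # most lateral flap point, frame coordinates
    box: SelectionBox  # suggested selection box, frame coordinates


@dataclass
class HeadTruth:
    frame: AnatomicalFrame
    sagittal: Plane
    left: EarTruth | None
    right: EarTruth | None
    position: PositionDifference | None
    head_axes: tuple
    wall_x_mm: float


@dataclass
class WallFlapTruth:
    mastoid_plane: Plane
    auricle_plane: Plane
    protrusion_mm: float
    ac_angle_sagittal_deg: float
    ac_angle_mastoid_deg: float


def _ellipse_prism(
    center: np.ndarray,
    axis_a: np.ndarray,
    semi_a: float,
    axis_b: np.ndarray,
    semi_b: float,
    extrude: np.ndarray,
    n: int = 96,
    back_floor_x: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Watertight (possibly oblique) prism: elliptical front face at
    ``center`` with outward normal along ``axis_a × axis_b``, back face
    translated by ``extrude``.  Fan-triangulated.

    Extruding along the projection-line direction (rather than the face
    normal) keeps the prism's shadow identical to the front face, so grid
    lines can never select a side-wall point.
    """
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    rim = center + np.outer(semi_a * np.cos(th), axis_a) + np.outer(semi_b * np.sin(th), axis_b)
    rim_back = rim + extrude
    back_center = center + extrude
    if back_floor_x is not None:
        # keep the back face lateral of the head interior (clamped depth)
        rim_back[:, 0] = np.maximum(rim_back[:, 0], back_floor_x)
        back_center[0] = max(back_center[0], back_floor_x)
    verts = np.vstack([rim, rim_back, center, back_center])
    ic, ic2 = 2 * n, 2 * n + 1
    faces = []
    for k in range(n):
        k2 = (k + 1) % n
        faces.append([ic, k, k2])  # front fan (outward = +normal)
        faces.append([ic2, n + k2, n + k])  # back fan
        faces.append([k, n + k, n + k2])  # side
        faces.append([k, n + k2, k2])
    return verts, np.array(faces, dtype=int)


def _flattened_superellipsoid(
    axes: tuple,
    x_wall: float,
    exponent: float = 3.0,
    n_rings: int = 64,
    n_phi: int = 128,
    asymmetry: float = 0.0,
    egg: float = 0.0,
    exponent_caudal: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Superellipsoid head with flat lateral faces at ``x = ±x_wall``.

    Cross-sections perpendicular to the cranio-caudal ŷ axis are ellipses
    with semi-axes ``(a·s, c·s)`` where the profile
    ``s(y) = (1 − |y/b|^p)^(1/p)`` follows a superellipse (``p = 2`` is an
    ellipsoid; larger ``p`` gives the barrel-like cranium that makes the
    cylinder-axis fit well conditioned).  Vertices with ``|x| > x_wall``
    are clamped onto the wall planes, producing exactly planar lateral
    (mastoid) faces.  Mirror-symmetric about x = 0 by construction.
    """
    a, b, c = axes
    if not 0 < x_wall < a:
        raise ConstructionError("wall offset must lie inside the x semi-axis")
    psi = np.linspace(0.0, np.pi, n_rings + 2)[1:-1]
    u = np.cos(psi)  # y/b, poles handled by fan vertices
    # different cranial/caudal exponents give the crown-vs-chin asymmetry
    # real heads have (and a symmetry-plane search relies on)
    p_lo = exponent_caudal if exponent_caudal is not None else exponent
    p = np.where(u >= 0, exponent, p_lo)
    s = (1.0 - np.abs(u) ** p) ** (1.0 / p)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    U, P = np.meshgrid(u, phi, indexing="ij")
    S = np.repeat(s[:, None], n_phi, axis=1)
    sin_p = np.sin(P)
    verts = np.column_stack(
        [
            (a * S * np.cos(P)).ravel(),
            (b * U).ravel(),
            # egg > 0 elongates the front (+z, "face") and shortens the
            # back, breaking the antero-posterior mirror symmetry that a
            # symmetry-plane search would otherwise confuse with sagittal
            (c * S * sin_p * (1.0 + egg * sin_p)).ravel(),
        ]
    )
    np.clip(verts[:, 0], -x_wall, x_wall, out=verts[:, 0])
    pole_top = len(verts)
    verts = np.vstack([verts, [0.0, b, 0.0], [0.0, -b, 0.0]])
    pole_bot = pole_top + 1
    if asymmetry:
        shrink = 1.0 - asymmetry * np.clip(-verts[:, 0] / a, 0.0, 1.0)
        verts[:, 2] *= shrink

    def vid(t, p):
        return t * n_phi + (p % n_phi)

    faces = []
    for t in range(n_rings - 1):
        for p in range(n_phi):
            faces.append([vid(t, p), vid(t + 1, p), vid(t + 1, p + 1)])
            faces.append([vid(t, p), vid(t + 1, p + 1), vid(t, p + 1)])
    for p in range(n_phi):  # cranial pole fan (ring 0 is the top ring)
        faces.append([pole_top, vid(0, p + 1), vid(0, p)])
    for p in range(n_phi):  # caudal pole fan
        faces.append([pole_bot, vid(n_rings - 1, p), vid(n_rings - 1, p + 1)])
    return verts, np.array(faces, dtype=int)


def _flat_patch_half_extents(
    axes: tuple, x_wall: float, exponent: float, y_abs: float, egg: float = 0.0
) -> float:
    """Half-extent in z of the flat lateral face at height ``|y| = y_abs``
    (conservative: the shorter, posterior side when ``egg`` > 0)."""
    a, b, c = axes
    uy = min(y_abs / b, 1.0)
    s = (1.0 - uy**exponent) ** (1.0 / exponent)
    val = s**2 - (x_wall / a) ** 2
    return c * (1.0 - egg) * np.sqrt(val) if val > 0 else 0.0


def _as_mesh(verts: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _mirror_x(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    v = mesh.vertices.copy()
    v[:, 0] *= -1.0
    f = mesh.faces[:, ::-1].copy()
    return trimesh.Trimesh(vertices=v, faces=f, process=False)


def make_wall_flap_phantom(
    wall_tilt_deg: float = 0.0,
    flap_offset_mm: float = 10.0,
    flap_radius_mm: float = 30.0,
    flap_tilt_deg: float = 0.0,
    flap_thickness_mm: float = 2.0,
    wall_size_mm: tuple = (100.0, 100.0),
    wall_thickness_mm: float = 12.0,
) -> tuple[trimesh.Trimesh, WallFlapTruth]:
    """Wall slab + disc flap micro-phantom.

    The wall's lateral face passes through the origin with normal
    ``R_y(wall_tilt)·x̂``.  The flap disc (radius ``flap_radius_mm``) sits
    ``flap_offset_mm`` along the wall normal and is tilted a further
    ``flap_tilt_deg`` about the ŷ hinge through its center, so

    * protrusion  = offset + radius·sin(flap_tilt),
    * AC vs mastoid = flap_tilt,  AC vs sagittal = wall_tilt + flap_tilt.
    """
    if flap_offset_mm < 0 or flap_radius_mm <= 0:
        raise ConstructionError("offset and radius must be non-negative/positive")
    if not 0 <= flap_tilt_deg < 90:
        raise ConstructionError("flap tilt must be in [0, 90)")
    tau = np.radians(wall_tilt_deg + flap_tilt_deg)
    w = np.radians(wall_tilt_deg)
    n_wall = np.array([np.cos(w), 0.0, -np.sin(w)])
    n_flap = np.array([np.cos(tau), 0.0, -np.sin(tau)])
    # a hinged flap may dip below the wall face; deepen the slab so the
    # submerged part never pokes out of its back
    sunk = flap_radius_mm * np.sin(np.radians(flap_tilt_deg)) - flap_offset_mm
    wall_thickness_mm = max(wall_thickness_mm, sunk + 3.0)

    wall = trimesh.creation.box(
        extents=[wall_thickness_mm, wall_size_mm[0], wall_size_mm[1]],
        transform=trimesh.transformations.translation_matrix(
            [-wall_thickness_mm / 2.0, 0, 0]
        ),
    )
    R = trimesh.transformations.rotation_matrix(w, [0, 1, 0])
    wall.apply_transform(R)

    h = np.array([0.0, 1.0, 0.0])
    w_dir = np.cross(n_flap, h)  # in-plane, perpendicular to the hinge
    center = flap_offset_mm * n_wall
    # extrude medially along −x̂ so the lateral shadow is the disc itself
    extrude = -(flap_thickness_mm / max(n_flap[0], 0.1)) * _X
    fv, ff = _ellipse_prism(
        center, h, flap_radius_mm, w_dir, flap_radius_mm, extrude
    )
    flap = _as_mesh(fv, ff)
    mesh = trimesh.util.concatenate([_as_mesh(wall.vertices, wall.faces), flap])
    truth = WallFlapTruth(
        mastoid_plane=Plane(n_wall, 0.0),
        auricle_plane=Plane(n_flap, float(np.dot(n_flap, center))),
        protrusion_mm=flap_offset_mm
        + flap_radius_mm * np.sin(np.radians(flap_tilt_deg)),
        ac_angle_sagittal_deg=wall_tilt_deg + flap_tilt_deg,
        ac_angle_mastoid_deg=flap_tilt_deg,
    )
    return mesh, truth


def _build_flap(
    spec: EarSpec, x_wall: float, thickness: float, n: int, stem_depth: float
) -> tuple[trimesh.Trimesh, trimesh.Trimesh, dict]:
    """Left-side ear flap + welding stem; mirror for the right side."""
    i = np.radians(spec.inclination_deg)
    ac = np.radians(spec.ac_angle_deg)
    L, W, P = spec.length_mm, spec.width_mm, spec.protrusion_mm
    g0 = P - W * np.sin(ac)
    if g0 < 0.2:
        raise ConstructionError(
            "protrusion too small for the requested width/AC angle "
            f"(clearance {g0:.2f} mm < 0.2 mm)"
        )
    h = np.array([0.0, np.cos(i), np.sin(i)])  # hinge = long axis, in wall plane
    u0 = np.array([0.0, -np.sin(i), np.cos(i)])  # in-wall, perpendicular to hinge
    w_dir = np.cos(ac) * u0 + np.sin(ac) * _X  # short axis, lifted off the wall
    n_lat = np.cos(ac) * _X - np.sin(ac) * u0  # lateral face normal
    oy, oz = spec.center_offset
    center = np.array([x_wall + g0 + (W / 2.0) * np.sin(ac), oy, oz])
    extrude = -(thickness / np.cos(ac)) * _X  # medial, along the grid lines
    fv, ff = _ellipse_prism(
        center, h, L / 2.0, w_dir, W / 2.0, extrude, n, back_floor_x=x_wall + 0.05
    )
    flap = _as_mesh(fv, ff)

    # stem: top quad strictly inside the flap at mid-depth, base inside the head
    top = []
    for sp, sq in ((-0.3, -0.25), (0.3, -0.25), (0.3, 0.25), (-0.3, 0.25)):
        p = center + sp * L * h + sq * W * w_dir + 0.5 * extrude
        p[0] = max(p[0], x_wall + 0.08)
        top.append(p)
    top = np.array(top)
    bottom = top.copy()
    bottom[:, 0] = x_wall - stem_depth
    stem = trimesh.convex.convex_hull(np.vstack([top, bottom]))

    apex = center + (W / 2.0) * w_dir
    truth = {
        "plane": Plane(n_lat, float(np.dot(n_lat, center))),
        "center": center,
        "apex": apex,
        "axis_y": float(
            np.sqrt((L / 2.0 * h[1]) ** 2 + (W / 2.0 * w_dir[1]) ** 2)
        ),
        "axis_z": float(
            np.sqrt((L / 2.0 * h[2]) ** 2 + (W / 2.0 * w_dir[2]) ** 2)
        ),
    }
    return flap, stem, truth


def make_head_with_ears(
    left: EarSpec | None = None,
    right: EarSpec | None = None,
    head_axes: tuple = (78.0, 95.0, 72.0),
    asymmetry: float = 0.0,
    wall_frac: float = 0.9,
    superellipse_exponent: float = 3.5,
    superellipse_exponent_caudal: float | None = None,
    egg: float = 0.05,
    flap_thickness_mm: float = 3.0,
    n_rings: int = 160,
    n_phi: int = 320,
    flap_segments: int = 96,
    box_margin_mm: float = 6.0,
    surface_jitter_mm: float = 0.3,
    jitter_seed: int = 12345,
) -> tuple[trimesh.Trimesh, HeadTruth]:
    """Parametric head phantom with ear flaps of exactly known parameters.

    The head is an ellipsoid (semi-axes ``head_axes`` mm: lateral,
    cranio-caudal, antero-posterior) truncated by flat lateral faces at
    ``x = ±wall_frac·head_axes[0]``; those faces are the exact mastoid
    planes.  Passing ``left``/``right`` as ``None`` omits that ear (for
    missing-auricle robustness tests); ``asymmetry`` smoothly shrinks the
    right half's z radius to break perfect mirror symmetry.

    Returns the mesh and a truth record: per-ear planes and Table-style
    parameters, the sagittal plane, the construction frame (identity axes,
    origin at the centroid projected into the sagittal plane), bilateral
    position differences and per-ear suggested selection boxes.
    """
    if left is None and right is None:
        raise ConstructionError("at least one ear is required")
    a = head_axes[0]
    x_wall = wall_frac * a
    hv, hf = _flattened_superellipsoid(
        head_axes,
        x_wall,
        superellipse_exponent,
        n_rings,
        n_phi,
        asymmetry,
        egg,
        exponent_caudal=superellipse_exponent_caudal,
    )
    if surface_jitter_mm > 0:
        # emulate surface-reconstruction roughness: seeded (y, z) jitter of
        # the head vertices.  Tangential on the flat lateral faces, so the
        # mastoid-plane truth is untouched.  The jitter is applied
        # mirror-symmetrically (mirror-partner vertices get the same y/z
        # perturbation), which breaks the regular-ring structure of the
        # tessellation — whose sampling resonances would distort the
        # symmetry-plane cost — while keeping the head exactly bilaterally
        # symmetric, as the phantom's ground truth requires.
        rng = np.random.default_rng(jitter_seed)
        hv = hv.copy()
        jit = rng.normal(0.0, surface_jitter_mm, size=(len(hv), 2))
        n_grid = len(hv) - 2  # ring vertices; the two poles follow
        t_idx, p_idx = np.divmod(np.arange(n_grid), n_phi)
        partner = t_idx * n_phi + (n_phi // 2 - p_idx) % n_phi
        share = np.minimum(np.arange(n_grid), partner)
        jit[:n_grid] = jit[share]
        hv[:, 1:] += jit
    parts = [_as_mesh(hv, hf)]

    ear_truth: dict[str, EarTruth | None] = {"left": None, "right": None}
    for side, spec in (("left", left), ("right", right)):
        if spec is None:
            continue
        flap, stem, t = _build_flap(
            spec, x_wall, flap_thickness_mm, flap_segments, stem_depth=2.0
        )
        # footprint must stay on the flat lateral face
        oy, oz = spec.center_offset
        z_room = _flat_patch_half_extents(
            head_axes,
            x_wall,
            min(
                superellipse_exponent,
                superellipse_exponent_caudal or superellipse_exponent,
            ),
            abs(oy) + t["axis_y"],
            egg,
        )
        if abs(oz) + t["axis_z"] > z_room:
            raise ConstructionError(f"{side} ear footprint exceeds the flat lateral face")
        if side == "right":
            flap, stem = _mirror_x(flap), _mirror_x(stem)
        parts.extend([flap, stem])
        s = 1.0 if side == "left" else -1.0
        plane = t["plane"] if side == "left" else _mirror_plane(t["plane"])
        center = t["center"] * np.array([s, 1, 1])
        apex = t["apex"] * np.array([s, 1, 1])
        box = SelectionBox(
            center=np.array(
                [s * (x_wall + spec.protrusion_mm / 2.0), center[1], center[2]]
            ),
            extents=np.array(
                [
                    spec.protrusion_mm + 8.0,
                    2 * (t["axis_y"] + box_margin_mm),
                    2 * (t["axis_z"] + box_margin_mm),
                ]
            ),
            side=side,
        )
        ear_truth[side] = EarTruth(
            side=side,
            plane=plane,
            mastoid_plane=Plane(s * _X, x_wall),
            length_mm=spec.length_mm,
            width_mm=spec.width_mm,
            inclination_deg=spec.inclination_deg,
            protrusion_mm=spec.protrusion_mm,
            ac_angle_sagittal_deg=spec.ac_angle_deg,
            ac_angle_mastoid_deg=spec.ac_angle_deg,
            center=center,
            apex=apex,
            box=box,
        )

    mesh = trimesh.util.concatenate(parts)
    centroid = np.asarray(mesh.vertices, dtype=float).mean(axis=0)
    origin = centroid.copy()
    origin[0] = 0.0
    frame = AnatomicalFrame(origin, _X, [0.0, 1.0, 0.0], [0.0, 0.0, 1.0])
    # express truth centers/boxes in frame coordinates
    for et in ear_truth.values():
        if et is None:
            continue
        et.center = et.center - origin
        et.apex = et.apex - origin
        et.box = SelectionBox(et.box.center - origin, et.box.extents, et.box.side)
    position = None
    if ear_truth["left"] is not None and ear_truth["right"] is not None:
        delta = ear_truth["left"].center - ear_truth["right"].center
        position = PositionDifference(delta_pa_mm=float(delta[2]), delta_si_mm=float(delta[1]))
    truth = HeadTruth(
        frame=frame,
        sagittal=Plane(_X, 0.0),
        left=ear_truth["left"],
        right=ear_truth["right"],
        position=position,
        head_axes=tuple(head_axes),
        wall_x_mm=x_wall,
    )
    return mesh, truth


def _mirror_plane(p: Plane) -> Plane:
    n = p.normal.copy()
    n[0] *= -1.0
    return Plane(n, p.offset)


def voxelize_to_ct(
    mesh: trimesh.Trimesh,
    spec: ScanSpec | None = None,
    tissue_hu: tuple = (40.0, 1200.0, -1000.0),
    bone_core: bool = True,
) -> CTVolume:
    """Voxelize a watertight phantom to a noisy CT volume.

    Inside voxels get the soft-tissue HU (with a spherical bone core at
    the largest component's center), outside voxels air.  The inside test
    is crossing parity along x-parallel lines through the voxel centers,
    per watertight component (components may overlap; their union is
    taken).  Additive Gaussian noise ``N(0, noise_sd/√dose)`` is seeded
    from ``spec.seed``.
    """
    spec = spec or ScanSpec()
    soft_hu, bone_hu, air_hu = tissue_hu
    components = mesh.split(only_watertight=False)
    if len(components) == 0:
        components = [mesh]
    for comp in components:
        if not comp.is_watertight:
            raise ConstructionError("phantom mesh has a non-watertight component")
    lo = mesh.vertices.min(axis=0) - spec.pad_mm
    hi = mesh.vertices.max(axis=0) + spec.pad_mm
    sp = np.asarray(spec.voxel_mm)
    shape = np.ceil((hi - lo) / sp).astype(int)
    centers0 = lo + 0.5 * sp  # world position of voxel (0,0,0)
    ys = centers0[1] + np.arange(shape[1]) * sp[1]
    zs = centers0[2] + np.arange(shape[2]) * sp[2]
    inside = np.zeros(shape, dtype=bool)
    for comp in components:
        hits = parallel_grid_intersections(
            np.asarray(comp.vertices), np.asarray(comp.faces), 0, ys, zs
        )
        for (iy, iz), xs in hits.items():
            m = xs.size - xs.size % 2
            for k in range(0, m, 2):
                i0 = int(np.ceil((xs[k] - centers0[0]) / sp[0]))
                i1 = int(np.floor((xs[k + 1] - centers0[0]) / sp[0]))
                if i1 >= i0:
                    inside[max(i0, 0) : min(i1, shape[0] - 1) + 1, iy, iz] = True
    data = np.full(shape, air_hu, dtype=np.float32)
    data[inside] = soft_hu
    if bone_core:
        main = max(components, key=lambda c: abs(c.volume))
        c = (main.bounds[0] + main.bounds[1]) / 2.0
        r = 0.4 * float(np.min(main.bounds[1] - main.bounds[0]))
        ii, jj, kk = np.meshgrid(
            centers0[0] + np.arange(shape[0]) * sp[0],
            ys,
            zs,
            indexing="ij",
            sparse=True,
        )
        core = ((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2) <= r**2
        data[inside & core] = bone_hu
    sd = spec.noise_sd_hu / np.sqrt(spec.dose_factor)
    if sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, sd, size=data.shape).astype(np.float32)
    return CTVolume(data, tuple(spec.voxel_mm), origin=centers0)


def _random_rigid(rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float):
    axis = rng.normal(size=3)
    axis /= max(np.linalg.norm(axis), 1e-12)
    angle = np.radians(rng.uniform(0.0, max_rot_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    direction = rng.normal(size=3)
    direction /= max(np.linalg.norm(direction), 1e-12)
    t = direction * rng.uniform(0.0, max_trans_mm)
    return R, t


def simulate_repeat_scans(
    mesh: trimesh.Trimesh,
    spec: ScanSpec | None = None,
    n_repeats: int = 5,
    return_meshes: bool = False,
):
    """Repeat-scan simulation: per repeat an independent seeded rigid
    repositioning (rotation ≤ 10°, translation ≤ 20 mm by default) and
    fresh noise.  Returns CT volumes, or the repositioned meshes with
    ``return_meshes=True`` (for mesh-level invariance tests)."""
    spec = spec or ScanSpec()
    if n_repeats < 1:
        raise ArgumentError("n_repeats must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(n_repeats)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        R, t = _random_rigid(rng, spec.max_rotation_deg, spec.max_translation_mm)
        moved = trimesh.Trimesh(
            vertices=np.asarray(mesh.vertices) @ R.T + t,
            faces=mesh.faces.copy(),
            process=False,
        )
        if return_meshes:
            out.append(moved)
            continue
        noise_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(voxelize_to_ct(moved, replace(spec, seed=noise_seed)))
    return out
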