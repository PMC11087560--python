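"""Selection of the lateral auricle surface and its derived planes.

A box aligned with the anatomical frame encloses the auricle.  A dense
grid of parallel lines (0.3 mm spacing, running medial→lateral along x̂)
is cast through the box; a line that crosses the head surface at least
twice inside the box passes through the auricle (elsewhere only the scalp
is crossed once), and its most-lateral crossing lies on the outer auricle
surface.  The kept points are triangulated grid-cell-wise, a least-squares
plane through them is the *auricle plane*, and the convex hull of their
in-plane projection — pushed into the mid-sagittal plane and ray-cast back
laterally onto the head behind the auricle — yields the *mastoid outline*
and the *mastoid plane*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import (
    ArgumentError,
    InsufficientSurfaceError,
    MastoidProjectionError,
)
from .frame import AnatomicalFrame
from .geometry import (
    InPlanePointSet,
    Plane,
    convex_hull_2d,
    fit_plane_lsq,
    intersect_line_with_mesh,
    parallel_grid_intersections,
)

__all__ = [
    "SelectionBox",
    "ExtractionConfig",
    "AuricleSurface",
    "MastoidOutline",
    "select_auricle_surface",
    "project_surface_to_plane",
    "compute_mastoid_outline",
    "auto_selection_box",
]


@dataclass
class SelectionBox:
    """Auricle selection box, axis-aligned in anatomical frame coordinates.

    Lateral/medial faces are normal to x̂ and cranial/caudal faces to ŷ.
    ``center`` and ``extents`` are mm in frame coordinates.
    """

    center: np.ndarray
    extents: np.ndarray
    side: str

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.extents = np.asarray(self.extents, dtype=float)
        if self.side not in ("left", "right"):
            raise ArgumentError("side must be 'left' or 'right'")
        if not np.all(self.extents > 0):
            raise ArgumentError("box extents must be positive")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.extents / 2.0

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.extents / 2.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "side": self.side,
                    "center": self.center.tolist(),
                    "extents": self.extents.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SelectionBox":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["center"]), np.array(d["extents"]), d["side"])


@dataclass
class ExtractionConfig:
    grid_spacing_mm: float = 0.3
    min_intersections: int = 2
    min_lines: int = 10  # fewer qualifying lines → insufficient surface
    mastoid_epsilon_mm: float = 0.5
    mastoid_max_failures: float = 0.2
    hull_kind: str = "convex"  # or 'concave' (alpha-shape-style outline)
    concave_ratio: float = 0.3  # shapely concave_hull ratio when concave

    def __post_init__(self):
        if self.grid_spacing_mm <= 0:
            raise ArgumentError("grid spacing must be positive")
        if self.min_intersections < 2:
            raise ArgumentError("min_intersections must be >= 2")


@dataclass
class AuricleSurface:
    """Selected lateral auricle surface.

    ``points`` are world coordinates of the kept most-lateral grid hits,
    ``grid_index`` their (iy, iz) grid cell, ``mesh`` the grid-cell
    triangulation, ``plane`` the least-squares auricle plane (normal
    oriented laterally) and ``plane_rms_mm`` its fit residual.
    """

    points: np.ndarray
    grid_index: np.ndarray
    mesh: trimesh.Trimesh
    side: str
    plane: Plane
    plane_rms_mm: float
    box: SelectionBox
    lateral_dir: np.ndarray


@dataclass
class MastoidOutline:
    points: np.ndarray
    plane: Plane
    plane_rms_mm: float
    n_failed_rays: int = 0
    hull_indices: np.ndarray = field(default=None)


def _frame_mesh(head: trimesh.Trimesh, frame: AnatomicalFrame):
    v = frame.to_frame(np.asarray(head.vertices, dtype=float))
    return v, np.asarray(head.faces, dtype=int)


def select_auricle_surface(
    head: trimesh.Trimesh,
    frame: AnatomicalFrame,
    box: SelectionBox,
    cfg: ExtractionConfig | None = None,
) -> AuricleSurface:
    """Select the most-lateral auricle points on a grid of projection lines.

    Grid lines run along ±x̂ between the medial and lateral box faces with
    ``cfg.grid_spacing_mm`` spacing over the (y, z) box face.  A line
    qualifies if it crosses the head surface at least
    ``cfg.min_intersections`` times *inside the box*; the most-lateral
    crossing (largest x̂ for the left side, smallest for the right) is
    kept.  Kept grid points are triangulated per 2×2 grid cell (two
    triangles for complete cells, one for 3-corner cells) and a
    least-squares plane is fitted through them.
    """
    cfg = cfg or ExtractionConfig()
    v, f = _frame_mesh(head, frame)
    lo, hi = box.lo, box.hi
    ny = int(np.floor((hi[1] - lo[1]) / cfg.grid_spacing_mm)) + 1
    nz = int(np.floor((hi[2] - lo[2]) / cfg.grid_spacing_mm)) + 1
    grid_y = lo[1] + np.arange(ny) * cfg.grid_spacing_mm
    grid_z = lo[2] + np.arange(nz) * cfg.grid_spacing_mm

    # restrict to faces whose bbox overlaps the box (in frame coords)
    tri_lo = v[f].min(axis=1)
    tri_hi = v[f].max(axis=1)
    keep = np.all(tri_hi >= lo, axis=1) & np.all(tri_lo <= hi, axis=1)
    if not keep.any():
        raise InsufficientSurfaceError("selection box does not intersect the mesh")
    hits = parallel_grid_intersections(v, f[keep], 0, grid_y, grid_z)

    pick_max = box.side == "left"
    sel_pts = []
    sel_idx = []
    for (iy, iz), xs in hits.items():
        xs = xs[(xs >= lo[0]) & (xs <= hi[0])]
        if xs.size < cfg.min_intersections:
            continue
        x = xs[-1] if pick_max else xs[0]
        sel_pts.append((x, grid_y[iy], grid_z[iz]))
        sel_idx.append((iy, iz))
    if len(sel_pts) < cfg.min_lines:
        raise InsufficientSurfaceError(
            f"only {len(sel_pts)} qualifying grid lines (need {cfg.min_lines})"
        )
    pts_frame = np.array(sel_pts)
    grid_index = np.array(sel_idx, dtype=int)
    faces = _triangulate_grid(grid_index, ny, nz)
    pts_world = frame.to_world(pts_frame)
    surface_mesh = trimesh.Trimesh(vertices=pts_world, faces=faces, process=False)

    lateral_frame = np.array([1.0, 0.0, 0.0]) if box.side == "left" else np.array([-1.0, 0.0, 0.0])
    lateral_world = frame.rotation().T @ lateral_frame
    plane = fit_plane_lsq(pts_world, orientation_hint=lateral_world)
    rms = float(np.sqrt(np.mean(plane.signed_distance(pts_world) ** 2)))
    return AuricleSurface(
        points=pts_world,
        grid_index=grid_index,
        mesh=surface_mesh,
        side=box.side,
        plane=plane,
        plane_rms_mm=rms,
        box=box,
        lateral_dir=lateral_world,
    )


def _triangulate_grid(grid_index: np.ndarray, ny: int, nz: int) -> np.ndarray:
    """Triangulate kept grid nodes cell-wise.

    Complete 2×2 cells yield two triangles; cells with exactly three valid
    corners yield one; fewer yield none.
    """
    lut = -np.ones((ny, nz), dtype=int)
    lut[grid_index[:, 0], grid_index[:, 1]] = np.arange(len(grid_index))
    faces = []
    present = np.zeros((ny, nz), dtype=bool)
    present[grid_index[:, 0], grid_index[:, 1]] = True
    a = present[:-1, :-1]
    b = present[1:, :-1]
    c = present[:-1, 1:]
    d = present[1:, 1:]
    count = a.astype(int) + b + c + d
    cy, cz = np.nonzero(count >= 3)
    for iy, iz in zip(cy, cz):
        ia, ib = lut[iy, iz], lut[iy + 1, iz]
        ic, id_ = lut[iy, iz + 1], lut[iy + 1, iz + 1]
        corners = [ia, ib, id_, ic]  # cycle around the cell
        missing = [k for k, w in enumerate(corners) if w < 0]
        if not missing:
            faces.append([ia, ib, id_])
            faces.append([ia, id_, ic])
        elif len(missing) == 1:
            tri = [w for w in corners if w >= 0]
            faces.append(tri)
    return np.array(faces, dtype=int) if faces else np.zeros((0, 3), dtype=int)


def project_surface_to_plane(
    surface: AuricleSurface, frame: AnatomicalFrame | None = None
) -> InPlanePointSet:
    """Project the selected auricle points into the auricle plane.

    The in-plane basis is right-handed with the first basis vector along
    the projection of ŷ (so the in-plane v axis relates to cranio-caudal
    when a frame is given; without a frame a stable default basis is used).
    """
    hint = frame.y_hat if frame is not None else None
    return InPlanePointSet.from_projection(surface.points, surface.plane, basis_u=hint)


def compute_mastoid_outline(
    head: trimesh.Trimesh,
    surface: AuricleSurface,
    frame: AnatomicalFrame,
    sagittal: Plane,
    cfg: ExtractionConfig | None = None,
) -> MastoidOutline:
    """Mastoid outline and plane behind the auricle.

    The convex hull of the projected auricle is pushed orthogonally into
    the mid-sagittal plane; from each such point a ray is cast laterally
    (±x̂ by side).  A qualifying hit must (a) lie farther than
    ``cfg.mastoid_epsilon_mm`` from every selected auricle point and
    (b) be an *exit* crossing — its outward face normal points along the
    ray — since the mastoid skin faces laterally while entry crossings
    (e.g. the back of the auricle) face the other way.  The first
    qualifying hit per ray is a mastoid point; a least-squares plane
    through the mastoid points, normal oriented laterally, is the mastoid
    plane.
    """
    cfg = cfg or ExtractionConfig()
    in_plane = project_surface_to_plane(surface, frame)
    hull_idx = _outline_indices(in_plane.points2d, cfg)
    hull_3d = in_plane.to_3d()[hull_idx]
    sag_pts = sagittal.project(hull_3d)
    direction = surface.lateral_dir / np.linalg.norm(surface.lateral_dir)
    tree = cKDTree(surface.points)
    normals = np.asarray(head.face_normals)
    mastoid_pts = []
    failed = 0
    for p in sag_pts:
        hits = intersect_line_with_mesh(p, direction, head, (0.0, np.inf), return_faces=True)
        found = None
        for _, loc, fi in hits:
            if float(np.dot(normals[fi], direction)) <= 0:
                continue  # entry crossing, not lateral-facing skin
            d, _ = tree.query(loc, k=1)
            if d > cfg.mastoid_epsilon_mm:
                found = loc
                break
        if found is None:
            failed += 1
        else:
            mastoid_pts.append(found)
    if failed > cfg.mastoid_max_failures * len(sag_pts):
        raise MastoidProjectionError(
            f"{failed}/{len(sag_pts)} mastoid rays failed to find a qualifying hit"
        )
    mastoid_pts = np.array(mastoid_pts)
    plane = fit_plane_lsq(mastoid_pts, orientation_hint=direction)
    rms = float(np.sqrt(np.mean(plane.signed_distance(mastoid_pts) ** 2)))
    return MastoidOutline(
        points=mastoid_pts,
        plane=plane,
        plane_rms_mm=rms,
        n_failed_rays=failed,
        hull_indices=hull_idx,
    )


def _outline_indices(points2d: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Outline vertex indices of the projected auricle.

    Convex hull by default; ``hull_kind='concave'`` uses a concave
    (alpha-shape-style) outline, useful when the projected auricle has
    pronounced notches.
    """
    if cfg.hull_kind == "convex":
        return convex_hull_2d(points2d)
    import shapely

    hull = shapely.concave_hull(
        shapely.MultiPoint(points2d), ratio=cfg.concave_ratio
    )
    boundary = np.asarray(hull.exterior.coords)[:-1]
    tree = cKDTree(points2d)
    _, idx = tree.query(boundary)
    # preserve boundary order, drop duplicate snaps
    _, first = np.unique(idx, return_index=True)
    return idx[np.sort(first)]


def auto_selection_box(
    head: trimesh.Trimesh,
    frame: AnatomicalFrame,
    side: str,
    extents=(50.0, 70.0, 50.0),
    apex_band_mm: float = 2.0,
) -> SelectionBox:
    """Center a default-size box on the lateral-most surface patch of a side.

    The (y, z) center is the centroid of all vertices within
    ``apex_band_mm`` of the extreme lateral coordinate, which is far more
    stable on noisy reconstructed surfaces than the single extreme vertex.
    """
    v = frame.to_frame(np.asarray(head.vertices, dtype=float))
    x = v[:, 0] if side == "left" else -v[:, 0]
    x_max = float(x.max())
    patch = v[x >= x_max - apex_band_mm]
    center = np.array(
        [x_max if side == "left" else -x_max, patch[:, 1].mean(), patch[:, 2].mean()]
    )
    return SelectionBox(center, np.asarray(extents, dtype=float), side)
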