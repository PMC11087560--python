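"""Geometric primitives shared by every stage of the auricle pipeline.

All lengths are millimetres and all angles are degrees unless a name says
otherwise.  Point sets are ``(n, 3)`` (or ``(n, 2)`` in-plane) float arrays.

The module covers:

* least-squares plane fitting and plane parameterizations,
* the trimmed nearest-neighbour cost used by the symmetry-plane and
  cylinder optimizers,
* ray/segment-mesh intersection (vectorized Möller–Trumbore, plus a batch
  variant for dense grids of parallel lines),
* 2-D analysis of projected point sets: convex hull, diameter, extent
  perpendicular to an axis, inertia-tensor principal axes and bounding
  extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import ArgumentError, DegenerateGeometryError

__all__ = [
    "Plane",
    "PlaneParams3",
    "InPlanePointSet",
    "fit_plane_lsq",
    "trimmed_mean_nn_distance",
    "intersect_line_with_mesh",
    "parallel_grid_intersections",
    "convex_hull_2d",
    "diameter_2d",
    "perpendicular_extent_2d",
    "inertia_axes_2d",
    "bounding_extents_along_axes",
    "load_mesh",
    "save_mesh",
    "rigid_transform",
]

_MERGE_TOL = 1e-6  # mm along the line parameter; shared-edge hits merge


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ArgumentError("zero-length vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``n·p = offset`` with unit normal ``n``.

    ``offset`` is the signed distance from the world origin along the
    normal, so ``signed_distance(p) = n·p − offset``.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        object.__setattr__(self, "normal", _unit(self.normal))
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.normal - self.offset

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of ``points`` into the plane."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.signed_distance(points)
        return points - d[:, None] * self.normal

    def mirror(self, points: np.ndarray) -> np.ndarray:
        """Reflect ``points`` across the plane."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.signed_distance(points)
        return points - 2.0 * d[:, None] * self.normal

    def oriented(self, hint: np.ndarray) -> "Plane":
        """Flip the normal, if needed, to form an acute angle with ``hint``."""
        if float(np.dot(self.normal, hint)) < 0:
            return Plane(-self.normal, -self.offset)
        return self

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """An orthonormal in-plane basis (u, v) with (u, v, n) right-handed."""
        n = self.normal
        seed = np.array([0.0, 1.0, 0.0]) if abs(n[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
        u = _unit(np.cross(seed, n))
        v = np.cross(n, u)
        return u, v

    def to_params(self) -> "PlaneParams3":
        n = self.normal
        lat = np.degrees(np.arcsin(np.clip(n[2], -1.0, 1.0)))
        lon = np.degrees(np.arctan2(n[1], n[0]))
        if lon >= 180.0:
            lon -= 360.0
        return PlaneParams3(lon, lat, self.offset)


@dataclass(frozen=True)
class PlaneParams3:
    """Three-parameter plane chart used by the symmetry-plane optimizer.

    ``longitude``/``latitude`` (degrees) give the normal direction and
    ``distance`` (mm) is the offset from the origin along that normal.
    """

    longitude: float
    latitude: float
    distance: float

    def normal(self) -> np.ndarray:
        lon = np.radians(self.longitude)
        lat = np.radians(self.latitude)
        return np.array(
            [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
        )

    def to_plane(self) -> Plane:
        return Plane(self.normal(), self.distance)

    def as_array(self) -> np.ndarray:
        return np.array([self.longitude, self.latitude, self.distance], dtype=float)


@dataclass
class InPlanePointSet:
    """2-D coordinates of points expressed in an orthonormal in-plane basis.

    ``points2d[i] = ((p_i − origin)·basis_u, (p_i − origin)·basis_v)``.
    """

    points2d: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray
    origin: np.ndarray
    source_indices: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.points2d = np.atleast_2d(np.asarray(self.points2d, dtype=float))
        self.basis_u = _unit(self.basis_u)
        self.basis_v = _unit(self.basis_v)
        self.origin = np.asarray(self.origin, dtype=float)
        if abs(float(np.dot(self.basis_u, self.basis_v))) > 1e-9:
            raise ArgumentError("in-plane basis must be orthonormal")

    def to_3d(self, points2d: np.ndarray | None = None) -> np.ndarray:
        q = self.points2d if points2d is None else np.atleast_2d(points2d)
        return self.origin + q[:, :1] * self.basis_u + q[:, 1:2] * self.basis_v

    @classmethod
    def from_projection(
        cls,
        points: np.ndarray,
        plane: Plane,
        basis_u: np.ndarray | None = None,
    ) -> "InPlanePointSet":
        """Project 3-D points into ``plane`` and express them in-plane.

        If ``basis_u`` is given it is orthogonalized against the plane
        normal; otherwise an arbitrary stable basis is used.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if basis_u is None:
            u, v = plane.basis()
        else:
            u = np.asarray(basis_u, dtype=float)
            u = u - float(np.dot(u, plane.normal)) * plane.normal
            if np.linalg.norm(u) < 1e-12:
                raise DegenerateGeometryError("basis hint parallel to plane normal")
            u = _unit(u)
            v = np.cross(plane.normal, u)
        origin = plane.project(np.zeros(3))[0]
        rel = points - origin
        uv = np.column_stack([rel @ u, rel @ v])
        return cls(uv, u, v, origin)


def fit_plane_lsq(points: np.ndarray, orientation_hint=(1.0, 0.0, 0.0)) -> Plane:
    """Total-least-squares plane through ``points``.

    Minimizes the sum of squared orthogonal distances via SVD of the
    centered coordinates; the normal sign is chosen to form an acute angle
    with ``orientation_hint``.

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or
    (near-)collinear input.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear: only one significant singular value
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane is underdetermined")
    normal = vt[2]
    plane = Plane(normal, float(np.dot(normal, centroid)))
    return plane.oriented(np.asarray(orientation_hint, dtype=float))


def trimmed_mean_nn_distance(
    source: np.ndarray,
    target: np.ndarray,
    trim_sd_factor: float = 0.5,
    sd_mode: str = "population",
    target_tree: cKDTree | None = None,
) -> float:
    """Outlier-trimmed mean nearest-neighbour distance (mm).

    For every source point the distance to its nearest target point is
    computed; distances larger than ``mean + trim_sd_factor·SD`` are
    discarded and the mean of the remainder is returned.  This is the cost
    driving both the symmetry-plane and the cylinder optimizers; the
    trimming lets the cost tolerate moderate asymmetry such as a missing
    auricle.

    ``sd_mode`` selects the population (``n`` divisor, default) or sample
    (``n−1``) standard deviation.  A prebuilt ``target_tree`` may be passed
    to amortize KD-tree construction across optimizer iterations.
    """
    source = np.atleast_2d(np.asarray(source, dtype=float))
    if source.size == 0:
        raise ArgumentError("source point set is empty")
    if target_tree is None:
        target = np.atleast_2d(np.asarray(target, dtype=float))
        if target.size == 0:
            raise ArgumentError("target point set is empty")
        target_tree = cKDTree(target)
    d, _ = target_tree.query(source, k=1)
    return trimmed_mean(d, trim_sd_factor, sd_mode)


def trimmed_mean(distances: np.ndarray, trim_sd_factor: float = 0.5, sd_mode: str = "population") -> float:
    """Mean of ``distances`` after dropping values above mean + f·SD."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ArgumentError("empty distance set")
    mu = float(d.mean())
    ddof = 0 if sd_mode == "population" else 1
    sigma = float(d.std(ddof=ddof)) if d.size > ddof else 0.0
    kept = d[d <= mu + trim_sd_factor * sigma]
    if kept.size == 0:  # cannot happen with trim_sd_factor >= 0, kept defensively
        return mu
    return float(kept.mean())


def _moller_trumbore(
    origin: np.ndarray, direction: np.ndarray, v0, v1, v2, eps: float = 1e-12
) -> np.ndarray:
    """Line parameters t of intersections with triangles (v0, v1, v2).

    Vectorized over triangles; returns the t values of hits (unsorted).
    """
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,j->i", qvec, direction) * inv_det
    t = np.einsum("ij,ij->i", qvec, e2) * inv_det
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps)
    return t[hit], np.nonzero(hit)[0]


def intersect_line_with_mesh(
    origin: np.ndarray,
    direction: np.ndarray,
    mesh: trimesh.Trimesh,
    segment_bounds: tuple[float, float] = (-np.inf, np.inf),
    return_faces: bool = False,
):
    """All intersections of a parametric segment with a triangle mesh.

    The segment is ``origin + t·direction`` for ``tmin ≤ t ≤ tmax``;
    ``direction`` must be unit length so ``t`` is in mm.  Hits are returned
    sorted ascending by ``t`` as ``(t, point)`` pairs (or ``(t, point,
    face_index)`` with ``return_faces``); hits closer than 1e-6 mm along
    the line (shared edges/vertices) are merged so closed surfaces keep an
    even crossing parity.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ArgumentError("direction must be unit length")
    tmin, tmax = segment_bounds
    if not tmin < tmax:
        raise ArgumentError("segment_bounds must satisfy tmin < tmax")
    tri = mesh.triangles  # (m, 3, 3)
    t, faces = _moller_trumbore(origin, direction, tri[:, 0], tri[:, 1], tri[:, 2])
    in_range = (t >= tmin) & (t <= tmax)
    t, faces = t[in_range], faces[in_range]
    if t.size == 0:
        return []
    order = np.argsort(t)
    t, faces = t[order], faces[order]
    keep = np.concatenate([[True], np.diff(t) > _MERGE_TOL])
    t, faces = t[keep], faces[keep]
    if return_faces:
        return [
            (float(ti), origin + ti * direction, int(fi)) for ti, fi in zip(t, faces)
        ]
    return [(float(ti), origin + ti * direction) for ti in t]


def parallel_grid_intersections(
    vertices: np.ndarray,
    faces: np.ndarray,
    axis: int,
    grid_u: np.ndarray,
    grid_v: np.ndarray,
    merge_tol: float = _MERGE_TOL,
) -> dict[tuple[int, int], np.ndarray]:
    """Intersections of an axis-aligned grid of parallel lines with a mesh.

    The lines run along coordinate ``axis``; their positions form the
    Cartesian product ``grid_u × grid_v`` over the other two coordinates
    (in increasing coordinate order, e.g. for ``axis=0`` the line through
    ``(·, grid_u[i], grid_v[j])``).  Returns a dict mapping grid index
    ``(i, j)`` to the sorted array of intersection coordinates along the
    line axis, duplicates within ``merge_tol`` merged.

    This is a scanline rasterization: each triangle is projected onto the
    grid plane and tested against only the grid nodes inside its bounding
    box, which makes dense grids (0.3 mm spacing over an auricle box)
    tractable without a spatial index.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    other = [c for c in range(3) if c != axis]
    tu = vertices[:, other[0]][faces]  # (m, 3)
    tv = vertices[:, other[1]][faces]
    tw = vertices[:, axis][faces]

    du = float(grid_u[1] - grid_u[0]) if len(grid_u) > 1 else 1.0
    dv = float(grid_v[1] - grid_v[0]) if len(grid_v) > 1 else 1.0
    u0, v0 = float(grid_u[0]), float(grid_v[0])
    nu, nv = len(grid_u), len(grid_v)

    iu_lo = np.ceil((tu.min(axis=1) - u0) / du - 1e-12).astype(int).clip(0, nu)
    iu_hi = np.floor((tu.max(axis=1) - u0) / du + 1e-12).astype(int).clip(-1, nu - 1)
    iv_lo = np.ceil((tv.min(axis=1) - v0) / dv - 1e-12).astype(int).clip(0, nv)
    iv_hi = np.floor((tv.max(axis=1) - v0) / dv + 1e-12).astype(int).clip(-1, nv - 1)
    counts = (iu_hi - iu_lo + 1).clip(min=0) * (iv_hi - iv_lo + 1).clip(min=0)
    active = np.nonzero(counts > 0)[0]
    if active.size == 0:
        return {}

    hits_i: list[np.ndarray] = []
    hits_j: list[np.ndarray] = []
    hits_w: list[np.ndarray] = []
    # chunk over faces to bound memory
    chunk = 4096
    for s in range(0, active.size, chunk):
        fs = active[s : s + chunk]
        for f in fs:
            ius = np.arange(iu_lo[f], iu_hi[f] + 1)
            ivs = np.arange(iv_lo[f], iv_hi[f] + 1)
            uu = u0 + ius * du
            vv = v0 + ivs * dv
            U, V = np.meshgrid(uu, vv, indexing="ij")
            # barycentric in the (u, v) projection
            x1, x2, x3 = tu[f]
            y1, y2, y3 = tv[f]
            det = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
            if abs(det) < 1e-12:
                continue  # edge-on triangle: measure-zero contribution
            l1 = ((y2 - y3) * (U - x3) + (x3 - x2) * (V - y3)) / det
            l2 = ((y3 - y1) * (U - x3) + (x1 - x3) * (V - y3)) / det
            l3 = 1.0 - l1 - l2
            inside = (l1 >= -1e-9) & (l2 >= -1e-9) & (l3 >= -1e-9)
            if not inside.any():
                continue
            w = l1 * tw[f, 0] + l2 * tw[f, 1] + l3 * tw[f, 2]
            I, J = np.meshgrid(ius, ivs, indexing="ij")
            hits_i.append(I[inside])
            hits_j.append(J[inside])
            hits_w.append(w[inside])
    if not hits_i:
        return {}
    ii = np.concatenate(hits_i)
    jj = np.concatenate(hits_j)
    ww = np.concatenate(hits_w)
    order = np.lexsort((ww, jj, ii))
    ii, jj, ww = ii[order], jj[order], ww[order]
    out: dict[tuple[int, int], np.ndarray] = {}
    start = 0
    n = len(ii)
    while start < n:
        end = start
        while end < n and ii[end] == ii[start] and jj[end] == jj[start]:
            end += 1
        w = ww[start:end]
        keep = np.concatenate([[True], np.diff(w) > merge_tol])
        out[(int(ii[start]), int(jj[start]))] = w[keep]
        start = end
    return out


def convex_hull_2d(points: InPlanePointSet | np.ndarray) -> np.ndarray:
    """Counter-clockwise convex hull vertex indices of a 2-D point set."""
    pts = points.points2d if isinstance(points, InPlanePointSet) else np.atleast_2d(points)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("convex hull needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate 2-D point set: {exc}") from exc
    return hull.vertices  # scipy guarantees CCW order in 2-D


def diameter_2d(points: InPlanePointSet | np.ndarray) -> tuple[float, int, int]:
    """Largest pairwise distance of a 2-D point set.

    Returns ``(length, i, j)`` with ``(i, j)`` the lexicographically
    smallest index pair among ties (``i < j``).  The maximum is searched
    over convex-hull vertices, which always contain the diameter endpoints.
    """
    pts = points.points2d if isinstance(points, InPlanePointSet) else np.atleast_2d(points)
    m = pts.shape[0]
    if m < 2:
        raise ArgumentError("diameter needs at least 2 points")
    if m == 2:
        return float(np.linalg.norm(pts[1] - pts[0])), 0, 1
    try:
        cand = np.sort(np.asarray(convex_hull_2d(pts)))
    except DegenerateGeometryError:
        cand = np.arange(m)  # collinear: fall back to all points
    sub = pts[cand]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=-1)
    best = float(d2.max())
    # lexicographic tie-break on original indices (cand is sorted ascending)
    ii, jj = np.nonzero(np.isclose(d2, best, rtol=0, atol=1e-12))
    pairs = sorted(
        (int(cand[a]), int(cand[b])) for a, b in zip(ii, jj) if cand[a] < cand[b]
    )
    i, j = pairs[0]
    return float(np.sqrt(best)), i, j


def perpendicular_extent_2d(
    points: InPlanePointSet | np.ndarray, axis_direction: np.ndarray
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Extent of a 2-D point set perpendicular to ``axis_direction``.

    Projects all points onto the in-plane direction perpendicular to the
    (unit) axis and returns the span of those projections together with the
    width line: a segment of that perpendicular direction through the point
    farthest from the axis line, spanning the projected extent.
    """
    pts = points.points2d if isinstance(points, InPlanePointSet) else np.atleast_2d(points)
    if pts.shape[0] < 2:
        raise ArgumentError("extent needs at least 2 points")
    a = _unit(axis_direction)
    perp = np.array([-a[1], a[0]])
    s = pts @ perp
    width = float(s.max() - s.min())
    center = pts.mean(axis=0)
    # the point farthest from line L (L runs along `a` through the centroid)
    far = pts[np.argmax(np.abs(s - float(center @ perp)))]
    # width line: perpendicular of L through that farthest point
    lo = far + (s.min() - float(far @ perp)) * perp
    hi = far + (s.max() - float(far @ perp)) * perp
    return width, (lo, hi)


def inertia_axes_2d(
    points: InPlanePointSet | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Principal inertia axes of a centered 2-D point set.

    The planar inertia tensor ``[[Σv², −Σuv], [−Σuv, Σu²]]`` is
    eigen-decomposed; the eigenvector of the *smallest* eigenvalue is the
    elongation (length) axis — mass far from an axis raises the moment
    about the perpendicular one.  Returns ``(length_axis, width_axis,
    eigenvalues, isotropic)``; the sign convention is a non-negative v
    component (ties: non-negative u).  Near-equal eigenvalues (relative gap
    below 1e-9) fall back to the coordinate axes and set ``isotropic``.
    """
    pts = points.points2d if isinstance(points, InPlanePointSet) else np.atleast_2d(points)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("inertia axes need at least 3 points")
    c = pts - pts.mean(axis=0)
    suu = float(np.dot(c[:, 0], c[:, 0]))
    svv = float(np.dot(c[:, 1], c[:, 1]))
    suv = float(np.dot(c[:, 0], c[:, 1]))
    if max(suu, svv) <= 1e-24:
        raise DegenerateGeometryError("all points coincide")
    tensor = np.array([[svv, -suv], [-suv, suu]])
    evals, evecs = np.linalg.eigh(tensor)  # ascending eigenvalues
    if evals[0] <= 1e-12 * max(evals[1], 1.0) and np.isclose(evals[0], 0.0):
        raise DegenerateGeometryError("points are collinear")
    isotropic = bool(abs(evals[1] - evals[0]) <= 1e-9 * max(abs(evals[1]), 1.0))
    if isotropic:
        length_axis = np.array([1.0, 0.0])
        width_axis = np.array([0.0, 1.0])
    else:
        length_axis = evecs[:, 0]
        width_axis = evecs[:, 1]
    length_axis = _sign_convention(length_axis)
    width_axis = _sign_convention(width_axis)
    return length_axis, width_axis, evals, isotropic


def _sign_convention(axis: np.ndarray) -> np.ndarray:
    if axis[1] < 0 or (axis[1] == 0 and axis[0] < 0):
        return -axis
    return axis


def bounding_extents_along_axes(
    points: InPlanePointSet | np.ndarray, axes: tuple[np.ndarray, np.ndarray]
) -> tuple[float, float]:
    """Side lengths of the bounding rectangle aligned with ``axes``."""
    pts = points.points2d if isinstance(points, InPlanePointSet) else np.atleast_2d(points)
    a, b = np.asarray(axes[0], float), np.asarray(axes[1], float)
    if abs(float(np.dot(a, b))) > 1e-9 or abs(np.linalg.norm(a) - 1) > 1e-9:
        raise ArgumentError("axes must be orthonormal")
    sa = pts @ a
    sb = pts @ b
    return float(sa.max() - sa.min()), float(sb.max() - sb.min())


def rigid_transform(rotation: np.ndarray, translation: np.ndarray):
    """Return a callable applying ``p ↦ R p + t`` to ``(n, 3)`` arrays."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)

    def apply(points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ rotation.T + translation

    return apply


def load_mesh(path) -> trimesh.Trimesh:
    """Load an STL/PLY/OBJ surface mesh (vertex units mm)."""
    mesh = trimesh.load_mesh(str(path))
    if isinstance(mesh, trimesh.Scene):
        mesh = trimesh.util.concatenate(list(mesh.geometry.values()))
    if len(mesh.vertices) < 3:
        raise ArgumentError(f"mesh at {path} has fewer than 3 vertices")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write a mesh to STL/PLY/OBJ chosen by file extension."""
    mesh.export(str(path))
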