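"""Anatomical coordinate frame of the head.

The frame is derived from the head surface alone, with no landmarks:

* the **mid-sagittal plane** is the plane minimizing the trimmed mean
  nearest-neighbour distance between the head vertices and their mirror
  image in that plane (Nelder–Mead over longitude/latitude/distance);
* the **cranio-caudal axis** is the axis of a cylinder fitted to the head
  by the same trimmed-NN cost against a sparse sampling of the cylinder
  surface (Nelder–Mead over 6 parameters);
* x̂ is the sagittal normal pointing toward the left ear, ŷ the cylinder
  axis orthogonalized against x̂ and pointing cranially, ẑ = x̂ × ŷ, and
  the origin is the mesh vertex centroid projected into the sagittal plane.

Left/right chirality cannot be inferred from geometry alone, so a
``left_hint`` vector (from scan orientation metadata or the user) is
required to orient x̂.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import ArgumentError, ConvergenceError, DegenerateFrameError, DegenerateGeometryError
from .geometry import Plane, PlaneParams3, trimmed_mean, trimmed_mean_nn_distance

__all__ = [
    "FrameConfig",
    "CylinderParams",
    "AnatomicalFrame",
    "find_midsagittal_plane",
    "fit_head_cylinder",
    "build_anatomical_frame",
    "initial_sagittal_guess",
    "initial_cylinder_guess",
    "point_to_cylinder_distance",
]


@dataclass
class FrameConfig:
    """Optimizer settings for the frame construction.

    Defaults: 0.5·SD outlier trimming recomputed at every cost evaluation,
    a 250-point cylinder surface sampling, Nelder–Mead tolerances of
    1e-4 (mm and parameter units), at most 500 iterations and initial
    simplex steps of 2° / 2 mm.  Head meshes above ``max_cost_vertices``
    vertices are subsampled (uniform, seeded) for cost evaluation; the
    final reported cost always uses the full vertex set.
    """

    trim_sd_factor: float = 0.5
    cylinder_sample_points: int = 250
    fatol: float = 1e-4
    xatol: float = 1e-4
    max_iterations: int = 500
    initial_step_deg: float = 2.0
    initial_step_mm: float = 2.0
    max_cost_vertices: int = 20000
    subsample_seed: int = 0
    sd_mode: str = "population"
    # NN direction for the mirror cost is moot: because mirroring is an
    # isometry of the same point set, original→mirrored and
    # mirrored→original produce identical distance multisets
    nn_direction: str = "original_to_mirrored"
    restarts: int = 2  # fresh-simplex restarts to escape trimming plateaus
    polish_steps: int = 40  # compass-search polish iterations after NM
    cylinder_cost_mode: str = "mesh"  # 'mesh': distance to the faceted
    # 250-vertex cylinder surface (closed form); 'points': to its vertices

    def __post_init__(self):
        if self.cylinder_sample_points < 8:
            raise ArgumentError("cylinder_sample_points must be >= 8")


@dataclass(frozen=True)
class CylinderParams:
    """Six-parameter cylinder: axis direction (longitude/latitude, degrees),
    a point on the axis (mm) and the radius (mm)."""

    longitude: float
    latitude: float
    origin: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.radius <= 0:
            raise ArgumentError("cylinder radius must be positive")

    def axis(self) -> np.ndarray:
        lon = np.radians(self.longitude)
        lat = np.radians(self.latitude)
        return np.array(
            [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
        )

    def as_array(self) -> np.ndarray:
        return np.concatenate(
            [[self.longitude, self.latitude], self.origin, [self.radius]]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "CylinderParams":
        return cls(float(x[0]), float(x[1]), np.array(x[2:5]), float(max(x[5], 1e-6)))


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal frame: x̂ lateral-left, ŷ cranial, ẑ = x̂ × ŷ."""

    origin: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray
    z_hat: np.ndarray
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for name in ("origin", "x_hat", "y_hat", "z_hat"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        R = self.rotation()
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise DegenerateFrameError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise DegenerateFrameError("frame is left-handed")

    def rotation(self) -> np.ndarray:
        """Rows are x̂, ŷ, ẑ: maps world vectors to frame coordinates."""
        return np.vstack([self.x_hat, self.y_hat, self.z_hat])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.rotation().T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation() + self.origin

    def to_json(self, path) -> None:
        payload = {
            "origin": self.origin.tolist(),
            "x_hat": self.x_hat.tolist(),
            "y_hat": self.y_hat.tolist(),
            "z_hat": self.z_hat.tolist(),
            "diagnostics": {
                k: (float(v) if np.isscalar(v) else v)
                for k, v in self.diagnostics.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AnatomicalFrame":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.array(d["origin"]),
            np.array(d["x_hat"]),
            np.array(d["y_hat"]),
            np.array(d["z_hat"]),
            d.get("diagnostics", {}),
        )


def _vertices_of(head) -> np.ndarray:
    if isinstance(head, trimesh.Trimesh):
        return np.asarray(head.vertices, dtype=float)
    return np.atleast_2d(np.asarray(head, dtype=float))


def _subsample(vertices: np.ndarray, cfg: FrameConfig) -> np.ndarray:
    if vertices.shape[0] <= cfg.max_cost_vertices:
        return vertices
    rng = np.random.default_rng(cfg.subsample_seed)
    idx = rng.choice(vertices.shape[0], size=cfg.max_cost_vertices, replace=False)
    return vertices[np.sort(idx)]


def initial_sagittal_guess(head, cfg: "FrameConfig | None" = None) -> PlaneParams3:
    """Automatic initializer for the symmetry-plane search.

    Candidate planes through the centroid normal to each principal axis of
    the vertex cloud are scored with the mirror cost; the cheapest one
    seeds the optimizer.  (The smallest-extent axis is usually — but not
    always — the left-right direction, e.g. for long-faced heads.)
    """
    cfg = cfg or FrameConfig()
    v = _vertices_of(head)
    c = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - c, full_matrices=False)
    sub = _subsample(v, cfg)
    best = None
    for n in vt:
        plane = Plane(n, float(np.dot(n, c)))
        cost = trimmed_mean_nn_distance(
            sub, plane.mirror(sub), cfg.trim_sd_factor, cfg.sd_mode
        )
        if best is None or cost < best[0]:
            best = (cost, plane)
    return best[1].to_params()


def initial_cylinder_guess(head) -> CylinderParams:
    """Automatic initializer: axis = largest-extent principal axis through
    the centroid; radius = mean distance of vertices to that line."""
    v = _vertices_of(head)
    c = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - c, full_matrices=False)
    axis = vt[0]
    # geometry cannot tell cranial from caudal; default to the scanner's
    # world +y (callers with orientation metadata pass a cranial hint)
    if axis[1] < 0 or (axis[1] == 0 and axis[2] < 0):
        axis = -axis
    rel = v - c
    radial = rel - np.outer(rel @ axis, axis)
    radius = float(np.linalg.norm(radial, axis=1).mean())
    lat = np.degrees(np.arcsin(np.clip(axis[2], -1, 1)))
    lon = np.degrees(np.arctan2(axis[1], axis[0]))
    return CylinderParams(lon, lat, c, max(radius, 1.0))


def _run_nelder_mead(cost, x0, steps, cfg: FrameConfig, grid_span: float = 0.75):
    """Nelder–Mead with fresh-simplex restarts.

    The trimmed-NN cost is piecewise smooth (the trimmed subset changes
    with the parameters), which can collapse the simplex on a plateau;
    re-inflating it at the best point found lets the search escape."""
    steps0 = np.asarray(steps, dtype=float)
    steps = steps0.copy()
    best = None
    x = np.asarray(x0, dtype=float)
    for attempt in range(cfg.restarts + 1):
        simplex = np.vstack([x] + [x + np.eye(len(x))[i] * steps[i] for i in range(len(x))])
        res = minimize(
            cost,
            x,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "fatol": cfg.fatol,
                "xatol": cfg.xatol,
                "maxiter": cfg.max_iterations,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        x = np.asarray(best.x, dtype=float)
        steps = steps / 2.0
    # deterministic rescan over the two orientation angles: the trimmed
    # cost can have narrow basins flanked by shallow side minima (e.g.
    # sampling resonances of regular meshes), which pure descent misses
    x, fx = _angle_grid_refine(cost, np.asarray(best.x, float), best.fun, cfg, span=grid_span)
    if fx < best.fun:
        res = minimize(
            cost,
            x,
            method="Nelder-Mead",
            options={
                "initial_simplex": np.vstack(
                    [x] + [x + np.eye(len(x))[i] * min(s, 0.25) for i, s in enumerate(steps0)]
                ),
                "fatol": cfg.fatol,
                "xatol": cfg.xatol,
                "maxiter": cfg.max_iterations,
            },
        )
        if res.fun < fx:
            x, fx = res.x, res.fun
        best.x, best.fun = x, fx
    if cfg.polish_steps > 0:
        x, fx = _compass_polish(
            cost, np.asarray(best.x, float), np.asarray(steps0, float) / 2.0,
            best.fun, cfg.polish_steps,
        )
        best.x, best.fun = x, fx
    return best


def _angle_grid_refine(cost, x, fx, cfg: FrameConfig, span: float = 0.75, step: float = 0.25):
    """Scan a small (longitude, latitude) grid around the current optimum."""
    offsets = np.arange(-span, span + 1e-9, step)
    best_x, best_f = x, fx
    for da in offsets:
        for db in offsets:
            if da == 0.0 and db == 0.0:
                continue
            trial = x.copy()
            trial[0] += da
            trial[1] += db
            ft = cost(trial)
            if ft < best_f:
                best_x, best_f = trial, ft
    return best_x, best_f


def _compass_polish(cost, x, steps, fx, max_steps):
    """Deterministic compass (pattern) search with shrinking steps.

    The trimmed-NN cost is only piecewise smooth, so the simplex can stall
    in micro-basins; axis-aligned probing with step halving descends them
    reliably and deterministically."""
    steps = steps.copy()
    for _ in range(max_steps):
        improved = False
        for i in range(len(x)):
            for sgn in (1.0, -1.0):
                trial = x.copy()
                trial[i] += sgn * steps[i]
                ft = cost(trial)
                if ft < fx:
                    x, fx = trial, ft
                    improved = True
                    break
        if not improved:
            steps /= 2.0
            if np.max(steps) < 1e-4:
                break
    return x, fx


def find_midsagittal_plane(
    head,
    initial: PlaneParams3 | None = None,
    cfg: FrameConfig | None = None,
) -> tuple[Plane, float]:
    """Mid-sagittal symmetry plane of a head mesh.

    Minimizes the trimmed mean NN distance between the (subsampled) head
    vertices and their mirror image across the candidate plane, over the
    3-parameter chart (longitude, latitude, distance).  Returns the plane
    and the final cost evaluated on the full vertex set.

    Raises :class:`ConvergenceError` (carrying the best plane so far) if
    the simplex does not converge within ``cfg.max_iterations``.
    """
    cfg = cfg or FrameConfig()
    vertices = _vertices_of(head)
    sub = _subsample(vertices, cfg)
    tree = cKDTree(sub)

    def cost(x: np.ndarray) -> float:
        plane = PlaneParams3(x[0], x[1], x[2]).to_plane()
        mirrored = plane.mirror(sub)
        # mirroring is an isometry, so the original→mirrored NN distances
        # equal the mirrored→original ones point-for-point:
        # |a_i − M(a_j)| = |M(a_i) − a_j|.  Both directions therefore share
        # one prebuilt tree on the original vertices; 'symmetric' averages
        # the two (identical) trimmed means and needs no second pass.
        return trimmed_mean_nn_distance(
            mirrored, sub, cfg.trim_sd_factor, cfg.sd_mode, target_tree=tree
        )

    steps = [cfg.initial_step_deg, cfg.initial_step_deg, cfg.initial_step_mm]
    if initial is None:
        # the trimmed cost deliberately tolerates local asymmetries (a
        # missing auricle), so a static score cannot tell the true
        # bilateral plane from another near-symmetry of the head: briefly
        # descend from each principal-axis candidate and keep the best
        c = vertices.mean(axis=0)
        _, _, vt = np.linalg.svd(vertices - c, full_matrices=False)
        best_x, best_f = None, np.inf
        for n in vt:
            x0 = Plane(n, float(np.dot(n, c))).to_params().as_array()
            res = minimize(
                cost,
                x0,
                method="Nelder-Mead",
                options={
                    "initial_simplex": np.vstack(
                        [x0] + [x0 + np.eye(3)[i] * steps[i] for i in range(3)]
                    ),
                    "fatol": 1e-2,
                    "xatol": 1e-2,
                    "maxiter": 80,
                },
            )
            if res.fun < best_f:
                best_x, best_f = res.x, res.fun
        initial = PlaneParams3(*best_x)
    x0 = initial.as_array()
    res = _run_nelder_mead(cost, x0, steps, cfg)
    plane = PlaneParams3(*res.x).to_plane()
    mirrored = plane.mirror(vertices)
    final_cost = trimmed_mean_nn_distance(
        vertices, mirrored, cfg.trim_sd_factor, cfg.sd_mode
    )
    if not res.success:
        raise ConvergenceError(
            "mid-sagittal plane search did not converge", best=(plane, final_cost)
        )
    return plane, final_cost


def sample_cylinder_surface(
    params: CylinderParams, span: tuple[float, float], n_points: int
) -> np.ndarray:
    """Roughly uniform point sampling of a finite cylinder surface.

    ``span`` is the axial extent (mm, relative to ``params.origin``) that
    the sampled mesh must cover — in practice the head's bounding extent
    along the axis.
    """
    axis = params.axis()
    u = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    n_axial, n_circ = _cylinder_mesh_layout(n_points)
    h = np.linspace(span[0], span[1], n_axial)
    th = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    H, TH = np.meshgrid(h, th, indexing="ij")
    pts = (
        params.origin
        + H.ravel()[:, None] * axis
        + params.radius * (np.cos(TH.ravel())[:, None] * e1 + np.sin(TH.ravel())[:, None] * e2)
    )
    return pts


def _cylinder_mesh_layout(n_points: int) -> tuple[int, int]:
    """Rings × sectors of the sampled cylinder mesh (≈ ``n_points`` vertices)."""
    n_axial = max(2, int(round(np.sqrt(n_points / 2))))
    n_circ = max(4, int(round(n_points / n_axial)))
    return n_axial, n_circ


def cylinder_mesh_distance(
    points: np.ndarray,
    params: CylinderParams,
    span: tuple[float, float],
    n_circ: int,
) -> np.ndarray:
    """Exact unsigned distance from points to the faceted cylinder surface.

    The sampled cylinder mesh is an ``n_circ``-sided prism spanning
    ``span`` along the axis; the nearest point of any query lies in its
    angular sector, so the distance reduces to a chord-line distance plus
    an axial overshoot.  The prism's vertices are placed slightly outside
    the nominal radius so the facets straddle the true cylinder surface
    (zero-mean chordal error), keeping the fitted radius unbiased by the
    sparse sampling.
    """
    points = np.atleast_2d(points)
    axis = params.axis()
    u = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rel = points - params.origin
    y = rel @ axis
    c1 = rel @ e1
    c2 = rel @ e2
    rho = np.hypot(c1, c2)
    phi = np.arctan2(c2, c1)
    delta = 2.0 * np.pi / n_circ
    alpha = np.mod(phi, delta) - delta / 2.0  # offset from the sector midline
    # mid-surface apothem: facets straddle the radius-R cylinder
    apothem = params.radius * (1.0 + np.cos(delta / 2.0)) / 2.0
    d_cross = np.abs(rho * np.cos(alpha) - apothem)
    dy_out = np.maximum(np.maximum(span[0] - y, y - span[1]), 0.0)
    return np.hypot(d_cross, dy_out)


def point_to_cylinder_distance(points: np.ndarray, params: CylinderParams) -> np.ndarray:
    """Analytic unsigned distance from points to an infinite cylinder surface."""
    points = np.atleast_2d(points)
    axis = params.axis()
    rel = points - params.origin
    radial = rel - np.outer(rel @ axis, axis)
    return np.abs(np.linalg.norm(radial, axis=1) - params.radius)


def fit_head_cylinder(
    head,
    initial: CylinderParams | None = None,
    cfg: FrameConfig | None = None,
) -> tuple[CylinderParams, float]:
    """Fit a cylinder to the head by trimmed-NN cost against a sampled
    cylinder surface.

    The cost is the trimmed mean NN distance from the head vertices to a
    ``cfg.cylinder_sample_points``-point sampling of the candidate cylinder
    spanning the head's extent along the axis.  The returned axis is
    normalized to point the same way as the initial axis (cranially, when
    the initializer is sensible).
    """
    cfg = cfg or FrameConfig()
    vertices = _vertices_of(head)
    c = vertices.mean(axis=0)
    spread = np.linalg.svd(vertices - c, full_matrices=False)[1]
    if spread[1] <= 1e-9 * max(spread[0], 1.0):
        raise DegenerateGeometryError("vertices are collinear; cylinder fit undefined")
    if initial is None:
        initial = initial_cylinder_guess(vertices)
    sub = _subsample(vertices, cfg)
    init_axis = initial.axis()

    _, n_circ = _cylinder_mesh_layout(cfg.cylinder_sample_points)

    def cost(x: np.ndarray) -> float:
        p = CylinderParams.from_array(x)
        ax = p.axis()
        proj = (sub - p.origin) @ ax
        span = (float(proj.min()), float(proj.max()))
        if cfg.cylinder_cost_mode == "points":
            surf = sample_cylinder_surface(p, span, cfg.cylinder_sample_points)
            return trimmed_mean_nn_distance(sub, surf, cfg.trim_sd_factor, cfg.sd_mode)
        d = cylinder_mesh_distance(sub, p, span, n_circ)
        return trimmed_mean(d, cfg.trim_sd_factor, cfg.sd_mode)

    x0 = initial.as_array()
    steps = [cfg.initial_step_deg, cfg.initial_step_deg] + [cfg.initial_step_mm] * 4
    # the cylinder's tilt landscape has shallow local minima over a couple
    # of degrees; rescan a wider angle grid than the plane search needs
    res = _run_nelder_mead(cost, x0, steps, cfg, grid_span=2.0)
    best = CylinderParams.from_array(res.x)
    if float(np.dot(best.axis(), init_axis)) < 0:
        # keep the axis pointing cranially: flip via the antipodal chart
        lon = best.longitude + 180.0
        if lon >= 180.0:
            lon -= 360.0
        best = CylinderParams(lon, -best.latitude, best.origin, best.radius)
    proj = (vertices - best.origin) @ best.axis()
    span = (float(proj.min()), float(proj.max()))
    if cfg.cylinder_cost_mode == "points":
        surf = sample_cylinder_surface(best, span, cfg.cylinder_sample_points)
        final_cost = trimmed_mean_nn_distance(
            vertices, surf, cfg.trim_sd_factor, cfg.sd_mode
        )
    else:
        final_cost = trimmed_mean(
            cylinder_mesh_distance(vertices, best, span, n_circ),
            cfg.trim_sd_factor,
            cfg.sd_mode,
        )
    if not res.success:
        raise ConvergenceError(
            "cylinder fit did not converge", best=(best, final_cost)
        )
    return best, final_cost


def build_anatomical_frame(
    head,
    sagittal: Plane,
    cylinder: CylinderParams,
    left_hint: np.ndarray,
    diagnostics: dict | None = None,
) -> AnatomicalFrame:
    """Assemble the right-handed anatomical frame.

    x̂ is the sagittal normal oriented so ``x̂ · left_hint > 0``; ŷ is the
    cylinder axis Gram–Schmidt-orthogonalized against x̂ (kept pointing the
    way the fitted axis points, i.e. cranially); ẑ = x̂ × ŷ.  The origin is
    the head vertex centroid projected orthogonally into the sagittal
    plane.
    """
    left_hint = np.asarray(left_hint, dtype=float)
    if np.linalg.norm(left_hint) == 0:
        raise ArgumentError("left_hint must be a nonzero vector")
    vertices = _vertices_of(head)
    axis = cylinder.axis()
    x_hat = sagittal.oriented(left_hint).normal
    cos_angle = abs(float(np.dot(axis, x_hat)))
    if cos_angle > np.cos(np.radians(10.0)):
        raise DegenerateFrameError(
            "cylinder axis within 10 deg of the sagittal normal; frame undefined"
        )
    y_hat = axis - float(np.dot(axis, x_hat)) * x_hat
    y_hat /= np.linalg.norm(y_hat)
    z_hat = np.cross(x_hat, y_hat)
    origin = sagittal.project(vertices.mean(axis=0))[0]
    return AnatomicalFrame(origin, x_hat, y_hat, z_hat, diagnostics or {})


def derive_frame(
    head,
    left_hint: np.ndarray,
    cfg: FrameConfig | None = None,
    initial_sagittal: PlaneParams3 | None = None,
    initial_cylinder: CylinderParams | None = None,
    cranial_hint: np.ndarray | None = None,
) -> tuple[AnatomicalFrame, Plane, CylinderParams]:
    """Full frame derivation: sagittal plane, cylinder, then the frame.

    ``cranial_hint`` orients the ŷ axis; without it the fitted axis keeps
    the initializer's convention (world +y-ish), which is only meaningful
    when the scan is roughly upright.
    """
    cfg = cfg or FrameConfig()
    sagittal, sag_cost = find_midsagittal_plane(head, initial_sagittal, cfg)
    cylinder, cyl_cost = fit_head_cylinder(head, initial_cylinder, cfg)
    if cranial_hint is not None and float(np.dot(cylinder.axis(), cranial_hint)) < 0:
        lon = cylinder.longitude + 180.0
        if lon >= 180.0:
            lon -= 360.0
        cylinder = CylinderParams(lon, -cylinder.latitude, cylinder.origin, cylinder.radius)
    frame = build_anatomical_frame(
        head,
        sagittal,
        cylinder,
        left_hint,
        diagnostics={"sagittal_cost_mm": sag_cost, "cylinder_cost_mm": cyl_cost},
    )
    return frame, sagittal, cylinder
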