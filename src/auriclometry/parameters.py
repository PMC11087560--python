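"""Auricle parameters computed from the extracted surface and planes.

Eight quantities per side, following common clinical usage:

* two auriculocephalic (AC) angles — between the auricle-plane normal and
  the mid-sagittal-plane normal, and between the auricle-plane normal and
  the mastoid-plane normal (both normals oriented laterally, so the angle
  is the opening angle of the protruding auricle);
* protrusion — the largest perpendicular distance from the mastoid plane
  to any selected auricle point;
* length and width, each in two variants: the *diameter* variant (largest
  in-plane point pair distance L, extent perpendicular to L) and the *PCA*
  variant (bounding-rectangle extents along the in-plane inertia axes);
* inclination — angle between the sagittal projection of the length axis
  and the cranio-caudal ŷ axis, again for both variants;

plus the bilateral position differences of the auricle centers (selection
box centers projected into the sagittal plane) along ẑ (posterior–
anterior) and ŷ (superior–inferior).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import trimesh

from .errors import ArgumentError, DegenerateInclinationError
from .extraction import (
    AuricleSurface,
    ExtractionConfig,
    MastoidOutline,
    SelectionBox,
    compute_mastoid_outline,
    project_surface_to_plane,
    select_auricle_surface,
)
from .frame import AnatomicalFrame, FrameConfig, derive_frame
from .geometry import (
    InPlanePointSet,
    Plane,
    bounding_extents_along_axes,
    diameter_2d,
    inertia_axes_2d,
    perpendicular_extent_2d,
)

__all__ = [
    "AuricleParameters",
    "PositionDifference",
    "MeasurementResult",
    "ac_angle_sagittal",
    "ac_angle_mastoid",
    "protrusion_distance",
    "length_width_diameter",
    "length_width_pca",
    "inclination_angle",
    "bilateral_position_difference",
    "measure_side",
    "measure_all",
]


@dataclass
class AuricleParameters:
    side: str
    ac_angle_sagittal_deg: float
    ac_angle_mastoid_deg: float
    protrusion_mm: float
    length_diameter_mm: float
    width_diameter_mm: float
    length_pca_mm: float
    width_pca_mm: float
    inclination_pca_deg: float
    inclination_diameter_deg: float
    center: np.ndarray
    length_line: tuple = field(default=None, repr=False)
    width_line: tuple = field(default=None, repr=False)
    isotropic: bool = False
    diagnostics: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = {}
        for k, v in asdict(self).items():
            if isinstance(v, np.ndarray):
                v = np.round(v, 3).tolist()
            elif isinstance(v, float):
                v = round(v, 3)
            elif k in ("length_line", "width_line") and v is not None:
                v = [np.round(np.asarray(e), 3).tolist() for e in v]
            d[k] = v
        return d


@dataclass
class PositionDifference:
    """Left-minus-right auricle center differences in the sagittal plane."""

    delta_pa_mm: float  # along ẑ (posterior–anterior)
    delta_si_mm: float  # along ŷ (superior–inferior)

    def to_dict(self) -> dict:
        return {
            "delta_pa_mm": round(self.delta_pa_mm, 3),
            "delta_si_mm": round(self.delta_si_mm, 3),
        }


def _angle_between_normals(a: Plane, b: Plane) -> float:
    c = float(np.clip(np.dot(a.normal, b.normal), -1.0, 1.0))
    ang = float(np.degrees(np.arccos(c)))
    return ang % 180.0


def ac_angle_sagittal(auricle_plane: Plane, sagittal: Plane, lateral_hint=None) -> float:
    """AC angle between auricle-plane and sagittal-plane normals (degrees).

    Both normals must be (or are re-oriented to be) laterally directed on
    the same side; the result lies in [0, 180).
    """
    if lateral_hint is not None:
        auricle_plane = auricle_plane.oriented(lateral_hint)
        sagittal = sagittal.oriented(lateral_hint)
    return _angle_between_normals(auricle_plane, sagittal)


def ac_angle_mastoid(auricle_plane: Plane, mastoid_plane: Plane, lateral_hint=None) -> float:
    """AC angle between auricle-plane and mastoid-plane normals (degrees)."""
    if lateral_hint is not None:
        auricle_plane = auricle_plane.oriented(lateral_hint)
        mastoid_plane = mastoid_plane.oriented(lateral_hint)
    return _angle_between_normals(auricle_plane, mastoid_plane)


def protrusion_distance(surface: AuricleSurface, mastoid_plane: Plane) -> float:
    """Largest signed perpendicular distance (mm) from the mastoid plane to
    any selected auricle point; the plane normal must point laterally."""
    return float(mastoid_plane.signed_distance(surface.points).max())


def length_width_diameter(in_plane: InPlanePointSet):
    """Diameter-based length/width of the projected auricle.

    Length is the largest in-plane point-pair distance (line L); width is
    the extent of all points projected perpendicular to L (line W).
    Returns ``(length, width, L_endpoint_indices, W_line)``.
    """
    length, i, j = diameter_2d(in_plane)
    axis = in_plane.points2d[j] - in_plane.points2d[i]
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ArgumentError("diameter endpoints coincide")
    width, w_line = perpendicular_extent_2d(in_plane, axis / norm)
    return length, width, (i, j), w_line


def length_width_pca(in_plane: InPlanePointSet):
    """PCA-based length/width: bounding-rectangle extents along the in-plane
    inertia axes (length along the smallest-inertia eigenvector).

    Returns ``(length, width, (length_axis, width_axis), isotropic)``.
    For elongated auricle-like point sets the smallest-inertia axis always
    carries the larger extent; for strongly non-convex clouds the two
    orderings can disagree, in which case the axes are relabeled so that
    width ≤ length always holds.
    """
    length_axis, width_axis, _, isotropic = inertia_axes_2d(in_plane)
    length, width = bounding_extents_along_axes(in_plane, (length_axis, width_axis))
    if width > length:
        length, width = width, length
        length_axis, width_axis = width_axis, length_axis
    return length, width, (length_axis, width_axis), isotropic


def inclination_angle(
    length_axis_3d: np.ndarray,
    frame: AnatomicalFrame,
    signed: bool = False,
) -> float:
    """Inclination (degrees): angle between the sagittal projection of the
    length axis and the cranio-caudal ŷ axis.

    Unsigned by default, in [0, 90], invariant to the axis sign.  With
    ``signed=True`` the result lies in (−90, 90], positive when the
    cranial end of the axis leans toward +ẑ.
    """
    a = np.asarray(length_axis_3d, dtype=float)
    ay = float(np.dot(a, frame.y_hat))
    az = float(np.dot(a, frame.z_hat))
    norm = np.hypot(ay, az)
    if norm < 1e-9 * max(np.linalg.norm(a), 1.0):
        raise DegenerateInclinationError(
            "length axis is parallel to x̂; no sagittal projection"
        )
    if ay < 0:  # make the axis point cranially; result is sign-invariant
        ay, az = -ay, -az
    if signed:
        return float(np.degrees(np.arctan2(az, ay)))
    return float(np.degrees(np.arccos(np.clip(ay / norm, -1.0, 1.0))))


def bilateral_position_difference(
    left_box: SelectionBox, right_box: SelectionBox, frame: AnatomicalFrame, sagittal: Plane | None = None
) -> PositionDifference:
    """Left-minus-right box-center differences, projected into the sagittal
    plane, along ẑ (posterior–anterior) and ŷ (superior–inferior).

    Box centers are in frame coordinates; projecting into the mid-sagittal
    plane of the frame simply zeroes the x̂ component, so the differences
    are the y/z components of the center difference.
    """
    delta = left_box.center - right_box.center
    return PositionDifference(delta_pa_mm=float(delta[2]), delta_si_mm=float(delta[1]))


def measure_side(
    head: trimesh.Trimesh,
    frame: AnatomicalFrame,
    sagittal: Plane,
    box: SelectionBox,
    cfg: ExtractionConfig | None = None,
) -> tuple[AuricleParameters, AuricleSurface, MastoidOutline]:
    """Run extraction and all per-side parameter computations."""
    cfg = cfg or ExtractionConfig()
    surface = select_auricle_surface(head, frame, box, cfg)
    outline = compute_mastoid_outline(head, surface, frame, sagittal, cfg)
    in_plane = project_surface_to_plane(surface, frame)

    lateral = surface.lateral_dir
    ac_sag = ac_angle_sagittal(surface.plane, sagittal, lateral_hint=lateral)
    ac_mas = ac_angle_mastoid(surface.plane, outline.plane, lateral_hint=lateral)
    protrusion = protrusion_distance(surface, outline.plane.oriented(lateral))

    len_d, wid_d, (i, j), w_line = length_width_diameter(in_plane)
    len_p, wid_p, (l_axis, w_axis), isotropic = length_width_pca(in_plane)

    # diameter-variant axis: the 3-D segment between L's unprojected points
    axis_d_3d = surface.points[j] - surface.points[i]
    axis_p_3d = l_axis[0] * in_plane.basis_u + l_axis[1] * in_plane.basis_v
    incl_d = inclination_angle(axis_d_3d, frame)
    incl_p = inclination_angle(axis_p_3d, frame)

    params = AuricleParameters(
        side=box.side,
        ac_angle_sagittal_deg=ac_sag,
        ac_angle_mastoid_deg=ac_mas,
        protrusion_mm=protrusion,
        length_diameter_mm=len_d,
        width_diameter_mm=wid_d,
        length_pca_mm=len_p,
        width_pca_mm=wid_p,
        inclination_pca_deg=incl_p,
        inclination_diameter_deg=incl_d,
        center=box.center.copy(),
        length_line=(surface.points[i], surface.points[j]),
        width_line=tuple(in_plane.to_3d(np.vstack(w_line))),
        isotropic=isotropic,
        diagnostics={
            "n_selected_points": int(surface.points.shape[0]),
            "auricle_plane_rms_mm": surface.plane_rms_mm,
            "mastoid_plane_rms_mm": outline.plane_rms_mm,
            "mastoid_failed_rays": outline.n_failed_rays,
        },
    )
    return params, surface, outline


@dataclass
class MeasurementResult:
    """Complete bilateral measurement with per-stage diagnostics."""

    left: AuricleParameters
    right: AuricleParameters
    position: PositionDifference
    frame: AnatomicalFrame
    sagittal: Plane
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
            "position": self.position.to_dict(),
            "frame": {
                "origin": np.round(self.frame.origin, 3).tolist(),
                "x_hat": np.round(self.frame.x_hat, 6).tolist(),
                "y_hat": np.round(self.frame.y_hat, 6).tolist(),
                "z_hat": np.round(self.frame.z_hat, 6).tolist(),
            },
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def measure_all(
    head: trimesh.Trimesh,
    left_box: SelectionBox,
    right_box: SelectionBox,
    frame: AnatomicalFrame | None = None,
    sagittal: Plane | None = None,
    left_hint=None,
    cranial_hint=None,
    frame_cfg: FrameConfig | None = None,
    cfg: ExtractionConfig | None = None,
) -> MeasurementResult:
    """Measure both auricles of a head mesh.

    If ``frame``/``sagittal`` are not supplied they are derived from the
    mesh (``left_hint`` then being mandatory; ``cranial_hint`` orients ŷ
    for scans that are not roughly upright).  Boxes are given in frame
    coordinates.
    """
    diagnostics = {}
    if frame is None:
        if left_hint is None:
            raise ArgumentError("left_hint is required when the frame is derived")
        frame, sagittal, _cyl = derive_frame(
            head, left_hint, frame_cfg, cranial_hint=cranial_hint
        )
        diagnostics.update(frame.diagnostics)
    elif sagittal is None:
        # the frame's own sagittal plane: normal x̂ through the origin
        sagittal = Plane(frame.x_hat, float(np.dot(frame.x_hat, frame.origin)))
    left_params, _, _ = measure_side(head, frame, sagittal, left_box, cfg)
    right_params, _, _ = measure_side(head, frame, sagittal, right_box, cfg)
    position = bilateral_position_difference(left_box, right_box, frame, sagittal)
    return MeasurementResult(
        left=left_params,
        right=right_params,
        position=position,
        frame=frame,
        sagittal=sagittal,
        diagnostics=diagnostics,
    )
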