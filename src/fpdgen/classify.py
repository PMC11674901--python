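"""Support-type detection from lumen cross-section circularity.

Each lumen is sliced with a stack of equally spaced planes perpendicular
to the gingival-to-occlusal axis of the restoration's bounding box.  The
circularity index CI = mean(4*pi*A_i / Pe_i^2) over the retained closed
section curves is 1 for perfect circles and drops toward 0 for irregular
shapes; machined implant abutments read close to 1, natural tooth stumps
clearly below.  A bridge is classified implant-supported when both sides
have CI in [0.97, 1], tooth-supported otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import Polygon

from .geometry import Frame, GeometryError, Polyline3D, section_with_plane

CI_IMPLANT_MIN = 0.97
CI_IMPLANT_MAX = 1.0


@dataclass
class SectionStack:
    """Closed lumen section curves retained for circularity analysis."""

    curves: list[Polyline3D]
    plane_positions: np.ndarray  # parameter along the slicing axis, per curve
    axis: np.ndarray  # unit slicing direction (plane normal)


@dataclass
class CiReport:
    ci_distal: float
    ci_mesial: float
    support_type: str
    per_curve_distal: list[tuple[float, float, float]] = field(default_factory=list)
    per_curve_mesial: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ci_distal": self.ci_distal,
            "ci_mesial": self.ci_mesial,
            "support_type": self.support_type,
            "per_curve_distal": [
                {"area_mm2": a, "perimeter_mm": p, "ratio": r}
                for a, p, r in self.per_curve_distal
            ],
            "per_curve_mesial": [
                {"area_mm2": a, "perimeter_mm": p, "ratio": r}
                for a, p, r in self.per_curve_mesial
            ],
        }


def section_lumen(
    lumen: trimesh.Trimesh,
    p_start: np.ndarray,
    p_end: np.ndarray,
    n_planes: int = 100,
) -> SectionStack:
    """Slice a lumen with ``n_planes`` equally spaced planes along the
    segment from ``p_start`` to ``p_end`` (endpoints included), keep only
    closed intersection curves, then drop the first and last retained
    curves to discard margin/tip artefacts."""
    if n_planes < 3:
        raise GeometryError("need at least 3 slicing planes")
    p_start = np.asarray(p_start, dtype=float)
    p_end = np.asarray(p_end, dtype=float)
    axis = p_end - p_start
    length = np.linalg.norm(axis)
    if length < 1e-12:
        raise GeometryError("degenerate slicing segment")
    axis = axis / length

    curves: list[Polyline3D] = []
    positions: list[float] = []
    for t in np.linspace(0.0, 1.0, n_planes):
        origin = p_start + t * length * axis
        plane = Frame.from_origin_normal(origin, axis)
        for poly in section_with_plane(lumen, plane):
            if poly.closed and len(poly) >= 3:
                curves.append(poly)
                positions.append(float(t))
    if len(curves) < 3:
        raise GeometryError(
            "lumen too shallow to classify: fewer than 3 closed section "
            "curves"
        )
    # protocol: remove the initial and final retained curves
    curves = curves[1:-1]
    positions = positions[1:-1]
    return SectionStack(curves, np.asarray(positions), axis)


def _curve_metrics(curve: Polyline3D, axis: np.ndarray,
                   n_resample: int = 256) -> tuple[float, float] | None:
    """(area, perimeter) of the section polygon projected into its plane;
    None when the polygon self-intersects."""
    rs = curve.resample(n_resample)
    area, per = rs.area_perimeter(normal=axis)
    if area <= 0 or per <= 0:
        return None
    # self-intersection guard on the projected polygon
    n = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    pts2 = np.column_stack([rs.points @ u, rs.points @ v])
    if not Polygon(pts2).is_valid:
        return None
    return area, per


def circularity_index(stack: SectionStack) -> tuple[float, list[tuple[float, float, float]]]:
    """Mean of 4*pi*A/Pe^2 over the retained closed section curves.

    Self-intersecting section polygons are excluded with a warning.  The
    per-curve ratio is bounded by 1 (isoperimetric inequality) up to
    discretisation slack; the index is invariant under rigid motion and
    uniform scaling.
    """
    per_curve: list[tuple[float, float, float]] = []
    skipped = 0
    for curve in stack.curves:
        m = _curve_metrics(curve, stack.axis)
        if m is None:
            skipped += 1
            continue
        area, per = m
        per_curve.append((area, per, 4.0 * np.pi * area / per**2))
    if skipped:
        warnings.warn(
            f"excluded {skipped} self-intersecting section curve(s)",
            stacklevel=2,
        )
    if not per_curve:
        raise GeometryError("no usable section curves")
    ci = float(np.mean([r for _, _, r in per_curve]))
    return ci, per_curve


def classify_support(ci_distal: float, ci_mesial: float) -> str:
    """'implant' iff both sides have CI in [0.97, 1] (inclusive bounds);
    'tooth' otherwise.  Mixed readings classify as tooth with a warning."""
    slack = 1e-6  # discretisation slack above the exact isoperimetric bound
    def is_implant(ci: float) -> bool:
        return CI_IMPLANT_MIN <= ci <= CI_IMPLANT_MAX + slack

    di, me = is_implant(ci_distal), is_implant(ci_mesial)
    if di and me:
        return "implant"
    if di != me:
        warnings.warn(
            "mixed support readings (one lumen implant-like, one "
            "tooth-like); classifying as tooth",
            stacklevel=2,
        )
    return "tooth"


def detect_support_type(
    aligned_fpd,
    landmarks=None,
    n_planes: int = 100,
) -> CiReport:
    """Full detection pass on an aligned restoration.

    Slices both lumens along the gingival-to-occlusal line of the minimal
    bounding box and applies the CI rule.
    """
    from .alignment import analyse

    if landmarks is None or landmarks.box is None:
        landmarks = analyse(aligned_fpd)
    box = landmarks.box
    gi = landmarks.gingival_face
    centers = box.face_centers()
    p_g = centers[gi]
    p_o = centers[box.opposite_face(gi)]

    reports = {}
    for side, lumen in (("distal", aligned_fpd.distal),
                        ("mesial", aligned_fpd.mesial)):
        stack = section_lumen(lumen, p_g, p_o, n_planes=n_planes)
        ci, per_curve = circularity_index(stack)
        reports[side] = (ci, per_curve)
    ci_d, pc_d = reports["distal"]
    ci_m, pc_m = reports["mesial"]
    return CiReport(
        ci_distal=ci_d,
        ci_mesial=ci_m,
        support_type=classify_support(ci_d, ci_m),
        per_curve_distal=pc_d,
        per_curve_mesial=pc_m,
    )
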