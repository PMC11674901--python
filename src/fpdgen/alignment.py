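"""Restoration alignment: lumen landmarks, gingival face, local frame.

The imported bridge arrives in an arbitrary scanner pose.  Alignment
derives the centre of each lumen margin curve, identifies the gingival
face of the minimal bounding box, builds the restoration's local frame
(origin at the distal lumen centre, x toward the mesial lumen, z occlusal)
and maps everything rigidly onto the global frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import (
    Frame,
    GeometryError,
    OrientedBox,
    Polyline3D,
    concat_meshes,
    min_oriented_bounding_box,
    naked_edge_loops,
)


@dataclass
class FpdModel:
    """The three labeled sub-meshes of a 4-unit bridge."""

    surface: trimesh.Trimesh
    distal: trimesh.Trimesh
    mesial: trimesh.Trimesh

    @property
    def merged(self) -> trimesh.Trimesh:
        return concat_meshes([self.surface, self.distal, self.mesial], "fpd")

    @classmethod
    def from_solids(cls, solids: dict) -> "FpdModel":
        missing = {"surface", "distal", "mesial"} - set(solids)
        if missing:
            raise GeometryError(
                f"multi-solid STL is missing part(s): {sorted(missing)}"
            )
        return cls(solids["surface"], solids["distal"], solids["mesial"])

    def to_solids(self) -> dict:
        return {
            "surface": self.surface,
            "distal": self.distal,
            "mesial": self.mesial,
        }

    def transformed(self, matrix: np.ndarray) -> "FpdModel":
        out = []
        for m in (self.surface, self.distal, self.mesial):
            c = m.copy()
            c.apply_transform(matrix)
            out.append(c)
        return FpdModel(*out)


@dataclass
class FpdLandmarks:
    p_distal: np.ndarray
    p_mesial: np.ndarray
    margin_distal: Polyline3D
    margin_mesial: Polyline3D
    box: OrientedBox | None = None
    gingival_face: int | None = None
    fpd_frame: Frame | None = None

    @property
    def line_md(self) -> np.ndarray:
        return self.p_mesial - self.p_distal

    @property
    def p_md(self) -> np.ndarray:
        return 0.5 * (self.p_distal + self.p_mesial)


def margin_curve(lumen: trimesh.Trimesh) -> Polyline3D:
    """Outer margin loop of an open lumen surface: the longest naked-edge
    loop (shorter loops are treated as scan noise)."""
    loops = naked_edge_loops(lumen)
    if not loops:
        raise GeometryError(
            "lumen must be open (watertight mesh has no margin curve)"
        )
    return max(loops, key=lambda p: p.length)


def extract_landmarks(fpd: FpdModel, n_resample: int = 256) -> FpdLandmarks:
    """Margin-curve centres of both lumens, their connecting line and its
    midpoint.  Centres are means of arc-length resampled margin points so
    scanner vertex density does not bias them."""
    md = margin_curve(fpd.distal)
    mm = margin_curve(fpd.mesial)
    return FpdLandmarks(
        p_distal=md.centroid(n_resample),
        p_mesial=mm.centroid(n_resample),
        margin_distal=md,
        margin_mesial=mm,
    )


def find_gingival_face(box: OrientedBox, p_md: np.ndarray) -> int:
    """Face of the minimal box whose centre is nearest the lumen midpoint;
    ties break to the lowest face index."""
    d = np.linalg.norm(box.face_centers() - p_md, axis=1)
    return int(np.argmin(np.round(d, 9)))


def build_fpd_frame(landmarks: FpdLandmarks, box: OrientedBox) -> Frame:
    """Local frame: origin at the distal margin centre; z normal to the
    gingival face pointing occlusally; x along the distal-to-mesial line
    projected into the gingival plane; y completes the right-handed set."""
    gi = find_gingival_face(box, landmarks.p_md)
    normals = box.face_normals()
    z = -normals[gi]  # gingival face outward normal points away from crowns
    l_md = landmarks.line_md
    x = l_md - (l_md @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9 * max(np.linalg.norm(l_md), 1.0):
        raise GeometryError("degenerate restoration: lumen line parallel to z")
    x = x / nx
    y = np.cross(z, x)
    frame = Frame(landmarks.p_distal.copy(), np.vstack([x, y, z]))
    landmarks.box = box
    landmarks.gingival_face = gi
    landmarks.fpd_frame = frame
    return frame


def analyse(fpd: FpdModel) -> FpdLandmarks:
    """Landmarks + bounding box + frame in one pass."""
    lm = extract_landmarks(fpd)
    box = min_oriented_bounding_box(fpd.merged)
    build_fpd_frame(lm, box)
    return lm


def align_to_global(fpd: FpdModel, frame: Frame | None = None) -> FpdModel:
    """Rigidly move the restoration so its local frame coincides with the
    global frame (distal margin centre at the origin, mesial centre on +x,
    occlusal direction +z)."""
    if frame is None:
        frame = analyse(fpd).fpd_frame
    T = np.linalg.inv(frame.matrix)
    return fpd.transformed(T)
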