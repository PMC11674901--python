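"""Mandibular bone segment: placement, subtraction, crestal defects.

The bone segment is a layered solid (cortical shell, 0.29 mm graded
transition, cancellous core) with an identified crestal ridge and a centre
curve running along it.  The restoration assembly is placed by mapping the
restoration frame onto a frame built on the centre curve, leaving a
user-set vertical gap ``d_bone`` between the distal margin centre and the
crest; the submerged support parts are then subtracted from the bone.
Crestal bone loss is carved as a saucer: a circular-arc vertical profile
of given depth over a mesiodistal width, spanning the full buccal-oral
width, with a tangent corner fillet at the rim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import trimesh

from .geometry import Frame, GeometryError, Polyline3D
from .materials import BoneQualitySpec


@dataclass
class DefectSpec:
    """Saucer-shaped crestal defect parameters."""

    depth: float  # mm, 0..3 in the study
    width: float = 10.0  # mesiodistal extent, mm
    fillet_radius: float = 0.4  # rim fillet, mm
    shape: str = "saucer"
    sites: list = field(default_factory=list)  # x positions (bone frame)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("defect depth must be >= 0")
        if self.width <= 0:
            raise ValueError("defect width must be positive")
        if self.shape != "saucer":
            raise ValueError("only saucer-shaped defects are supported")

    # profile geometry ----------------------------------------------------
    @property
    def arc_radius(self) -> float:
        d, w = self.depth, self.width
        return w * w / (8.0 * d) + d / 2.0

    def profile(self, dx: np.ndarray) -> np.ndarray:
        """Vertical bone loss f >= 0 at mesiodistal offset dx from the
        site centre: circular arc through (+-w/2, 0) and (0, -depth), with
        a tangent fillet of radius ``fillet_radius`` at the rim."""
        dx = np.abs(np.asarray(dx, dtype=float))
        if self.depth == 0:
            return np.zeros_like(dx)
        R = self.arc_radius
        rf = self.fillet_radius
        d = self.depth
        # fillet circle: tangent to the flat crest and externally tangent
        # to the saucer arc;  centre (x_c, +rf) in (dx, f) coordinates
        x_c = np.sqrt(max((R + rf) ** 2 - (R - d + rf) ** 2, 0.0))
        x_a = x_c * R / (R + rf)  # arc/fillet tangency abscissa
        f = np.zeros_like(dx)
        arc = dx <= x_a
        f[arc] = d - R + np.sqrt(np.maximum(R * R - dx[arc] ** 2, 0.0))
        fil = (~arc) & (dx < x_c)
        f[fil] = rf - np.sqrt(np.maximum(rf * rf - (x_c - dx[fil]) ** 2, 0.0))
        return f


@dataclass
class BoneSegment:
    """Layered bone solid with crestal metadata.

    ``crest_height(x, y)`` returns the intact crestal surface height (bone
    local coordinates); the defect cut surface is derived from it.
    """

    outer: trimesh.Trimesh
    interface_cortical: trimesh.Trimesh  # cortical / transition boundary
    interface_cancellous: trimesh.Trimesh  # transition / cancellous boundary
    centre_curve: Polyline3D
    quality: BoneQualitySpec
    frame: Frame  # x mesiodistal, z vertical (local up)
    crest_height: Callable[[np.ndarray, np.ndarray], np.ndarray]
    defects: list = field(default_factory=list)

    def cut_height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Current (possibly defected) crestal surface height."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h = np.asarray(self.crest_height(x, y), dtype=float)
        for spec in self.defects:
            for site in spec.sites:
                h = h - spec.profile(x - site)
        return h

    def crestal_face_mask(self, mesh: trimesh.Trimesh | None = None) -> np.ndarray:
        """Faces of the crestal ridge top: the near-horizontal band along
        the ridge line (where supports emerge and defects are carved)."""
        m = mesh if mesh is not None else self.outer
        local_n = m.face_normals @ self.frame.axes.T
        local_c = self.frame.to_local(m.triangles_center)
        zmax = local_c[:, 2].max()
        return (local_n[:, 2] > 0.97) & (local_c[:, 2] > zmax - 2.0)


def build_bone_frame(bone: BoneSegment, span: float) -> tuple[Frame, np.ndarray, np.ndarray]:
    """Frame for restoration placement: two points on the centre curve at
    arc distance ``span`` (centred on the curve), projected up to the
    crest; origin at the distal projection, x toward the mesial one.

    Returns (frame, p_cm_distal, p_cm_mesial) — the unprojected curve
    points."""
    curve = bone.centre_curve
    pts = curve.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if span >= total:
        raise GeometryError(
            f"restoration span {span:.1f} mm exceeds the centre curve "
            f"length {total:.1f} mm"
        )
    mid = total / 2.0
    targets = [mid - span / 2.0, mid + span / 2.0]
    cm = [
        np.array([np.interp(t, s, pts[:, k]) for k in range(3)])
        for t in targets
    ]
    up = bone.frame.z
    proj = []
    for q in cm:
        lx, ly = bone.frame.to_local(q)[0, :2]
        h = float(bone.cut_height(np.array([lx]), np.array([ly]))[0])
        proj.append(bone.frame.origin + bone.frame.axes.T @ np.array([lx, ly, h]))
    p_d, p_m = proj
    z = up.copy()
    x = p_m - p_d
    x = x - (x @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise GeometryError("degenerate bone frame")
    x /= nx
    y = np.cross(z, x)
    return Frame(p_d, np.vstack([x, y, z])), cm[0], cm[1]


def place_assembly(
    parts: dict[str, trimesh.Trimesh],
    fpd_frame: Frame,
    bone_frame: Frame,
    d_bone: float = 2.8,
) -> dict[str, trimesh.Trimesh]:
    """Rigidly map the assembly from its restoration frame onto the bone
    frame, then raise it ``d_bone`` along the bone's vertical axis so the
    distal margin centre sits that far above the crest."""
    T = bone_frame.matrix @ np.linalg.inv(fpd_frame.matrix)
    shift = d_bone * bone_frame.z
    out = {}
    lowest = np.inf
    for name, mesh in parts.items():
        m = mesh.copy()
        m.apply_transform(T)
        m.apply_translation(shift)
        out[name] = m
        lowest = min(lowest, float((m.vertices @ bone_frame.z).min()))
    crest_level = float(bone_frame.origin @ bone_frame.z)
    if lowest > crest_level:
        raise GeometryError(
            "support does not reach the bone (d_bone too large?)"
        )
    return out


def subtract_assembly(
    bone: BoneSegment,
    cavity_parts: list[trimesh.Trimesh],
    pitch: float | None = None,
    budget: float = 8.0e6,
) -> BoneSegment:
    """Subtract the cavity-bounding support parts (PDL shells for teeth,
    implant bodies for implants) from the bone solid."""
    from . import sdf

    relevant = [p for p in cavity_parts
                if sdf.surfaces_may_intersect(bone.outer, p)]
    if not relevant:
        return bone
    new_outer = sdf.voxel_combine(
        [bone.outer] + relevant,
        ["difference"] * len(relevant),
        pitch=pitch,
        budget=budget,
    )
    new_outer.metadata["name"] = "bone"
    return replace(bone, outer=new_outer)


def _clamp_to_cut(bone: BoneSegment, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Clamp mesh vertices to lie at or below the (defected) crest cut
    surface, in bone-local coordinates."""
    local = bone.frame.to_local(mesh.vertices)
    cut = bone.cut_height(local[:, 0], local[:, 1])
    over = local[:, 2] > cut
    if not np.any(over):
        return mesh
    local[over, 2] = cut[over]
    out = mesh.copy()
    out.vertices = bone.frame.origin + local @ bone.frame.axes
    return out


def carve_defect(bone: BoneSegment, spec: DefectSpec) -> BoneSegment:
    """Carve saucer defects at each site by clamping the bone surfaces to
    the defected crest height field.  depth = 0 is the identity; carving
    twice with the same spec equals carving once."""
    if not spec.sites:
        raise GeometryError("defect spec has no sites")
    if spec.depth == 0 or spec in bone.defects:
        return bone  # depth 0 and re-carving at equal spec are identities
    clearance = bone.quality.cortical_thickness + bone.quality.transition_thickness
    if spec.depth > clearance:
        warnings.warn(
            f"defect depth {spec.depth} mm enters the cancellous bone "
            f"(cortical + transition = {clearance:.2f} mm for "
            f"{bone.quality.label})",
            stacklevel=2,
        )
    carved = replace(bone, defects=bone.defects + [spec])
    carved.outer = _clamp_to_cut(carved, bone.outer)
    carved.outer.metadata["name"] = "bone"
    carved.interface_cortical = _clamp_to_cut(carved, bone.interface_cortical)
    carved.interface_cancellous = _clamp_to_cut(carved, bone.interface_cancellous)
    return carved


def trim_pdl(pdl: trimesh.Trimesh, bone: BoneSegment) -> trimesh.Trimesh:
    """Cut away the PDL portion standing above the (defected) crestal
    surface by clamping it onto the cut height field."""
    local = bone.frame.to_local(pdl.vertices)
    cut = bone.cut_height(local[:, 0], local[:, 1])
    if np.all(local[:, 2] > cut):
        raise GeometryError("PDL lies entirely above the bone")
    trimmed = _clamp_to_cut(bone, pdl)
    trimmed.metadata["name"] = pdl.metadata.get("name", "pdl") + "_trimmed"
    return trimmed


def defect_extent_measured(
    intact: BoneSegment,
    carved: BoneSegment,
    site: float,
    threshold: float = 0.01,
) -> float:
    """Mesiodistal extent of the carved region at one site: span of the
    vertices whose vertical deviation from the intact surface exceeds the
    threshold.  Requires the carve to have preserved mesh topology."""
    vi = intact.outer.vertices
    vc = carved.outer.vertices
    if len(vi) != len(vc):
        raise GeometryError("intact/carved meshes do not correspond")
    dz = (vi - vc) @ intact.frame.z
    x = intact.frame.to_local(vi)[:, 0]
    half = max(s.width for s in carved.defects) if carved.defects else 10.0
    sel = (dz > threshold) & (np.abs(x - site) < half)
    if not np.any(sel):
        raise GeometryError("no deviated vertices at the site")
    return float(x[sel].max() - x[sel].min())


def defect_max_depth_measured(
    intact: BoneSegment, carved: BoneSegment, site: float
) -> float:
    """Largest vertical deviation from the intact crest at one site."""
    dz = (intact.outer.vertices - carved.outer.vertices) @ intact.frame.z
    x = intact.frame.to_local(intact.outer.vertices)[:, 0]
    half = max(s.width for s in carved.defects) if carved.defects else 10.0
    sel = np.abs(x - site) < half
    return float(dz[sel].max())


def cortical_thickness_measured(
    bone: BoneSegment, n_samples: int = 100, seed: int = 0
) -> float:
    """Mean cortical-layer thickness along inward crest normals: rays cast
    from crestal face centres to the cortical/transition interface."""
    from . import sdf

    mask = bone.crestal_face_mask()
    centers = bone.outer.triangles_center[mask]
    normals = bone.outer.face_normals[mask]
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(centers), size=min(n_samples, len(centers)),
                     replace=False)
    d = sdf.ray_first_hit(centers[idx], -normals[idx], bone.interface_cortical)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise GeometryError("no crest rays hit the cortical interface")
    return float(d.mean())


def crest_height_from_mesh(mesh: trimesh.Trimesh, frame: Frame) -> Callable:
    """Height-field interpolator of a bone mesh's crestal surface, for
    segments loaded from file rather than generated."""
    from scipy.interpolate import LinearNDInterpolator

    local_n = mesh.face_normals @ frame.axes.T
    local_v = frame.to_local(mesh.vertices)
    zmax = local_v[:, 2].max()
    crest_faces = local_n[:, 2] > 0.6
    vids = np.unique(mesh.faces[crest_faces])
    pts = local_v[vids]
    pts = pts[pts[:, 2] > zmax - 6.0]
    interp = LinearNDInterpolator(pts[:, :2], pts[:, 2], fill_value=np.nan)

    def crest(x, y):
        h = interp(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        return np.where(np.isnan(h), zmax, h)

    return crest
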