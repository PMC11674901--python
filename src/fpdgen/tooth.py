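"""Tooth-type support generation: cement shell, abutment teeth, PDL.

The abutment teeth are built from the cement layer's interior surface: its
margin curve is projected onto a stack of level planes along the root axis
and scaled per level by cubic Bezier profiles (separate x and y profiles)
so the cross-section tapers like a natural root.  The premolar keeps a
single root; the molar duplicates the level curves, translating them apart
with a third Bezier profile to form two roots that merge at the furcation.
The periodontal ligament is the thin shell between the root surface and
its outward normal offset.

All shells produced here are watertight by construction: offset surfaces
reuse the source connectivity, so boundary loops correspond vertex-by-
vertex and can be welded with a triangle band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import (
    GeometryError,
    Polyline3D,
    band_between,
    boundary_loop_indices,
    make_mesh,
    mesh_boolean,
    offset_along_normals,
    vertex_normals_area_weighted,
)


# ---------------------------------------------------------------------------
# Bezier profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BezierProfile:
    """Cubic Bezier through four 2D control points (parameter, value)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]

    def __post_init__(self) -> None:
        ts = [self.p0[0], self.p1[0], self.p2[0], self.p3[0]]
        if any(b < a - 1e-12 for a, b in zip(ts, ts[1:])):
            raise ValueError("control-point parameters must be nondecreasing")


def eval_bezier(profile: BezierProfile, t: float) -> np.ndarray:
    """Point on the cubic Bezier at parameter ``t`` in [0, 1]."""
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError("Bezier parameter must lie in [0, 1]")
    p = np.array([profile.p0, profile.p1, profile.p2, profile.p3], dtype=float)
    u = 1.0 - t
    w = np.array([u**3, 3 * u**2 * t, 3 * u * t**2, t**3])
    return w @ p


def bezier_values(profile: BezierProfile, ts: np.ndarray) -> np.ndarray:
    """Value (second) coordinates of the Bezier sampled at parameters ts."""
    return np.array([eval_bezier(profile, t)[1] for t in ts])


# ---------------------------------------------------------------------------
# parameters (defaults are the study's standard configuration)
# ---------------------------------------------------------------------------

_PX = BezierProfile((0.0, 1.0), (0.08, 0.78), (0.75, 0.55), (1.0, 0.05))
_PY = BezierProfile((0.0, 1.0), (0.2, 0.58), (0.95, 0.5), (1.0, 0.05))
_PT = BezierProfile((0.0, 0.0), (0.35, 0.55), (0.4, 0.9), (1.0, 1.0))


@dataclass
class ToothParams:
    """Geometry parameters for one abutment tooth (mm)."""

    d_cement: float = 0.1
    epsilon: float = 0.15  # clearance between margin curve and first level
    d_tooth: float = 16.3  # root-axis length (16.3 premolar, 12.8 molar)
    bezier_x: BezierProfile = field(default_factory=lambda: _PX)
    bezier_y: BezierProfile = field(default_factory=lambda: _PY)
    bezier_t: BezierProfile | None = None  # translation profile (molar only)
    d_r: float = 4.0  # furcation-to-apex x offset (molar only)
    d_pdl: float = 0.3
    n_levels: int = 20

    def __post_init__(self) -> None:
        for name in ("d_cement", "epsilon", "d_tooth", "d_pdl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_r < 0:
            raise ValueError("d_r must be non-negative")
        if self.n_levels < 2:
            raise ValueError("need at least 2 root levels")

    @classmethod
    def premolar(cls, **kw) -> "ToothParams":
        return cls(d_tooth=kw.pop("d_tooth", 16.3), **kw)

    @classmethod
    def molar(cls, **kw) -> "ToothParams":
        kw.setdefault("bezier_t", _PT)
        return cls(d_tooth=kw.pop("d_tooth", 12.8), **kw)


# ---------------------------------------------------------------------------
# cement layer
# ---------------------------------------------------------------------------


@dataclass
class CementLayer:
    mesh: trimesh.Trimesh  # watertight shell
    interior: trimesh.Trimesh  # inward offset surface (open cup)
    interior_loop: np.ndarray  # boundary loop vertex indices into interior
    c_interior: Polyline3D  # boundary loop as polyline


def _single_boundary_loop(mesh: trimesh.Trimesh) -> np.ndarray:
    loops = boundary_loop_indices(mesh)
    if len(loops) == 0:
        raise GeometryError("surface is closed; expected one open margin")
    if len(loops) > 1:
        # keep the longest margin, but a lumen should have exactly one
        lengths = [
            Polyline3D(mesh.vertices[lp], closed=True).length for lp in loops
        ]
        return loops[int(np.argmax(lengths))]
    return loops[0]


def _orient_open_surface(mesh: trimesh.Trimesh, outward_hint: np.ndarray) -> None:
    """Flip face winding in place so mean normal agrees with the hint."""
    vn = mesh.face_normals.mean(axis=0)
    if vn @ outward_hint < 0:
        mesh.invert()


def make_cement_layer(lumen: trimesh.Trimesh, d_cement: float = 0.1) -> CementLayer:
    """Thin shell between the lumen surface and its inward normal offset,
    closed with a band between the corresponding margin loops."""
    if d_cement <= 0:
        raise GeometryError("cement thickness must be positive")
    loop = _single_boundary_loop(lumen)
    interior = offset_along_normals(lumen, d_cement, "inward")
    interior.metadata["name"] = "interior"

    nv = len(lumen.vertices)
    verts = np.vstack([lumen.vertices, interior.vertices])
    faces = [lumen.faces, interior.faces[:, ::-1] + nv,
             band_between(loop, loop + nv)]
    shell = make_mesh(verts, np.vstack(faces), name="cement")
    trimesh.repair.fix_normals(shell)
    if not shell.is_watertight:
        raise GeometryError(
            "cement shell is not watertight (offset self-intersection?)"
        )
    if shell.volume < 0:
        shell.invert()
    return CementLayer(
        mesh=shell,
        interior=interior,
        interior_loop=loop,
        c_interior=Polyline3D(interior.vertices[loop], closed=True),
    )


# ---------------------------------------------------------------------------
# roots
# ---------------------------------------------------------------------------


@dataclass
class ToothSupport:
    solid: trimesh.Trimesh  # watertight abutment tooth
    root_surface: trimesh.Trimesh  # root + apex cap, open at the cervix
    level_z: np.ndarray  # z of each level plane
    scale_x: np.ndarray
    scale_y: np.ndarray
    root_parts: list = field(default_factory=list)  # per-root open surfaces


def _level_heights(c_interior: Polyline3D, p: ToothParams) -> np.ndarray:
    """Level-plane heights: the first level sits epsilon below the margin's
    lowest point; the root axis extends d_tooth further down."""
    z_min = float(c_interior.points[:, 2].min())
    ts = np.linspace(0.0, 1.0, p.n_levels)
    return (z_min - p.epsilon) - p.d_tooth * ts


def _scaled_rings(
    loop_pts: np.ndarray,
    level_z: np.ndarray,
    sx: np.ndarray,
    sy: np.ndarray,
    x_shift: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Project the margin loop onto each level plane and scale it about the
    projected curve's centroid; optionally shift each level in x."""
    centroid = Polyline3D(loop_pts, closed=True).centroid()[:2]
    rings = []
    for j, z in enumerate(level_z):
        if sx[j] <= 0 or sy[j] <= 0:
            raise GeometryError("Bezier scale factors must stay positive")
        xy = loop_pts[:, :2] - centroid
        xy = xy * np.array([sx[j], sy[j]])
        xy = xy + centroid
        if x_shift is not None:
            xy = xy + np.array([x_shift[j], 0.0])
        rings.append(np.column_stack([xy, np.full(len(loop_pts), z)]))
    return rings


def _root_from_rings(
    cement: CementLayer, rings: list[np.ndarray], name: str
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """(solid, open root surface) welded onto the cement interior cup."""
    interior = cement.interior
    loop = cement.interior_loop
    n = len(loop)
    verts = [interior.vertices]
    faces = [interior.faces]
    prev = loop
    base = len(interior.vertices)
    root_faces = []
    for ring in rings:
        verts.append(ring)
        idx = np.arange(n) + base
        root_faces.append(band_between(prev, idx))
        prev = idx
        base += n
    # planar apex cap: centroid fan over the last ring
    apex_c = rings[-1].mean(axis=0)
    verts.append(apex_c[None, :])
    ci = base
    k = np.arange(n)
    root_faces.append(
        np.column_stack([prev[k], prev[(k + 1) % n], np.full(n, ci)])
    )
    faces.extend(root_faces)
    n_interior_faces = len(interior.faces)
    solid = make_mesh(np.vstack(verts), np.vstack(faces), name=name)
    trimesh.repair.fix_normals(solid)
    if not solid.is_watertight:
        raise GeometryError(f"{name} solid is not watertight")
    if solid.volume < 0:
        solid.invert()

    # standalone open root surface (strip + apex): reuse the solid's faces
    # beyond the interior cup so the outward orientation is inherited
    root = make_mesh(
        solid.vertices, solid.faces[n_interior_faces:], name=name + "_root"
    )
    root.remove_unreferenced_vertices()
    return solid, root


def make_single_root(cement: CementLayer, params: ToothParams) -> ToothSupport:
    """Single-rooted abutment tooth (premolar) lofted through Bezier-scaled
    copies of the cement interior margin."""
    ts = np.linspace(0.0, 1.0, params.n_levels)
    sx = bezier_values(params.bezier_x, ts)
    sy = bezier_values(params.bezier_y, ts)
    level_z = _level_heights(cement.c_interior, params)
    if not np.all(np.diff(level_z) < 0):
        raise GeometryError("root levels must decrease monotonically")
    rings = _scaled_rings(cement.c_interior.points, level_z, sx, sy)
    solid, root = _root_from_rings(cement, rings, "tooth_premolar")
    return ToothSupport(solid, root, level_z, sx, sy)


def make_two_root(
    cement: CementLayer,
    params: ToothParams,
    pitch: float | None = None,
    budget: float = 3.0e6,
) -> ToothSupport:
    """Two-rooted abutment tooth (molar): the level curves are duplicated
    and translated by +-B_T(t) * d_R in x, lofted into two root solids that
    share the cement interior cup, then merged with a Boolean union."""
    if params.bezier_t is None:
        raise GeometryError("two-root tooth requires a translation profile")
    ts = np.linspace(0.0, 1.0, params.n_levels)
    sx = bezier_values(params.bezier_x, ts)
    sy = bezier_values(params.bezier_y, ts)
    bt = bezier_values(params.bezier_t, ts)
    level_z = _level_heights(cement.c_interior, params)
    shift = bt * params.d_r
    loop_pts = cement.c_interior.points
    rings1 = _scaled_rings(loop_pts, level_z, sx, sy, x_shift=+shift)
    rings2 = _scaled_rings(loop_pts, level_z, sx, sy, x_shift=-shift)
    s1, r1 = _root_from_rings(cement, rings1, "tooth_molar_r1")
    s2, r2 = _root_from_rings(cement, rings2, "tooth_molar_r2")
    solid = mesh_boolean(s1, s2, "union", pitch=pitch, budget=budget)
    solid.metadata["name"] = "tooth_molar"
    if not solid.is_watertight:
        raise GeometryError("molar union is not watertight")

    # open root surface for reference: union faces below the margin level
    z_cut = float(cement.c_interior.points[:, 2].min()) - 0.5 * params.epsilon
    root = _clip_faces_below(solid, z_cut, "tooth_molar_root")
    return ToothSupport(root_surface=root, solid=solid,
                        level_z=level_z, scale_x=sx, scale_y=sy,
                        root_parts=[r1, r2])


def _clip_faces_below(mesh: trimesh.Trimesh, z_cut: float, name: str) -> trimesh.Trimesh:
    keep = np.all(mesh.vertices[mesh.faces][:, :, 2] <= z_cut, axis=1)
    out = mesh.copy()
    out.update_faces(keep)
    out.remove_unreferenced_vertices()
    out.metadata["name"] = name
    return out


# ---------------------------------------------------------------------------
# periodontal ligament
# ---------------------------------------------------------------------------


def make_pdl(root_surface: trimesh.Trimesh, d_pdl: float = 0.3) -> trimesh.Trimesh:
    """Watertight PDL shell between the root surface and its outward
    normal offset, closed by a band between the cervical margin loops."""
    if d_pdl <= 0:
        raise GeometryError("PDL thickness must be positive")
    loops = boundary_loop_indices(root_surface)
    if len(loops) != 1:
        raise GeometryError(
            f"root surface must have exactly one cervical margin loop "
            f"(found {len(loops)})"
        )
    loop = loops[0]
    outer = offset_along_normals(root_surface, d_pdl, "outward")
    # constant-thickness correction: in concave grooves the plain normal
    # offset lies nearer the opposite wall than d_pdl; rescale each
    # displacement so the true closest-point distance equals d_pdl
    from .sdf import MeshDistance

    vn = vertex_normals_area_weighted(root_surface)
    md = MeshDistance(root_surface)
    mag = np.full(len(vn), d_pdl)
    for _ in range(3):
        pts = root_surface.vertices + vn * mag[:, None]
        cur = np.maximum(md.unsigned(pts), 1e-9)
        mag = np.clip(mag * d_pdl / cur, d_pdl, 2.0 * d_pdl)
    outer.vertices = root_surface.vertices + vn * mag[:, None]
    nv = len(root_surface.vertices)
    verts = np.vstack([root_surface.vertices, outer.vertices])
    faces = np.vstack(
        [
            root_surface.faces[:, ::-1],
            outer.faces + nv,
            band_between(loop, loop + nv),
        ]
    )
    shell = make_mesh(verts, faces, name="pdl")
    trimesh.repair.fix_normals(shell)
    if not shell.is_watertight:
        raise GeometryError("PDL shell is not watertight")
    if shell.volume < 0:
        shell.invert()
    return shell


def make_pdl_for(
    support: ToothSupport,
    d_pdl: float = 0.3,
    pitch: float | None = None,
    budget: float = 3.0e6,
) -> trimesh.Trimesh:
    """PDL shell for any abutment tooth.

    Single root: exact offset shell.  Two roots: per-root shells are
    unioned and the tooth solid subtracted (the offset of one root passes
    through the other near the furcation), in a single voxel pass.
    """
    if not support.root_parts:
        return make_pdl(support.root_surface, d_pdl)
    from . import sdf

    shells = [make_pdl(r, d_pdl) for r in support.root_parts]
    pdl = sdf.voxel_combine(
        shells + [support.solid],
        ["union"] * (len(shells) - 1) + ["difference"],
        pitch=pitch,
        budget=budget,
    )
    pdl.metadata["name"] = "pdl"
    return pdl
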