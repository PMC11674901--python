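"""Mesh and curve primitives used by every later modelling stage.

Everything is an indexed triangle mesh in millimetres (``trimesh.Trimesh``
is the carrier), plus light wrappers for ordered 3D polylines, right-handed
orthonormal frames and oriented bounding boxes.  Frames follow the
convention that ``+z`` is the occlusal direction once a restoration is
aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

TOL = 1e-9


class GeometryError(ValueError):
    """Raised when an operation's geometric preconditions are violated."""


# ---------------------------------------------------------------------------
# basic containers
# ---------------------------------------------------------------------------


@dataclass
class Polyline3D:
    """Ordered 3D polyline in mm; ``closed`` means the last point connects
    back to the first (the closing point is *not* duplicated)."""

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GeometryError("polyline points must be (n, 3)")
        if self.closed and len(self.points) < 3:
            raise GeometryError("closed polyline needs at least 3 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def segments(self) -> np.ndarray:
        pts = self.points
        if self.closed:
            return np.roll(pts, -1, axis=0) - pts
        return pts[1:] - pts[:-1]

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.segments, axis=1).sum())

    def resample(self, n: int) -> "Polyline3D":
        """Resample to ``n`` points uniformly by arc length.

        For closed polylines the n samples cover one full cycle without
        duplicating the seam point.
        """
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total <= 0:
            raise GeometryError("cannot resample zero-length polyline")
        if self.closed:
            t = np.linspace(0.0, total, n, endpoint=False)
        else:
            t = np.linspace(0.0, total, n)
        out = np.column_stack([np.interp(t, s, pts[:, k]) for k in range(3)])
        return Polyline3D(out, closed=self.closed)

    def centroid(self, n: int = 256) -> np.ndarray:
        """Vertex-density-independent centre: mean of arc-length resampled
        points."""
        return self.resample(n).points.mean(axis=0)

    def best_fit_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """(origin, unit normal) of the least-squares plane."""
        c = self.points.mean(axis=0)
        _, _, vt = np.linalg.svd(self.points - c, full_matrices=False)
        return c, vt[2]

    def area_perimeter(self, normal: np.ndarray | None = None) -> tuple[float, float]:
        """Enclosed area and perimeter of a closed polyline projected into
        its (or the given) plane; area by the shoelace formula."""
        if not self.closed:
            raise GeometryError("area requires a closed polyline")
        if normal is None:
            _, normal = self.best_fit_plane()
        normal = _unit(normal)
        u, v = _plane_basis(normal)
        c = self.points.mean(axis=0)
        rel = self.points - c
        x, y = rel @ u, rel @ v
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        per = float(
            np.hypot(np.roll(x, -1) - x, np.roll(y, -1) - y).sum()
        )
        return float(area), per

    def transformed(self, matrix: np.ndarray) -> "Polyline3D":
        pts = trimesh.transformations.transform_points(self.points, matrix)
        return Polyline3D(pts, closed=self.closed)


@dataclass
class Frame:
    """Right-handed orthonormal frame: origin + rows (x, y, z) axes."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise GeometryError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise GeometryError("frame must be right-handed")

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.zeros(3), np.eye(3))

    @classmethod
    def from_origin_normal(cls, origin, normal) -> "Frame":
        """Frame whose z-axis is the given normal (used to represent planes)."""
        z = _unit(np.asarray(normal, dtype=float))
        x, y = _plane_basis(z)
        return cls(np.asarray(origin, dtype=float), np.vstack([x, y, z]))

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[2]

    @property
    def normal(self) -> np.ndarray:
        """When the frame represents a plane, its unit normal (= z-axis)."""
        return self.axes[2]

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous transform mapping frame-local to global coords."""
        m = np.eye(4)
        m[:3, :3] = self.axes.T
        m[:3, 3] = self.origin
        return m

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.axes.T


@dataclass
class OrientedBox:
    """Oriented bounding box: frame at the box centre + full extents."""

    frame: Frame
    extents: np.ndarray
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.extents = np.asarray(self.extents, dtype=float).reshape(3)

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))

    def face_centers(self) -> np.ndarray:
        """Centres of the 6 faces, ordered (-x, +x, -y, +y, -z, +z)."""
        out = []
        for ax in range(3):
            for sign in (-1.0, 1.0):
                out.append(
                    self.frame.origin
                    + sign * 0.5 * self.extents[ax] * self.frame.axes[ax]
                )
        return np.array(out)

    def face_normals(self) -> np.ndarray:
        out = []
        for ax in range(3):
            for sign in (-1.0, 1.0):
                out.append(sign * self.frame.axes[ax])
        return np.array(out)

    @staticmethod
    def opposite_face(face_id: int) -> int:
        return face_id ^ 1


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < TOL:
        raise GeometryError("zero-length vector")
    return v / n


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to ``normal``."""
    n = _unit(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(n, a))
    v = np.cross(n, u)
    return u, v


def make_mesh(vertices, faces, name: str = "") -> trimesh.Trimesh:
    """Construct a mesh without silent reprocessing; drops exactly
    degenerate (repeated-index) faces."""
    m = trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )
    f = m.faces
    ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    if not ok.all():
        m.update_faces(ok)
    m.metadata["name"] = name
    return m


def concat_meshes(meshes, name: str = "") -> trimesh.Trimesh:
    m = trimesh.util.concatenate(list(meshes))
    m.metadata["name"] = name
    return m


def vertex_normals_area_weighted(mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-vertex unit normals as area-weighted face-normal averages."""
    fn = mesh.face_normals
    fa = mesh.area_faces
    acc = np.zeros_like(mesh.vertices)
    w = fn * fa[:, None]
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], w)
    norm = np.linalg.norm(acc, axis=1)
    norm[norm < TOL] = 1.0
    return acc / norm[:, None]


def is_watertight(mesh: trimesh.Trimesh) -> bool:
    return bool(mesh.is_watertight)


def ensure_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Flip winding so the (watertight) mesh encloses positive volume."""
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def naked_edge_loops(mesh: trimesh.Trimesh) -> list[Polyline3D]:
    """Chains of boundary (naked) edges as closed polylines.

    Watertight meshes yield an empty list.  Boundary edges that do not
    chain into closed loops indicate non-manifold topology and raise.
    """
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    # adjacency: every boundary vertex must have exactly two boundary edges
    nxt: dict[int, list[int]] = {}
    for a, b in boundary:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    bad = [v for v, ns in nxt.items() if len(ns) != 2]
    if bad:
        raise GeometryError(
            f"boundary edges do not chain into closed loops; offending "
            f"vertices: {sorted(bad)[:10]}"
        )
    loops = []
    unvisited = {tuple(e) for e in boundary.tolist()}
    while unvisited:
        a, b = next(iter(unvisited))
        loop = [a, b]
        unvisited.discard((a, b))
        while True:
            cands = [v for v in nxt[loop[-1]] if v != loop[-2]]
            v = cands[0]
            edge = tuple(sorted((loop[-1], v)))
            if edge not in unvisited:
                # returned to start
                break
            unvisited.discard(edge)
            loop.append(v)
        loops.append(Polyline3D(mesh.vertices[loop], closed=True))
    return loops


def boundary_loop_indices(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Vertex-index loops of every boundary chain (same order convention as
    :func:`naked_edge_loops`)."""
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    nxt: dict[int, list[int]] = {}
    for a, b in boundary:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    if any(len(ns) != 2 for ns in nxt.values()):
        raise GeometryError("non-manifold boundary")
    loops = []
    unvisited = {tuple(e) for e in boundary.tolist()}
    while unvisited:
        a, b = next(iter(unvisited))
        loop = [a, b]
        unvisited.discard((a, b))
        while True:
            v = [u for u in nxt[loop[-1]] if u != loop[-2]][0]
            edge = tuple(sorted((loop[-1], v)))
            if edge not in unvisited:
                break
            unvisited.discard(edge)
            loop.append(v)
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def min_oriented_bounding_box(mesh: trimesh.Trimesh) -> OrientedBox:
    """Minimal-volume oriented bounding box of the mesh vertices.

    The vertex set is first rotated into its principal-axis frame so the
    box search sees numerically identical coordinates regardless of the
    mesh's world pose; the discrete orientation search is then exactly
    pose-invariant (to rounding), which downstream alignment relies on.
    """
    if len(mesh.vertices) == 0:
        raise GeometryError("empty mesh")
    v = np.asarray(mesh.vertices, dtype=float)
    c = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - c, full_matrices=False)
    # canonicalise axis signs by third moments (pose-invariant); the two
    # most skewed axes define their signs, the third follows handedness
    local = (v - c) @ vt.T
    skew = (local**3).sum(axis=0)
    order = np.argsort(-np.abs(skew))
    for ax in order[:2]:
        if skew[ax] < 0:
            vt[ax] = -vt[ax]
    vt[order[2]] = np.cross(vt[(order[2] + 1) % 3], vt[(order[2] + 2) % 3])
    if np.linalg.det(vt) < 0:
        vt[order[2]] = -vt[order[2]]
    local = (v - c) @ vt.T
    # quantise so the discrete orientation search sees bit-identical input
    # in every world pose (rounding noise would otherwise flip near-tied
    # candidate orientations)
    local = np.round(local * 1e8) / 1e8
    try:
        to_local_origin, extents = trimesh.bounds.oriented_bounds(local)
        # compose: world -> pca-local -> box frame
        pca = np.eye(4)
        pca[:3, :3] = vt
        pca[:3, 3] = -vt @ c
        to_origin = to_local_origin @ pca
    except Exception:
        # degenerate / coplanar input: fall back to PCA axes
        v = mesh.vertices - mesh.vertices.mean(axis=0)
        _, _, vt = np.linalg.svd(v, full_matrices=False)
        local = v @ vt.T
        lo, hi = local.min(axis=0), local.max(axis=0)
        extents = hi - lo
        center = mesh.vertices.mean(axis=0) + 0.5 * (lo + hi) @ vt
        axes = vt
        if np.linalg.det(axes) < 0:
            axes = axes * np.array([[1.0], [1.0], [-1.0]])
        return OrientedBox(Frame(center, axes), np.maximum(extents, 0.0),
                           degenerate=bool(np.min(extents) < 1e-6))
    m = np.linalg.inv(to_origin)
    axes = m[:3, :3].T
    if np.linalg.det(axes) < 0:  # keep right-handed
        axes = axes * np.array([[1.0], [1.0], [-1.0]])
    center = m[:3, 3]
    degenerate = bool(np.min(extents) < 1e-6)
    return OrientedBox(Frame(center, axes), extents, degenerate=degenerate)


def _chain_segments(segments: np.ndarray, tol: float) -> list[Polyline3D]:
    """Chain unordered 3D segments (n, 2, 3) into polylines."""
    if len(segments) == 0:
        return []
    pts = segments.reshape(-1, 3)
    # merge endpoints by rounding to tolerance grid
    key = np.round(pts / tol).astype(np.int64)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    uniq_pts: dict[int, np.ndarray] = {}
    for i, idx in enumerate(inv):
        uniq_pts.setdefault(int(idx), pts[i])
    seg_ids = inv.reshape(-1, 2)
    adj: dict[int, list[int]] = {}
    for a, b in seg_ids:
        a, b = int(a), int(b)
        if a == b:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    seen_edges = set()
    polylines = []
    for a, b in seg_ids:
        a, b = int(a), int(b)
        e = (min(a, b), max(a, b))
        if a == b or e in seen_edges:
            continue
        # walk both directions
        chain = [a, b]
        seen_edges.add(e)
        for _ in range(2):
            while True:
                tail, prev = chain[-1], chain[-2]
                nxt_opts = [
                    v
                    for v in adj.get(tail, [])
                    if (min(tail, v), max(tail, v)) not in seen_edges
                ]
                if not nxt_opts:
                    break
                v = nxt_opts[0]
                seen_edges.add((min(tail, v), max(tail, v)))
                chain.append(v)
            chain.reverse()
        closed = False
        if chain[0] == chain[-1] and len(chain) > 3:
            chain = chain[:-1]
            closed = True
        if len(chain) >= 2:
            polylines.append(
                Polyline3D(np.array([uniq_pts[i] for i in chain]), closed=closed)
            )
    return polylines


def section_with_plane(mesh: trimesh.Trimesh, plane: Frame) -> list[Polyline3D]:
    """Intersection polylines of a mesh with a plane (frame origin + z-axis
    normal).  Points are snapped exactly onto the plane."""
    normal = _unit(plane.normal)
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=normal, plane_origin=plane.origin
    )
    if len(segments) == 0:
        return []
    scale = max(mesh.scale, 1.0)
    polys = _chain_segments(np.asarray(segments), tol=1e-7 * scale)
    out = []
    for p in polys:
        d = (p.points - plane.origin) @ normal
        pts = p.points - np.outer(d, normal)  # enforce plane equation exactly
        out.append(Polyline3D(pts, closed=p.closed))
    return out


def offset_along_normals(
    mesh: trimesh.Trimesh, distance: float, direction: str = "outward"
) -> trimesh.Trimesh:
    """Displace every vertex by ``distance`` along its (area-weighted) unit
    normal; connectivity is unchanged."""
    if distance <= 0:
        raise GeometryError("offset distance must be > 0")
    if direction not in ("inward", "outward"):
        raise GeometryError("direction must be 'inward' or 'outward'")
    sign = 1.0 if direction == "outward" else -1.0
    vn = vertex_normals_area_weighted(mesh)
    out = make_mesh(
        mesh.vertices + sign * distance * vn,
        mesh.faces.copy(),
        name=mesh.metadata.get("name", "") + f"_offset{distance:g}",
    )
    return out


def band_between(loop_a: np.ndarray, loop_b: np.ndarray,
                 offset: int = 0) -> np.ndarray:
    """Triangle strip faces connecting two corresponding closed vertex rings.

    ``loop_a``/``loop_b`` are index arrays of equal length referring to a
    shared vertex buffer; quads are split along the shorter diagonal.
    """
    n = len(loop_a)
    if len(loop_b) != n:
        raise GeometryError("rings must have equal point counts")
    faces = []
    for i in range(n):
        j = (i + 1) % n
        a0, a1 = loop_a[i], loop_a[j]
        b0, b1 = loop_b[i], loop_b[j]
        faces.append([a0, a1, b1])
        faces.append([a0, b1, b0])
    return np.array(faces, dtype=np.int64)


def _align_ring(ref: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Cyclic shift (and orientation reversal if needed) of ``ring``
    minimising the sum of squared distances to ``ref``."""
    n = len(ref)
    best = None
    for cand in (ring, ring[::-1]):
        # brute-force over shifts; n is small (<= few hundred)
        diffs = np.empty(n)
        for s in range(n):
            diffs[s] = np.sum((np.roll(cand, -s, axis=0) - ref) ** 2)
        s = int(np.argmin(diffs))
        val = diffs[s]
        if best is None or val < best[0]:
            best = (val, np.roll(cand, -s, axis=0))
    return best[1]


def loft(curve_a: Polyline3D, curve_b: Polyline3D, n: int = 256) -> trimesh.Trimesh:
    """Open triangulated strip interpolating between two closed curves.

    Both curves are resampled to ``n`` points by arc length; the seam is the
    cyclic shift (with optional reversal) minimising summed squared point
    distances; quads split along the shorter diagonal.
    """
    if not (curve_a.closed and curve_b.closed):
        raise GeometryError("loft requires closed curves")
    a = curve_a.resample(n).points
    b = _align_ring(a, curve_b.resample(n).points)
    if np.allclose(a, b, atol=1e-12):
        raise GeometryError("cannot loft a curve onto itself (zero-area strip)")
    verts = np.vstack([a, b])
    faces = []
    for i in range(n):
        j = (i + 1) % n
        a0, a1, b0, b1 = i, j, n + i, n + j
        # split the quad along its shorter diagonal
        if np.linalg.norm(verts[a0] - verts[b1]) <= np.linalg.norm(
            verts[a1] - verts[b0]
        ):
            faces.append([a0, a1, b1])
            faces.append([a0, b1, b0])
        else:
            faces.append([a0, a1, b0])
            faces.append([a1, b1, b0])
    return make_mesh(verts, faces, name="loft")


def loft_rings(rings: list[np.ndarray], cap_start: bool = False,
               cap_end: bool = False, name: str = "loft") -> trimesh.Trimesh:
    """Watertight-by-construction loft through corresponding point rings.

    All rings must have the same point count and consistent ordering; caps
    are centroid fans.
    """
    counts = {len(r) for r in rings}
    if len(counts) != 1:
        raise GeometryError("all rings must share a point count")
    n = counts.pop()
    verts = [np.asarray(r, dtype=float) for r in rings]
    vbuf = np.vstack(verts)
    faces = []
    for k in range(len(rings) - 1):
        ia = np.arange(n) + k * n
        ib = np.arange(n) + (k + 1) * n
        faces.append(band_between(ia, ib))
    faces = list(faces)
    extra_verts = []
    nv = len(vbuf)
    if cap_start:
        c = verts[0].mean(axis=0)
        ci = nv + len(extra_verts)
        extra_verts.append(c)
        ring = np.arange(n)
        cap = np.column_stack(
            [ring, np.full(n, ci), (ring + 1) % n]
        )
        faces.append(cap)
    if cap_end:
        c = verts[-1].mean(axis=0)
        ci = nv + len(extra_verts)
        extra_verts.append(c)
        ring = np.arange(n) + (len(rings) - 1) * n
        base = (len(rings) - 1) * n
        idx = np.arange(n)
        cap = np.column_stack(
            [base + idx, base + (idx + 1) % n, np.full(n, ci)]
        )
        faces.append(cap)
    if extra_verts:
        vbuf = np.vstack([vbuf, np.array(extra_verts)])
    return make_mesh(vbuf, np.vstack(faces), name=name)


def transform_to_frame(
    mesh: trimesh.Trimesh, frame_from: Frame, frame_to: Frame
) -> trimesh.Trimesh:
    """Rigid motion carrying ``frame_from`` onto ``frame_to``."""
    T = frame_to.matrix @ np.linalg.inv(frame_from.matrix)
    out = mesh.copy()
    out.apply_transform(T)
    return out


def frame_transform(frame_from: Frame, frame_to: Frame) -> np.ndarray:
    return frame_to.matrix @ np.linalg.inv(frame_from.matrix)


def mesh_boolean(
    a: trimesh.Trimesh,
    b: trimesh.Trimesh,
    op: str,
    pitch: float | None = None,
    budget: float = 4.0e6,
) -> trimesh.Trimesh:
    """Boolean combination of two watertight meshes.

    Non-intersecting configurations (disjoint or fully nested surfaces) are
    resolved exactly by classification; otherwise a signed-distance voxel
    engine (marching cubes) computes the result at an adaptive pitch.
    """
    from . import sdf  # local import to avoid cycle

    if op not in ("union", "difference", "intersection"):
        raise GeometryError(f"unknown boolean op {op!r}")
    for name, m in (("a", a), ("b", b)):
        if not m.is_watertight:
            raise GeometryError(f"boolean input {name} is not watertight")
    a = ensure_outward(a.copy())
    b = ensure_outward(b.copy())

    if not sdf.surfaces_may_intersect(a, b):
        a_in_b = sdf.contains(b, a.vertices[:1])[0]
        b_in_a = sdf.contains(a, b.vertices[:1])[0]
        if op == "union":
            if a_in_b:
                return b
            if b_in_a:
                return a
            return concat_meshes([a, b], name="union")
        if op == "difference":
            if b_in_a:
                bb = b.copy()
                bb.invert()
                return concat_meshes([a, bb], name="difference")
            if a_in_b:
                return make_mesh(np.zeros((0, 3)), np.zeros((0, 3)), "empty")
            return a
        # intersection
        if a_in_b:
            return a
        if b_in_a:
            return b
        return make_mesh(np.zeros((0, 3)), np.zeros((0, 3)), "empty")

    return sdf.voxel_boolean(a, b, op, pitch=pitch, budget=budget)


def mesh_union_many(meshes, pitch=None, budget=6.0e6) -> trimesh.Trimesh:
    """Union of several watertight meshes via the signed-distance engine."""
    from . import sdf

    meshes = [ensure_outward(m.copy()) for m in meshes]
    return sdf.voxel_combine(meshes, ["union"] * (len(meshes) - 1),
                             pitch=pitch, budget=budget)
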