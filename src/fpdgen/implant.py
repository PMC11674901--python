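"""Implant-type support generation: abutment, implant body, thread, screw.

The abutment is a loft from the cement layer's interior margin through
three circles (neck, taper, post) with a stepped internal borehole; it is
built as one ring-welded tube so the bore needs no Boolean.  The implant
body is a solid of revolution (chamfered neck, filleted apex, stepped
internal bore) whose outer wall carries an ISO-metric V thread realised as
an exact helical radial displacement.  The abutment screw is a plain
turned part (cylindrical head + shaft) sized to the bores.

Axial datum: depths are measured downward from the plane of the interior
margin's lowest point (the cement/abutment margin level); the implant neck
plane sits ``l_a1`` below that datum.  The printed bore depths are treated
as cumulative below the neck plane; the d-2.6 bore section is deepened
when necessary so the abutment post seats fully (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import (
    Frame,
    GeometryError,
    Polyline3D,
    band_between,
    make_mesh,
    section_with_plane,
)
from .tooth import CementLayer


@dataclass
class ImplantParams:
    """All user parameters of the implant-type support (mm)."""

    d_cement: float = 0.1
    # abutment: circle depths below the margin datum and diameters
    l_a1: float = 1.0
    l_a2: float = 1.5
    l_a3: float = 7.0
    d_a1: float = 3.0
    d_a2: float = 2.6
    d_a3: float = 2.6
    # abutment borehole
    l_ba1: float = 2.0
    l_ba2: float = 2.2
    d_ba1: float = 1.6
    d_ba2: float = 1.3
    # implant body
    d_i1: float = 5.0
    d_i2: float = 5.0
    l_i1: float = 8.0
    r_c: float = 1.5  # neck chamfer
    r_f: float = 0.2  # apex fillet
    # implant borehole (cumulative depths below the neck plane)
    l_bi1: float = 0.5
    l_bi2: float = 4.0
    l_bi3: float = 5.0
    l_bi4: float = 5.3
    d_bi1: float = 3.0  # = d_a1
    d_bi2: float = 2.6  # = d_a3
    d_bi3: float = 1.1
    r_b: float = 0.2  # blend radius at internal bore steps
    # thread
    l_t: float = 1.5  # helix start below the neck plane
    p_t: float = 0.5  # pitch
    n_turns: int = 10
    # screw
    l_s: float = 4.5

    def __post_init__(self) -> None:
        positive = [
            "d_cement", "l_a1", "l_a2", "l_a3", "d_a1", "d_a2", "d_a3",
            "l_ba1", "l_ba2", "d_ba1", "d_ba2", "d_i1", "d_i2", "l_i1",
            "r_c", "r_f", "l_bi1", "l_bi2", "l_bi3", "l_bi4", "d_bi1",
            "d_bi2", "d_bi3", "l_t", "p_t", "l_s",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")
        if abs(self.d_i1 - self.d_i2) > 1e-12:
            raise ValueError("straight implant requires d_i1 == d_i2")
        if abs(self.d_bi1 - self.d_a1) > 1e-12:
            raise ValueError("d_bi1 must equal d_a1")
        if abs(self.d_bi2 - self.d_a3) > 1e-12:
            raise ValueError("d_bi2 must equal d_a3")

    # derived datum chain -------------------------------------------------
    @property
    def post_depth_below_neck(self) -> float:
        """How far the abutment post reaches below the neck plane."""
        return self.l_a3 - self.l_a1

    @property
    def bore26_depth(self) -> float:
        """Depth (below neck) of the d_bi2 bore bottom; deepened to seat
        the abutment post when the printed value is too shallow."""
        return max(self.l_bi2, self.post_depth_below_neck)

    @property
    def bore_cone_depth(self) -> float:
        return self.bore26_depth + (self.l_bi3 - self.l_bi2)

    @property
    def bore_end_depth(self) -> float:
        return self.bore26_depth + (self.l_bi4 - self.l_bi2)

    @property
    def thread_depth(self) -> float:
        """Radial thread depth for an ISO-metric external profile."""
        return 0.61343 * self.p_t


# ---------------------------------------------------------------------------
# abutment
# ---------------------------------------------------------------------------


def _matched_circle(loop_pts: np.ndarray, centre_xy: np.ndarray,
                    radius: float, z: float) -> np.ndarray:
    """Circle ring whose points sit at the same polar angles as the margin
    loop points, so ring bands never twist."""
    rel = loop_pts[:, :2] - centre_xy
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    return np.column_stack(
        [
            centre_xy[0] + radius * np.cos(theta),
            centre_xy[1] + radius * np.sin(theta),
            np.full(len(loop_pts), z),
        ]
    )


def make_abutment(cement: CementLayer, p: ImplantParams) -> trimesh.Trimesh:
    """Watertight abutment: interior cup + loft through the three abutment
    circles + stepped blind borehole ending at the margin datum plane."""
    if p.d_ba1 >= p.d_a2 or p.d_ba2 >= p.d_a3:
        raise GeometryError("borehole wider than the local abutment section")
    loop = cement.interior_loop
    interior = cement.interior
    loop_pts = interior.vertices[loop]
    centre = Polyline3D(loop_pts, closed=True).centroid()[:2]
    z0 = float(loop_pts[:, 2].min())  # margin datum

    n = len(loop)
    ring = lambda r, z: _matched_circle(loop_pts, centre, r, z)
    # outer profile downward, then bore upward; all rings share the angular
    # parameterisation of the margin loop
    rings = [
        ring(p.d_a1 / 2, z0 - p.l_a1),
        ring(p.d_a2 / 2, z0 - p.l_a2),
        ring(p.d_a3 / 2, z0 - p.l_a3),
        ring(p.d_ba2 / 2, z0 - p.l_a3),  # bottom annulus inner edge
        ring(p.d_ba2 / 2, z0 - p.l_ba1),  # lower bore up to the step
        ring(p.d_ba1 / 2, z0 - p.l_ba1),  # step annulus
        ring(p.d_ba1 / 2, z0),  # upper bore up to the datum
    ]
    verts = [interior.vertices]
    faces = [interior.faces]
    prev = loop
    base = len(interior.vertices)
    for r in rings:
        verts.append(r)
        idx = np.arange(n) + base
        faces.append(band_between(prev, idx))
        prev = idx
        base += n
    # close the bore with a disk at the datum plane
    verts.append(np.array([[centre[0], centre[1], z0]]))
    k = np.arange(n)
    faces.append(np.column_stack([prev[k], prev[(k + 1) % n], np.full(n, base)]))
    solid = make_mesh(np.vstack(verts), np.vstack(faces), name="abutment")
    trimesh.repair.fix_normals(solid)
    if not solid.is_watertight:
        raise GeometryError("abutment is not watertight")
    if solid.volume < 0:
        solid.invert()
    return solid


# ---------------------------------------------------------------------------
# implant body (lathe profile + helical thread displacement)
# ---------------------------------------------------------------------------


def _implant_profile(p: ImplantParams, dz_thread: float) -> np.ndarray:
    """Closed (r, z) lathe profile of the implant body, z = 0 at the neck
    plane, z negative downward.  The wall section overlapping the thread
    span is sampled at ``dz_thread`` so the displacement is well resolved.
    """
    R = p.d_i1 / 2
    if p.r_c + p.r_f >= p.l_i1:
        raise GeometryError("chamfer and fillet exceed the implant length")
    # neck chamfer: internal 45-degree funnel from the platform edge down
    # toward the bore (keeps the platform at full diameter at the neck)
    funnel = min(p.r_c, R - p.d_bi2 / 2)
    if funnel <= 0:
        raise GeometryError("bore diameter exceeds the implant diameter")

    prof: list[tuple[float, float]] = []
    prof.append((0.0, -p.l_i1))  # apex pole
    # apex fillet: quarter arc from the bottom face to the wall
    fc = (R - p.r_f, -(p.l_i1 - p.r_f))
    prof.append((fc[0], -p.l_i1))
    for a in np.linspace(-np.pi / 2, 0.0, 8)[1:]:
        prof.append((fc[0] + p.r_f * np.cos(a), fc[1] + p.r_f * np.sin(a)))
    # outer wall up to the platform, densely sampled across the thread span
    z_wall_lo, z_wall_hi = -(p.l_i1 - p.r_f), 0.0
    t_lo = -(p.l_t + p.n_turns * p.p_t)  # thread bottom
    t_hi = -p.l_t
    zs = [z_wall_lo]
    z = z_wall_lo
    while z < z_wall_hi - 1e-9:
        step = dz_thread if (t_lo - 0.6 < z < t_hi + 0.6) else 0.25
        z = min(z + step, z_wall_hi)
        zs.append(z)
    prof.extend((R, z) for z in zs)
    # funnel cone inward-downward at 45 degrees
    prof.append((R - funnel, -funnel))
    if R - funnel > p.d_bi1 / 2 + 1e-9:
        # platform annulus down to the upper bore, then the d_bi1 section
        prof.append((p.d_bi1 / 2, -funnel))
        prof.append((p.d_bi1 / 2, -max(p.l_bi1, funnel)))
        prof.append((p.d_bi2 / 2, -max(p.l_bi1, funnel)))
    prof.append((p.d_bi2 / 2, -p.bore26_depth))
    prof.append((p.d_bi3 / 2, -p.bore_cone_depth))
    prof.append((p.d_bi3 / 2, -p.bore_end_depth))
    prof.append((0.0, -p.bore_end_depth))  # bore end pole
    return np.array(prof)


def _thread_depth_fraction(u: np.ndarray, p: ImplantParams) -> np.ndarray:
    """Axial thread profile over one pitch: 0 at the crest flat, 1 at the
    root flat, 60-degree flanks (ISO-metric external form)."""
    u = np.mod(u + 0.5, 1.0) - 0.5  # crest centred at u = 0
    au = np.abs(u)
    crest = 1.0 / 16.0  # crest half-width (p/8 flat)
    flank = p.thread_depth * np.tan(np.pi / 6) / p.p_t  # axial flank width
    g = (au - crest) / flank
    return np.clip(g, 0.0, 1.0)


def make_implant_body(p: ImplantParams, z_neck: float = 0.0,
                      n_theta: int = 128, threaded: bool = True) -> trimesh.Trimesh:
    """Watertight implant body with (optionally) the thread applied.

    ``z_neck`` places the neck plane in world coordinates.  The thread is
    an exact radial displacement of the outer wall: depth follows the ISO
    V profile in the helical phase u = z/p + theta/2pi, fading over half a
    turn at both ends (the milling tool's tangential run-in/run-out).
    """
    span = p.l_t + p.n_turns * p.p_t
    if span > p.l_i1 - p.r_f:
        raise GeometryError("thread span exceeds the implant length")
    prof = _implant_profile(p, dz_thread=p.p_t / 24.0)
    m = len(prof)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    R = p.d_i1 / 2

    # rows x theta grid
    rr = np.repeat(prof[:, 0][:, None], n_theta, axis=1)
    zz = np.repeat(prof[:, 1][:, None], n_theta, axis=1)
    tt = np.repeat(theta[None, :], m, axis=0)
    if threaded:
        on_wall = np.isclose(prof[:, 0], R)
        z_start = -p.l_t  # thread top (below neck)
        u = zz / p.p_t + tt / (2 * np.pi)
        u0 = z_start / p.p_t
        g = _thread_depth_fraction(u - u0, p)
        # fade over the first/last half turn of the helical coordinate
        h = (z_start - zz) / p.p_t  # turns below thread start at theta=0
        h = h - tt / (2 * np.pi)
        fade = np.clip(2.0 * h, 0.0, 1.0) * np.clip(
            2.0 * (p.n_turns - h), 0.0, 1.0
        )
        rr = rr - np.where(on_wall[:, None], p.thread_depth * g * fade, 0.0)

    xx = rr * np.cos(tt)
    yy = rr * np.sin(tt)
    zz = zz + z_neck

    # assemble: pole rows (r == 0) collapse to single vertices
    pole = np.isclose(prof[:, 0], 0.0)
    verts = []
    row_start = np.empty(m, dtype=np.int64)
    for i in range(m):
        row_start[i] = len(verts)
        if pole[i]:
            verts.append([0.0, 0.0, prof[i, 1] + z_neck])
        else:
            verts.extend(np.column_stack([xx[i], yy[i], zz[i]]))
    verts = np.array(verts)
    faces = []
    k = np.arange(n_theta)
    for i in range(m - 1):
        a, b = row_start[i], row_start[i + 1]
        if pole[i] and not pole[i + 1]:
            faces.append(np.column_stack([np.full(n_theta, a), b + (k + 1) % n_theta, b + k]))
        elif pole[i + 1] and not pole[i]:
            faces.append(np.column_stack([a + k, a + (k + 1) % n_theta, np.full(n_theta, b)]))
        elif not pole[i] and not pole[i + 1]:
            faces.append(band_between(a + k, b + k))
    # close the revolve: last ring (bore end pole) connects back to first
    # (apex pole) through the bore end cap already handled by profile order
    solid = make_mesh(verts, np.vstack(faces), name="implant")
    trimesh.repair.fix_normals(solid)
    if not solid.is_watertight:
        raise GeometryError("implant body is not watertight")
    if solid.volume < 0:
        solid.invert()
    return solid


def make_thread_cutter(p: ImplantParams, z_neck: float = 0.0,
                       samples_per_turn: int = 96) -> trimesh.Trimesh:
    """Swept thread-cutting solid: the ISO V groove profile swept along the
    helix (with tangential half-turn extensions), as a watertight tube.

    Subtracting this from the unthreaded body is the Boolean route to the
    same thread the displacement construction produces.
    """
    depth = p.thread_depth
    half_w = depth * np.tan(np.pi / 6) + p.p_t / 16.0
    n = int(samples_per_turn * (p.n_turns + 1))
    t = np.linspace(-0.5, p.n_turns + 0.5, n)  # turns, incl. extensions
    theta = 2 * np.pi * t
    z = z_neck - p.l_t - p.p_t * t
    R = p.d_i1 / 2
    rings = []
    for th, zz in zip(theta, z):
        c, s = np.cos(th), np.sin(th)
        # triangular groove cross-section in the (radial, axial) plane
        sec = np.array(
            [
                [R + 0.2, zz - half_w],
                [R + 0.2, zz + half_w],
                [R - depth, zz + p.p_t / 32],
                [R - depth, zz - p.p_t / 32],
            ]
        )
        rings.append(
            np.column_stack([sec[:, 0] * c, sec[:, 0] * s, sec[:, 1]])
        )
    nv = 4
    verts = np.vstack(rings)
    faces = []
    for i in range(n - 1):
        faces.append(band_between(np.arange(nv) + i * nv, np.arange(nv) + (i + 1) * nv))
    faces.append(np.array([[0, 2, 1], [0, 3, 2]]))
    last = (n - 1) * nv
    faces.append(np.array([[last, last + 1, last + 2], [last, last + 2, last + 3]]))
    cutter = make_mesh(verts, np.vstack(faces), name="thread_cutter")
    trimesh.repair.fix_normals(cutter)
    if cutter.volume < 0:
        cutter.invert()
    return cutter


# ---------------------------------------------------------------------------
# abutment screw
# ---------------------------------------------------------------------------


def make_screw(p: ImplantParams, z_datum: float = 0.0,
               centre_xy=(0.0, 0.0), n_theta: int = 96) -> trimesh.Trimesh:
    """Turned abutment screw: cylindrical head filling the upper abutment
    bore seat, shaft of the tip-channel diameter extending ``l_s`` below
    the head seat."""
    z_seat = z_datum - p.l_ba1  # step plane of the abutment bore
    z_tip = z_seat - p.l_s
    if p.l_ba1 + p.l_s > p.l_a3 + (p.l_bi4 - p.l_bi2):
        raise GeometryError("screw longer than the available bore depth")
    r_head = p.d_ba1 / 2
    r_shaft = p.d_bi3 / 2
    prof = np.array(
        [
            (0.0, z_datum),
            (r_head, z_datum),
            (r_head, z_seat),
            (r_shaft, z_seat),
            (r_shaft, z_tip),
            (0.0, z_tip),
        ]
    )
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    verts = []
    row_start = []
    pole = np.isclose(prof[:, 0], 0.0)
    for i, (r, z) in enumerate(prof):
        row_start.append(len(verts))
        if pole[i]:
            verts.append([centre_xy[0], centre_xy[1], z])
        else:
            verts.extend(
                np.column_stack(
                    [
                        centre_xy[0] + r * np.cos(theta),
                        centre_xy[1] + r * np.sin(theta),
                        np.full(n_theta, z),
                    ]
                )
            )
    verts = np.array(verts)
    faces = []
    k = np.arange(n_theta)
    for i in range(len(prof) - 1):
        a, b = row_start[i], row_start[i + 1]
        if pole[i]:
            faces.append(np.column_stack([np.full(n_theta, a), b + (k + 1) % n_theta, b + k]))
        elif pole[i + 1]:
            faces.append(np.column_stack([a + k, a + (k + 1) % n_theta, np.full(n_theta, b)]))
        else:
            faces.append(band_between(a + k, b + k))
    screw = make_mesh(verts, np.vstack(faces), name="screw")
    trimesh.repair.fix_normals(screw)
    if not screw.is_watertight:
        raise GeometryError("screw is not watertight")
    if screw.volume < 0:
        screw.invert()
    return screw


# ---------------------------------------------------------------------------
# measurements used by tests and the acceptance script
# ---------------------------------------------------------------------------


def neck_section_diameter(implant: trimesh.Trimesh, z_neck: float,
                          probe_dz: float = 0.05) -> float:
    """Outer diameter at (just below) the neck plane: twice the maximum
    centroid distance of the outermost section curve."""
    plane = Frame.from_origin_normal([0, 0, z_neck - probe_dz], [0, 0, 1])
    curves = [c for c in section_with_plane(implant, plane) if c.closed]
    if not curves:
        raise GeometryError("no section at the neck plane")
    outer = max(curves, key=lambda c: c.area_perimeter([0, 0, 1])[0])
    pts = outer.resample(512).points
    c = pts.mean(axis=0)
    return 2.0 * float(np.linalg.norm(pts[:, :2] - c[:2], axis=1).max())


def fit_thread_pitch(implant: trimesh.Trimesh, p: ImplantParams,
                     z_neck: float = 0.0) -> float:
    """Axial advance per revolution fitted to thread-root vertices.

    Vertices in the root-radius band are unwrapped to (turn count, z) and a
    line is fitted; the slope magnitude is the realised pitch.
    """
    v = implant.vertices
    r = np.linalg.norm(v[:, :2], axis=1)
    R = p.d_i1 / 2
    band = (r < R - 0.97 * p.thread_depth) & (r > R - 1.03 * p.thread_depth)
    z_lo = z_neck - p.l_t - p.n_turns * p.p_t + p.p_t
    z_hi = z_neck - p.l_t - p.p_t
    band &= (v[:, 2] > z_lo) & (v[:, 2] < z_hi)
    if band.sum() < 20:
        raise GeometryError("too few thread-root vertices to fit a pitch")
    vv = v[band]
    theta = np.arctan2(vv[:, 1], vv[:, 0]) / (2 * np.pi)  # fractional turn
    # unwrap to a continuous turn coordinate; the nominal pitch only seeds
    # the integer turn index (root centre phase is half a turn off the
    # thread start, hence the 0.5)
    turn = (z_neck - p.l_t - vv[:, 2]) / p.p_t - 0.5
    k = np.round(turn - theta)
    x = theta + k
    A = np.column_stack([x, np.ones_like(x)])
    slope, _ = np.linalg.lstsq(A, vv[:, 2], rcond=None)[0]
    return float(abs(slope))
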