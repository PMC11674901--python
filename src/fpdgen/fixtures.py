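"""Deterministic synthetic stand-ins for the scanned master geometry.

Real inputs to this pipeline are optical scans of a 4-unit bridge and a
mandible; none ship with the package, so these generators emulate them:

* a tooth-variant bridge whose lumen cross-sections are lobed (circularity
  index near 0.92, like a prepared natural tooth) and an implant-variant
  with near-circular lumens (CI around 0.997, like machined abutments);
* a parametric mandibular segment with a crestal ridge, an arch-curved
  centre curve and quality-dependent cortical/transition layering.

Every fixture is generated with fixed-order floating point arithmetic from
a single seeded generator, so equal seeds give byte-identical meshes; the
construction ground truth (margin centres, gingival normal, pose) is
recorded for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .alignment import FpdModel
from .bone import BoneSegment
from .geometry import Frame, Polyline3D, band_between, make_mesh
from .materials import BoneQualitySpec, bone_quality


@dataclass
class FixtureSpec:
    """Configuration of a synthetic bridge fixture."""

    support_type: str = "tooth"  # 'tooth' | 'implant'
    seed: int = 0
    lumen_span: float = 30.0  # distal-to-mesial margin centre distance, mm
    lumen_depth: float = 4.0
    noise_amplitude: float = 0.009  # machined-surface ripple (implant type)
    n_theta: int = 128
    n_rings: int = 16

    def __post_init__(self) -> None:
        if self.support_type not in ("tooth", "implant"):
            raise ValueError("support_type must be 'tooth' or 'implant'")

    @property
    def expected_ci_band(self) -> tuple[float, float]:
        return (0.99, 1.0) if self.support_type == "implant" else (0.88, 0.95)


# lobed cross-section amplitudes for the tooth variant, chosen once so the
# circularity index lands in the natural-tooth regime (~0.92) and frozen
_TOOTH_LOBES = ((2, 0.16), (3, 0.055), (4, 0.07))


def _lumen_radius(theta: np.ndarray, r0: float, support_type: str,
                  ripple: float, rng: np.random.Generator) -> np.ndarray:
    if support_type == "implant":
        phase = rng.uniform(0, 2 * np.pi)
        return r0 * (1.0 + ripple * np.cos(8 * theta + phase))
    r = np.ones_like(theta)
    for k, a in _TOOTH_LOBES:
        r = r + a * np.cos(k * theta + rng.uniform(-0.3, 0.3))
    return r0 * r


def _lumen_cup(centre, r0, spec: FixtureSpec, rng) -> trimesh.Trimesh:
    """Open lumen surface: margin ring at the bottom, tapering rings going
    occlusally, closed by a dome cap at the top.  Boundary = margin."""
    nt, nr = spec.n_theta, spec.n_rings
    theta = np.linspace(0, 2 * np.pi, nt, endpoint=False)
    base_r = _lumen_radius(theta, r0, spec.support_type, spec.noise_amplitude, rng)
    margin_wiggle = (
        0.25 * np.sin(2 * theta + rng.uniform(0, 2 * np.pi))
        if spec.support_type == "tooth"
        else 0.05 * np.sin(2 * theta)
    )
    s = np.linspace(0.0, 1.0, nr)
    taper = 1.0 - 0.45 * s  # occlusal convergence of the preparation
    rings = []
    for j in range(nr):
        z = margin_wiggle * (1.0 - s[j]) + spec.lumen_depth * s[j]
        rings.append(
            np.column_stack(
                [
                    centre[0] + base_r * taper[j] * np.cos(theta),
                    centre[1] + base_r * taper[j] * np.sin(theta),
                    centre[2] + z,
                ]
            )
        )
    verts = np.vstack(rings)
    faces = []
    for j in range(nr - 1):
        faces.append(band_between(np.arange(nt) + j * nt,
                                  np.arange(nt) + (j + 1) * nt))
    # dome cap on the last ring
    cap_c = rings[-1].mean(axis=0) + np.array([0, 0, 0.2 * r0])
    verts = np.vstack([verts, cap_c[None, :]])
    top = (nr - 1) * nt
    k = np.arange(nt)
    faces.append(np.column_stack([top + k, top + (k + 1) % nt,
                                  np.full(nt, nr * nt)]))
    return make_mesh(verts, np.vstack(faces), name="lumen")


def _bridge_hull(span: float, rng) -> trimesh.Trimesh:
    """Smooth external 4-unit bridge surface: an elongated superellipsoid
    with a waist at the middle connector."""
    nu, nv = 96, 48
    u = np.linspace(-np.pi / 2, np.pi / 2, nv)  # polar (z)
    v = np.linspace(0, 2 * np.pi, nu, endpoint=False)
    uu, vv = np.meshgrid(u, v, indexing="ij")

    def spow(x, e):
        return np.sign(x) * np.abs(x) ** e

    ex, ez = 0.4, 0.5  # squareness of the outline / vertical flatness
    cx = span / 2.0
    ax_, ay, az = span / 2.0 + 7.0, 5.5, 5.0
    xs = cx + ax_ * spow(np.cos(vv), ex)
    waist = 1.0 - 0.22 * np.exp(-((xs - cx) ** 2) / (2 * 2.5**2))
    y = ay * waist * spow(np.sin(vv), ex) * np.cos(uu)
    z = 4.2 + az * spow(np.sin(uu), ez)
    verts = np.column_stack([xs.ravel(), y.ravel(), z.ravel()])
    faces = []
    for i in range(nv - 1):
        a = np.arange(nu) + i * nu
        b = np.arange(nu) + (i + 1) * nu
        faces.append(band_between(a, b))
    hull = make_mesh(verts, np.vstack(faces), name="surface")
    return hull


def make_fpd_fixture(spec: FixtureSpec) -> tuple[FpdModel, dict]:
    """Labeled three-part bridge fixture in a random rigid pose.

    Returns (model, ground_truth): the truth dict records the pre-pose
    margin centres, the posed gingival outward normal, the pose matrix and
    the expected circularity band.
    """
    rng = np.random.default_rng(spec.seed)
    span = spec.lumen_span
    if spec.support_type == "tooth":
        r_mesial, r_distal = 3.0, 4.6  # premolar / molar preparations
    else:
        r_mesial = r_distal = 2.2  # machined abutment copings
    distal = _lumen_cup(np.zeros(3), r_distal, spec, rng)
    distal.metadata["name"] = "distal"
    mesial = _lumen_cup(np.array([span, 0.0, 0.0]), r_mesial, spec, rng)
    mesial.metadata["name"] = "mesial"
    surface = _bridge_hull(span, rng)

    # record exact pre-pose landmarks from the construction
    from .alignment import margin_curve

    p_distal = margin_curve(distal).centroid()
    p_mesial = margin_curve(mesial).centroid()

    # random rigid pose
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    T = trimesh.transformations.quaternion_matrix(q)
    T[:3, 3] = rng.uniform(-25.0, 25.0, 3)
    model = FpdModel(surface, distal, mesial).transformed(T)
    truth = {
        "p_distal_prepose": p_distal,
        "p_mesial_prepose": p_mesial,
        "pose": T,
        "p_distal": trimesh.transformations.transform_points([p_distal], T)[0],
        "p_mesial": trimesh.transformations.transform_points([p_mesial], T)[0],
        "gingival_normal": T[:3, :3] @ np.array([0.0, 0.0, -1.0]),
        "expected_ci_band": spec.expected_ci_band,
        "support_type": spec.support_type,
    }
    return model, truth


# ---------------------------------------------------------------------------
# bone fixture
# ---------------------------------------------------------------------------

_ARCH_RADIUS = 200.0  # dental-arch curvature of the ridge, mm
_CREST_RADIUS = 10.0  # buccal-oral convexity of the ridge crest, mm
_CREST_HALF = 5.0  # half-width of the convex crest, mm
_BASE_HALF = 8.0  # half-width at the segment base, mm
_HEIGHT = 24.0  # crest-to-base height, mm


def _arch_y(x: np.ndarray) -> np.ndarray:
    return _ARCH_RADIUS - np.sqrt(_ARCH_RADIUS**2 - np.asarray(x, float) ** 2)


def _crest_profile_z(y_local: np.ndarray) -> np.ndarray:
    """Upper surface height vs. buccal-oral offset from the ridge line."""
    y = np.asarray(y_local, dtype=float)
    ay = np.abs(y)
    z_crest = -(y**2) / (2 * _CREST_RADIUS)
    z_edge = -(_CREST_HALF**2) / (2 * _CREST_RADIUS)
    slope = (-_HEIGHT * 0.45 - z_edge) / (_BASE_HALF - _CREST_HALF)
    z_side = z_edge + (ay - _CREST_HALF) * slope
    return np.where(ay <= _CREST_HALF, z_crest, z_side)


def _bone_profile(n_side: int = 26) -> np.ndarray:
    """Closed (y, z) cross-section polygon of the segment (local ridge
    coordinates, crest at z = 0)."""
    y_top = np.linspace(-_CREST_HALF, _CREST_HALF, 41)
    top = np.column_stack([y_top, _crest_profile_z(y_top)])
    y_sh = np.linspace(_CREST_HALF, _BASE_HALF, 8)[1:]
    right_sh = np.column_stack([y_sh, _crest_profile_z(y_sh)])
    z_side = np.linspace(_crest_profile_z(np.array([_BASE_HALF]))[0], -_HEIGHT, n_side)[1:]
    right = np.column_stack([np.full(n_side - 1, _BASE_HALF), z_side])
    bottom = np.column_stack(
        [np.linspace(_BASE_HALF, -_BASE_HALF, 17)[1:], np.full(16, -_HEIGHT)]
    )
    left = np.column_stack(
        [np.full(n_side - 1, -_BASE_HALF), z_side[::-1]]
    )
    left_sh = np.column_stack([-y_sh[::-1], _crest_profile_z(y_sh)[::-1]])
    poly = np.vstack([top, right_sh, right, bottom, left, left_sh])
    # drop the duplicated closing point
    return poly[:-1]


def _inset_profile(prof: np.ndarray, dist: float, n_out: int = 300) -> np.ndarray:
    """Inward offset of the closed (y, z) profile polygon by ``dist``,
    resampled to ``n_out`` points by arc length."""
    from shapely.geometry import Polygon

    poly = Polygon(prof).buffer(-dist, join_style=1, quad_segs=24)
    if poly.is_empty:
        raise ValueError(f"profile vanishes at inset {dist}")
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    xy = np.asarray(poly.exterior.coords)[:-1]
    ring = Polyline3D(
        np.column_stack([xy[:, 0], xy[:, 1], np.zeros(len(xy))]), closed=True
    ).resample(n_out)
    return ring.points[:, :2]


def _extrude_profile(prof2d: np.ndarray, xs: np.ndarray, name: str) -> trimesh.Trimesh:
    """Extrude a closed (y, z) profile along x following the arch curve,
    with flat end caps."""
    n = len(prof2d)
    rings = []
    for xv in xs:
        yc = _arch_y(np.array([xv]))[0]
        rings.append(
            np.column_stack([np.full(n, xv), prof2d[:, 0] + yc, prof2d[:, 1]])
        )
    verts = np.vstack(rings)
    faces = []
    for j in range(len(xs) - 1):
        faces.append(band_between(np.arange(n) + j * n, np.arange(n) + (j + 1) * n))
    verts = np.vstack([verts, rings[0].mean(axis=0)[None, :],
                       rings[-1].mean(axis=0)[None, :]])
    c0, c1 = len(verts) - 2, len(verts) - 1
    k = np.arange(n)
    faces.append(np.column_stack([k, np.full(n, c0), (k + 1) % n]))
    last = (len(xs) - 1) * n
    faces.append(np.column_stack([last + k, last + (k + 1) % n, np.full(n, c1)]))
    m = make_mesh(verts, np.vstack(faces), name=name)
    trimesh.repair.fix_normals(m)
    if m.volume < 0:
        m.invert()
    return m


def make_bone_fixture(
    quality: str | BoneQualitySpec = "D1",
    seed: int = 0,
    length: float = 40.0,
    fine_band: tuple[float, float] = (8.0, 22.0),
) -> BoneSegment:
    """Parametric mandibular segment for the given Misch quality.

    Extruded rounded-trapezoid cross-section along an arch-curved centre
    line; mesh is refined over the mesiodistal bands where defects are
    carved.  Layer interfaces are inward normal offsets of the outer
    surface at the cortical thickness and 0.29 mm beyond.
    """
    spec = quality if isinstance(quality, BoneQualitySpec) else bone_quality(quality)
    half = length / 2.0
    xs = [-half]
    x = -half
    while x < half - 1e-9:
        ax = abs(x + 0.05)
        step = 0.1 if fine_band[0] - 1 < ax < fine_band[1] + 1 else 0.5
        x = min(x + step, half)
        xs.append(x)
    xs = np.array(xs)
    prof = _bone_profile()
    n = len(prof)
    rings = []
    for xv in xs:
        yc = _arch_y(np.array([xv]))[0]
        rings.append(
            np.column_stack(
                [np.full(n, xv), prof[:, 0] + yc, prof[:, 1]]
            )
        )
    verts = np.vstack(rings)
    faces = []
    for j in range(len(xs) - 1):
        faces.append(band_between(np.arange(n) + j * n, np.arange(n) + (j + 1) * n))
    # end caps (centroid fans)
    verts = np.vstack([verts, rings[0].mean(axis=0)[None, :],
                       rings[-1].mean(axis=0)[None, :]])
    c0 = len(verts) - 2
    c1 = len(verts) - 1
    k = np.arange(n)
    faces.append(np.column_stack([k, np.full(n, c0), (k + 1) % n]))
    last = (len(xs) - 1) * n
    faces.append(np.column_stack([last + k, last + (k + 1) % n, np.full(n, c1)]))
    outer = make_mesh(verts, np.vstack(faces), name="bone")
    trimesh.repair.fix_normals(outer)
    if outer.volume < 0:
        outer.invert()

    # layer interfaces: exact 2D inward offsets of the cross-section
    # profile (constant wall thickness, no corner folds), extruded the
    # same way; the segment's cut ends stay flat
    iface1 = _extrude_profile(
        _inset_profile(prof, spec.cortical_thickness), xs,
        "interface_cortical",
    )
    iface2 = _extrude_profile(
        _inset_profile(prof, spec.cortical_thickness + spec.transition_thickness),
        xs,
        "interface_cancellous",
    )

    cx = np.linspace(-half, half, 81)
    centre = Polyline3D(
        np.column_stack([cx, _arch_y(cx), np.zeros_like(cx)]), closed=False
    )

    def crest(x, y):
        yl = np.asarray(y, dtype=float) - _arch_y(x)
        return np.atleast_1d(_crest_profile_z(yl))

    return BoneSegment(
        outer=outer,
        interface_cortical=iface1,
        interface_cancellous=iface2,
        centre_curve=centre,
        quality=spec,
        frame=Frame.identity(),
        crest_height=crest,
    )
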