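"""Geometry kernel: boundary loops, bounding boxes, sections, offsets,
lofts, rigid transforms."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from fpdgen import geometry as G


def lat_long_hemisphere(radius=2.0, n_theta=96, n_phi=24):
    """Open hemisphere with an exactly circular equator boundary."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    phi = np.linspace(0, np.pi / 2 - 1e-9, n_phi)
    rings = [
        np.column_stack(
            [
                radius * np.cos(p) * np.cos(theta),
                radius * np.cos(p) * np.sin(theta),
                radius * np.sin(p) * np.ones(n_theta),
            ]
        )
        for p in phi
    ]
    verts = np.vstack(rings + [np.array([[0, 0, radius]])])
    faces = []
    for j in range(n_phi - 1):
        faces.append(
            G.band_between(np.arange(n_theta) + j * n_theta,
                           np.arange(n_theta) + (j + 1) * n_theta)
        )
    top = (n_phi - 1) * n_theta
    k = np.arange(n_theta)
    faces.append(np.column_stack([top + k, top + (k + 1) % n_theta,
                                  np.full(n_theta, n_phi * n_theta)]))
    return G.make_mesh(verts, np.vstack(faces))


class TestNakedEdgeLoops:
    def test_watertight_mesh_has_no_boundary(self):
        assert G.naked_edge_loops(trimesh.creation.box((1, 1, 1))) == []

    def test_capless_cylinder_has_two_loops(self):
        cyl = trimesh.creation.cylinder(radius=1, height=2, sections=48)
        tube = cyl.copy()
        tube.update_faces(np.abs(tube.face_normals[:, 2]) < 0.9)
        tube.remove_unreferenced_vertices()
        assert len(G.naked_edge_loops(tube)) == 2

    def test_hemisphere_boundary_length_matches_circumference(self):
        hemi = lat_long_hemisphere(radius=2.0)
        loops = G.naked_edge_loops(hemi)
        assert len(loops) == 1
        # inscribed 96-gon perimeter
        expected = 2 * 96 * 2.0 * np.sin(np.pi / 96)
        assert loops[0].length == pytest.approx(expected, rel=1e-9)
        assert loops[0].length == pytest.approx(2 * np.pi * 2.0, rel=1e-3)


class TestOrientedBoundingBox:
    def test_axis_aligned_box_recovered_exactly(self):
        ob = G.min_oriented_bounding_box(trimesh.creation.box((2, 3, 5)))
        assert sorted(ob.extents.round(9)) == [2, 3, 5]
        assert ob.volume == pytest.approx(30.0, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotation_invariant_volume(self, seed):
        box = trimesh.creation.box((2, 3, 5))
        R = trimesh.transformations.random_rotation_matrix(
            rand=np.random.RandomState(seed).rand(3)
        )
        box.apply_transform(R)
        ob = G.min_oriented_bounding_box(box)
        assert ob.volume == pytest.approx(30.0, rel=0.01)

    def test_sphere_box_extents_near_diameter(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        ob = G.min_oriented_bounding_box(sph)
        assert np.all(np.abs(ob.extents - 2.0) < 0.05)

    def test_face_centres_and_opposite_faces(self):
        ob = G.min_oriented_bounding_box(trimesh.creation.box((2, 2, 2)))
        centers = ob.face_centers()
        assert centers.shape == (6, 3)
        for i in range(6):
            j = ob.opposite_face(i)
            assert np.allclose(centers[i] + centers[j], 2 * ob.frame.origin)


class TestSectionWithPlane:
    def test_sphere_equator_perimeter_and_area(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=2.0)
        plane = G.Frame.from_origin_normal([0, 0, 0], [0, 0, 1])
        curves = G.section_with_plane(sph, plane)
        assert len(curves) == 1 and curves[0].closed
        area, per = curves[0].area_perimeter()
        assert per == pytest.approx(2 * np.pi * 2, rel=2e-3)
        assert area == pytest.approx(np.pi * 4, rel=5e-3)

    def test_plane_outside_mesh_gives_no_curves(self):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        plane = G.Frame.from_origin_normal([0, 0, 5], [0, 0, 1])
        assert G.section_with_plane(sph, plane) == []

    def test_axial_torus_section_has_two_closed_curves(self):
        tor = trimesh.creation.torus(major_radius=3, minor_radius=1)
        plane = G.Frame.from_origin_normal([0, 0, 0], [1, 0, 0])
        curves = G.section_with_plane(tor, plane)
        assert len(curves) == 2
        assert all(c.closed for c in curves)

    def test_points_lie_on_plane(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=1.5)
        normal = np.array([1.0, 2.0, 3.0]) / np.sqrt(14)
        plane = G.Frame.from_origin_normal([0.1, 0.2, -0.1], normal)
        for c in G.section_with_plane(sph, plane):
            d = (c.points - plane.origin) @ normal
            assert np.abs(d).max() < 1e-9


class TestOffsetAlongNormals:
    def test_sphere_inward_offset_shrinks_radius(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        off = G.offset_along_normals(sph, 0.1, "inward")
        r = np.linalg.norm(off.vertices, axis=1)
        assert np.abs(r - 4.9).max() < 1e-5

    def test_flat_patch_outward_offset_is_translation(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float
        )
        patch = G.make_mesh(verts, [[0, 1, 2], [0, 2, 3]])
        off = G.offset_along_normals(patch, 0.5, "outward")
        shift = off.vertices - patch.vertices
        assert np.allclose(np.abs(shift[:, 2]), 0.5)
        assert np.allclose(shift[:, :2], 0.0)

    def test_invalid_arguments_rejected(self):
        sph = trimesh.creation.icosphere(subdivisions=1)
        with pytest.raises(G.GeometryError):
            G.offset_along_normals(sph, 0.0, "inward")
        with pytest.raises(G.GeometryError):
            G.offset_along_normals(sph, 0.1, "sideways")


def circle(radius, z, n=64):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return G.Polyline3D(
        np.column_stack([radius * np.cos(t), radius * np.sin(t),
                         np.full(n, float(z))]),
        closed=True,
    )


class TestLoft:
    def test_cylinder_lateral_area(self):
        strip = G.loft(circle(1, 0), circle(1, 1), n=256)
        assert strip.area == pytest.approx(2 * np.pi, rel=0.01)

    def test_frustum_lateral_area_closed_form(self):
        r1, r2, h = 1.0, 0.5, 1.0
        strip = G.loft(circle(r1, 0), circle(r2, h), n=256)
        slant = np.hypot(r1 - r2, h)
        assert strip.area == pytest.approx(np.pi * (r1 + r2) * slant, rel=0.01)

    def test_translated_copy_gives_strip_of_width_t(self):
        c = circle(1, 0)
        t = np.array([0.0, 0.0, 0.7])
        strip = G.loft(c, G.Polyline3D(c.points + t, closed=True), n=128)
        z = strip.vertices[:, 2]
        assert z.min() == pytest.approx(0.0, abs=1e-12)
        assert z.max() == pytest.approx(0.7, abs=1e-12)

    def test_identical_curves_rejected(self):
        c = circle(1, 0)
        with pytest.raises(G.GeometryError):
            G.loft(c, c)


class TestTransformToFrame:
    def test_identity_when_frames_equal(self):
        mesh = trimesh.creation.box((1, 2, 3))
        f = G.Frame.identity()
        out = G.transform_to_frame(mesh, f, f)
        assert np.allclose(out.vertices, mesh.vertices, atol=1e-12)

    def test_pure_translation(self):
        mesh = trimesh.creation.box((1, 1, 1))
        f_from = G.Frame(np.array([1.0, 2.0, 3.0]), np.eye(3))
        out = G.transform_to_frame(mesh, f_from, G.Frame.identity())
        assert np.allclose(out.vertices, mesh.vertices - [1, 2, 3])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_preserves_pairwise_distances(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3))
        mesh = G.make_mesh(pts, [[0, 1, 2]])
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        R = trimesh.transformations.quaternion_matrix(q)[:3, :3]
        frame = G.Frame(rng.normal(size=3), R)
        out = G.transform_to_frame(mesh, G.Frame.identity(), frame)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        d1 = np.linalg.norm(
            out.vertices[:, None] - out.vertices[None], axis=2
        )
        assert np.abs(d0 - d1).max() < 1e-9

    def test_roundtrip_is_identity(self):
        rng = np.random.default_rng(3)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        frame = G.Frame(
            rng.normal(size=3),
            trimesh.transformations.quaternion_matrix(q)[:3, :3],
        )
        mesh = trimesh.creation.icosphere(subdivisions=1)
        out = G.transform_to_frame(
            G.transform_to_frame(mesh, G.Frame.identity(), frame),
            frame,
            G.Frame.identity(),
        )
        assert np.abs(out.vertices - mesh.vertices).max() < 1e-9


class TestPolyline:
    def test_resample_preserves_length(self):
        c = circle(2.0, 0, n=40)
        r = c.resample(256)
        assert r.length == pytest.approx(c.length, rel=1e-3)

    def test_open_resample_keeps_endpoints(self):
        p = G.Polyline3D(np.array([[0, 0, 0], [1, 0, 0], [3, 1, 0]], float))
        r = p.resample(17)
        assert np.allclose(r.points[0], [0, 0, 0])
        assert np.allclose(r.points[-1], [3, 1, 0])

    def test_area_requires_closed(self):
        p = G.Polyline3D(np.array([[0, 0, 0], [1, 0, 0]], float))
        with pytest.raises(G.GeometryError):
            p.area_perimeter()
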