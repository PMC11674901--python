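"""Tooth support: Bezier profiles, cement layer, roots, PDL."""

import numpy as np
import pytest

from fpdgen import geometry as G
from fpdgen import sdf
from fpdgen.tooth import (
    BezierProfile,
    ToothParams,
    eval_bezier,
    make_cement_layer,
    make_pdl,
    make_single_root,
)

PX = BezierProfile((0, 1), (0.08, 0.78), (0.75, 0.55), (1, 0.05))


class TestBezier:
    def test_endpoints(self):
        assert np.allclose(eval_bezier(PX, 0.0), [0, 1])
        assert np.allclose(eval_bezier(PX, 1.0), [1, 0.05])

    def test_midpoint_closed_form(self):
        # B(1/2) = (P0 + 3 P1 + 3 P2 + P3) / 8
        assert np.allclose(eval_bezier(PX, 0.5), [0.43625, 0.63])

    def test_parameter_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            eval_bezier(PX, 1.2)

    def test_nonmonotone_control_parameters_rejected(self):
        with pytest.raises(ValueError):
            BezierProfile((0, 1), (0.5, 0.5), (0.2, 0.3), (1, 0))


class TestCementLayer:
    def test_watertight_with_expected_thickness(self, cement_premolar,
                                                aligned_tooth):
        shell = cement_premolar.mesh
        assert shell.is_watertight
        d = sdf.MeshDistance(aligned_tooth.mesial).unsigned(
            cement_premolar.interior.vertices
        )
        assert d.mean() == pytest.approx(0.1, rel=0.05)

    def test_thin_shell_volume_approximation(self, cement_premolar,
                                             aligned_tooth):
        assert cement_premolar.mesh.volume == pytest.approx(
            aligned_tooth.mesial.area * 0.1, rel=0.2
        )

    def test_zero_thickness_rejected(self, aligned_tooth):
        with pytest.raises(G.GeometryError):
            make_cement_layer(aligned_tooth.mesial, 0.0)


class TestSingleRoot:
    def test_watertight_and_apex_depth(self, premolar, cement_premolar):
        assert premolar.solid.is_watertight
        z_min = cement_premolar.c_interior.points[:, 2].min()
        expected = z_min - 0.15 - 16.3
        assert premolar.solid.vertices[:, 2].min() == pytest.approx(
            expected, abs=1e-6
        )

    def test_root_length_equals_epsilon_plus_d_tooth(self, premolar,
                                                     cement_premolar):
        z_min = cement_premolar.c_interior.points[:, 2].min()
        length = z_min - premolar.level_z[-1]
        assert length == pytest.approx(0.15 + 16.3, abs=1e-9)

    def test_section_area_decreases_toward_apex(self, premolar):
        zs = premolar.level_z[2:-1:4]
        areas = []
        for z in zs:
            plane = G.Frame.from_origin_normal([0, 0, z], [0, 0, 1])
            curves = [
                c for c in G.section_with_plane(premolar.solid, plane)
                if c.closed
            ]
            areas.append(sum(c.area_perimeter([0, 0, 1])[0] for c in curves))
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_uniform_scaling_of_circular_margin(self):
        # circular interior margin scaled by (s, s) stays a circle of r*s
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring0 = np.column_stack([2 * np.cos(t), 2 * np.sin(t), np.zeros(64)])
        from fpdgen.tooth import _scaled_rings

        rings = _scaled_rings(
            ring0, np.array([-1.0]), np.array([0.5]), np.array([0.5])
        )
        r = np.linalg.norm(rings[0][:, :2], axis=1)
        assert np.allclose(r, 1.0, atol=1e-9)


class TestTwoRoot:
    def test_union_watertight_and_apex_depth(self, molar, cement_molar):
        assert molar.solid.is_watertight
        z_min = cement_molar.c_interior.points[:, 2].min()
        expected = z_min - 0.15 - 12.8
        assert molar.solid.vertices[:, 2].min() == pytest.approx(
            expected, abs=0.15
        )

    def test_one_component_near_cervix_two_near_apex(self, molar,
                                                     cement_molar):
        z0 = cement_molar.c_interior.points[:, 2].min() - 0.15
        for frac, n_expected in ((0.1, 1), (0.9, 2)):
            plane = G.Frame.from_origin_normal(
                [0, 0, z0 - 12.8 * frac], [0, 0, 1]
            )
            curves = [
                c for c in G.section_with_plane(molar.solid, plane) if c.closed
            ]
            assert len(curves) == n_expected

    def test_mirror_symmetric_with_symmetric_margin(self):
        # x-symmetric circular margin -> union symmetric about its y-z plane
        t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        ring = np.column_stack([3 * np.cos(t), 3 * np.sin(t), np.zeros(48)])
        from fpdgen.tooth import _scaled_rings, bezier_values, ToothParams

        p = ToothParams.molar()
        ts = np.linspace(0, 1, 8)
        sx = bezier_values(p.bezier_x, ts)
        sy = bezier_values(p.bezier_y, ts)
        bt = bezier_values(p.bezier_t, ts)
        zs = -1 - 10 * ts
        r_pos = _scaled_rings(ring, zs, sx, sy, x_shift=+bt * 4.0)
        r_neg = _scaled_rings(ring, zs, sx, sy, x_shift=-bt * 4.0)
        for a, b in zip(r_pos, r_neg):
            mirrored = b * np.array([-1.0, 1.0, 1.0])
            assert set(map(tuple, np.round(a, 9))) == set(
                map(tuple, np.round(mirrored, 9))
            )

    def test_missing_translation_profile_rejected(self, cement_molar):
        from fpdgen.tooth import make_two_root

        with pytest.raises(G.GeometryError):
            make_two_root(cement_molar, ToothParams.premolar())


class TestPdl:
    def test_watertight_with_expected_thickness(self, premolar, premolar_pdl):
        assert premolar_pdl.is_watertight
        n = len(premolar.root_surface.vertices)
        outer_pts = premolar_pdl.vertices[n: 2 * n]
        d = sdf.MeshDistance(premolar.root_surface).unsigned(outer_pts)
        assert d.mean() == pytest.approx(0.3, rel=0.05)

    def test_pdl_encloses_root_apex(self, premolar, premolar_pdl):
        apex = premolar.solid.vertices[
            np.argmin(premolar.solid.vertices[:, 2])
        ]
        below = apex - [0, 0, 0.15]
        assert sdf.MeshDistance(premolar_pdl).signed(below[None])[0] < 0

    def test_sphere_cap_toy_root_shell_volume(self):
        # hemispherical root: shell volume ~ 2/3 pi ((r+t)^3 - r^3)
        from tests.test_geometry import lat_long_hemisphere

        hemi = lat_long_hemisphere(radius=5.0)
        hemi.invert()  # open side up, normals outward-down like a root
        hemi.vertices[:, 2] *= -1
        shell = make_pdl(hemi, 0.3)
        expected = 2.0 / 3.0 * np.pi * ((5.3) ** 3 - 5.0**3)
        assert shell.volume == pytest.approx(expected, rel=0.05)

    def test_tooth_cement_pdl_do_not_interpenetrate(
        self, premolar, premolar_pdl, cement_premolar
    ):
        f1 = sdf.overlap_volume_fraction(premolar_pdl, premolar.solid, n=6000)
        f2 = sdf.overlap_volume_fraction(
            premolar_pdl, cement_premolar.mesh, n=6000
        )
        assert f1 < 1e-3
        assert f2 < 1e-3
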