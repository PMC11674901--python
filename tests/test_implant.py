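"""Implant support: abutment, implant body, thread, screw, assembly."""

import numpy as np
import pytest

from fpdgen import geometry as G
from fpdgen import sdf
from fpdgen.classify import SectionStack, circularity_index
from fpdgen.implant import (
    ImplantParams,
    fit_thread_pitch,
    make_abutment,
    make_implant_body,
    make_screw,
    make_thread_cutter,
    neck_section_diameter,
)


@pytest.fixture(scope="module")
def params():
    return ImplantParams()


def section_diameter(mesh, z, axis=(0, 0, 1)):
    plane = G.Frame.from_origin_normal([0, 0, z], axis)
    curves = [c for c in G.section_with_plane(mesh, plane) if c.closed]
    assert curves, f"no section at z={z}"
    outer = max(curves, key=lambda c: c.area_perimeter(axis)[0])
    pts = outer.resample(512).points
    ctr = pts.mean(axis=0)
    return 2 * np.linalg.norm(pts[:, :2] - ctr[:2], axis=1).max()


class TestAbutment:
    def test_watertight(self, implant_build):
        assert implant_build.parts["abutment_distal"].is_watertight

    def test_neck_and_post_diameters(self, implant_build):
        ab = implant_build.parts["abutment_distal"]
        z0 = implant_build.datums["distal"]
        assert section_diameter(ab, z0 - 1.0) == pytest.approx(3.0, rel=0.01)
        assert section_diameter(ab, z0 - 6.95) == pytest.approx(2.6, rel=0.01)

    def test_borehole_volume_removed(self, implant_build, aligned_implant,
                                     params):
        # compare against the same loft built without a bore
        from fpdgen.tooth import make_cement_layer

        cem = make_cement_layer(aligned_implant.distal, 0.1)
        ab = make_abutment(cem, params)
        bore_vol = (
            np.pi * (params.d_ba1 / 2) ** 2 * params.l_ba1
            + np.pi * (params.d_ba2 / 2) ** 2 * (params.l_a3 - params.l_ba1)
        )
        wide = ImplantParams(d_ba1=0.4, d_ba2=0.3)  # nearly boreless
        ab_small_bore = make_abutment(cem, wide)
        small = (
            np.pi * (wide.d_ba1 / 2) ** 2 * wide.l_ba1
            + np.pi * (wide.d_ba2 / 2) ** 2 * (wide.l_a3 - wide.l_ba1)
        )
        measured = ab_small_bore.volume - ab.volume
        assert measured == pytest.approx(bore_vol - small, rel=0.1)

    def test_bore_wider_than_section_rejected(self, aligned_implant):
        from fpdgen.tooth import make_cement_layer

        cem = make_cement_layer(aligned_implant.distal, 0.1)
        with pytest.raises(G.GeometryError):
            make_abutment(cem, ImplantParams(d_ba1=2.7, d_ba2=2.7))


class TestImplantBody:
    def test_neck_outer_diameter(self, params):
        imp = make_implant_body(params, z_neck=0.0)
        assert neck_section_diameter(imp, 0.0) == pytest.approx(5.0, rel=0.01)

    def test_axial_length(self, params):
        imp = make_implant_body(params, z_neck=0.0)
        z = imp.vertices[:, 2]
        assert z.max() - z.min() == pytest.approx(8.0, abs=1e-9)

    def test_mid_height_section_is_annulus(self, params):
        imp = make_implant_body(params, z_neck=0.0, threaded=False)
        plane = G.Frame.from_origin_normal([0, 0, -3.0], [0, 0, 1])
        curves = [c for c in G.section_with_plane(imp, plane) if c.closed]
        assert len(curves) == 2
        radii = sorted(
            np.linalg.norm(c.points[:, :2], axis=1).mean() for c in curves
        )
        assert radii[1] == pytest.approx(2.5, abs=1e-3)  # outer wall
        assert radii[0] == pytest.approx(params.d_bi2 / 2, abs=1e-3)

    def test_rotation_symmetry_via_circularity(self, params):
        imp = make_implant_body(params, z_neck=0.0, threaded=False)
        curves = []
        for z in (-2.0, -4.0, -6.0):
            plane = G.Frame.from_origin_normal([0, 0, z], [0, 0, 1])
            curves += [
                c for c in G.section_with_plane(imp, plane)
                if c.closed and
                np.linalg.norm(c.points[:, :2], axis=1).mean() > 2.0
            ]
        ci, _ = circularity_index(
            SectionStack(curves, np.zeros(len(curves)), np.array([0, 0, 1.0]))
        )
        assert ci > 0.999


class TestThread:
    def test_fitted_pitch(self, params):
        imp = make_implant_body(params, z_neck=0.0)
        assert fit_thread_pitch(imp, params) == pytest.approx(0.5, rel=0.02)

    def test_helix_span(self, params):
        # n_turns full revolutions over n_turns * pitch of axial travel
        imp = make_implant_body(params, z_neck=0.0)
        v = imp.vertices
        r = np.linalg.norm(v[:, :2], axis=1)
        root = (r < params.d_i1 / 2 - 0.9 * params.thread_depth) & (
            r > params.d_i1 / 2 - 1.1 * params.thread_depth
        )
        z_span = v[root][:, 2].max() - v[root][:, 2].min()
        assert z_span == pytest.approx(
            params.n_turns * params.p_t, abs=2 * params.p_t
        )

    def test_doubling_turns_doubles_span(self):
        p1 = ImplantParams(l_i1=12.0, n_turns=5)
        p2 = ImplantParams(l_i1=12.0, n_turns=10)
        spans = []
        for p in (p1, p2):
            imp = make_implant_body(p, z_neck=0.0)
            v = imp.vertices
            r = np.linalg.norm(v[:, :2], axis=1)
            root = (r < p.d_i1 / 2 - 0.99 * p.thread_depth) & (
                r > p.d_i1 / 2 - 1.01 * p.thread_depth
            )
            spans.append(v[root][:, 2].max() - v[root][:, 2].min())
        assert spans[1] / spans[0] == pytest.approx(2.0, rel=0.1)

    def test_removed_volume_matches_pappus(self, params):
        th = make_implant_body(params, z_neck=0.0)
        un = make_implant_body(params, z_neck=0.0, threaded=False)
        p, d = params.p_t, params.thread_depth
        flank_ax = d * np.tan(np.pi / 6)
        groove_area = d * (p - p / 8 - flank_ax)
        r_mean = params.d_i1 / 2 - d / 2
        expected = params.n_turns * groove_area * 2 * np.pi * r_mean
        assert un.volume - th.volume == pytest.approx(expected, rel=0.15)

    def test_thread_radius_bounds(self, params):
        imp = make_implant_body(params, z_neck=0.0)
        v = imp.vertices
        in_span = (v[:, 2] < -params.l_t) & (
            v[:, 2] > -(params.l_t + params.n_turns * params.p_t)
        )
        r = np.linalg.norm(v[in_span][:, :2], axis=1)
        wall = r > params.d_bi2 / 2 + 0.2  # ignore the internal bore
        assert r[wall].max() <= params.d_i1 / 2 + 1e-9
        assert r[wall].min() >= params.d_i1 / 2 - params.thread_depth - 1e-9

    def test_cutter_solid_watertight_with_matching_span(self, params):
        cutter = make_thread_cutter(params, z_neck=0.0)
        assert cutter.is_watertight
        z = cutter.vertices[:, 2]
        expected = (params.n_turns + 1) * params.p_t  # incl. extensions
        assert z.max() - z.min() == pytest.approx(expected, rel=0.1)

    def test_span_exceeding_length_rejected(self):
        with pytest.raises(G.GeometryError):
            make_implant_body(ImplantParams(n_turns=20), z_neck=0.0)


class TestScrew:
    def test_watertight_and_shaft_length(self, params):
        scr = make_screw(params, z_datum=0.0)
        assert scr.is_watertight and scr.volume > 0
        z = scr.vertices[:, 2]
        # shaft runs l_s below the head seat at -l_ba1
        assert z.min() == pytest.approx(-(params.l_ba1 + params.l_s), abs=1e-9)

    def test_overlong_screw_rejected(self, params):
        with pytest.raises(G.GeometryError):
            make_screw(ImplantParams(l_s=12.0), z_datum=0.0)

    def test_screw_contained_in_bores(self, implant_build):
        scr = implant_build.parts["screw_distal"]
        ab = implant_build.parts["abutment_distal"]
        imp = implant_build.parts["implant_distal"]
        # screw volume outside (abutment bore + implant bore) ~ 0:
        # equivalently the screw must not enter either metal part
        assert sdf.overlap_volume_fraction(scr, ab, n=6000) < 1e-3
        assert sdf.overlap_volume_fraction(scr, imp, n=6000) < 1e-3


class TestAssembly:
    def test_pairwise_non_interpenetration(self, implant_build):
        names = ["cement_distal", "abutment_distal", "implant_distal",
                 "screw_distal"]
        parts = [implant_build.parts[n] for n in names]
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                frac = sdf.overlap_volume_fraction(parts[i], parts[j], n=5000)
                assert frac < 1e-3, (names[i], names[j])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ImplantParams(d_i1=5.0, d_i2=4.0)  # tapered not supported
        with pytest.raises(ValueError):
            ImplantParams(d_bi1=2.0)  # must equal d_a1
        with pytest.raises(ValueError):
            ImplantParams(p_t=-0.5)
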