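"""Bone segment: frame, placement, subtraction, defects, PDL trim."""

import numpy as np
import pytest
import trimesh

from fpdgen import bone as BM
from fpdgen import fixtures as fx
from fpdgen import geometry as G
from fpdgen import pipeline as pl
from fpdgen import sdf


class TestBoneFrame:
    def test_orthonormal_right_handed(self, bone_d1):
        frame, _, _ = BM.build_bone_frame(bone_d1, span=30.0)
        assert np.allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-9)

    def test_projected_span_close_to_requested(self, bone_d1):
        frame, cm_d, cm_m = BM.build_bone_frame(bone_d1, span=30.0)
        d = np.linalg.norm(cm_m - cm_d)
        assert d == pytest.approx(30.0, rel=0.02)

    def test_span_longer_than_curve_rejected(self, bone_d1):
        with pytest.raises(G.GeometryError):
            BM.build_bone_frame(bone_d1, span=100.0)


class TestPlacement:
    def test_distal_margin_gap_is_d_bone(self, implant_build, bone_d1,
                                         implant_insertion):
        lm = implant_build.landmarks
        res = implant_insertion
        pd = trimesh.transformations.transform_points(
            [lm.p_distal], res.bone_frame.matrix
        )[0] + 2.8 * res.bone_frame.z
        loc = bone_d1.frame.to_local(pd)[0]
        crest = float(bone_d1.crest_height(loc[0], loc[1])[0])
        assert loc[2] - crest == pytest.approx(2.8, rel=0.02)

    def test_placement_is_rigid(self, implant_build, implant_insertion):
        a0 = implant_build.parts["implant_distal"].vertices
        a1 = implant_insertion.placed["implant_distal"].vertices
        i, j = 10, 500
        d0 = np.linalg.norm(a0[i] - a0[j])
        d1 = np.linalg.norm(a1[i] - a1[j])
        assert d0 == pytest.approx(d1, abs=1e-9)

    def test_implant_apex_ends_below_crest(self, implant_insertion, bone_d1):
        imp = implant_insertion.placed["implant_distal"]
        lowest = imp.vertices[np.argmin(imp.vertices[:, 2])]
        loc = bone_d1.frame.to_local(lowest)[0]
        crest = float(bone_d1.crest_height(loc[0], loc[1])[0])
        assert loc[2] < crest

    def test_too_large_gap_rejected(self, implant_build, aligned_implant,
                                    bone_d1):
        with pytest.raises(G.GeometryError):
            pl.insert_into_bone(
                implant_build, aligned_implant, bone_d1, d_bone=80.0,
                subtract=False,
            )


class TestSubtraction:
    def test_bone_volume_decreases_by_submerged_volume(
        self, implant_insertion, bone_d1
    ):
        removed = bone_d1.outer.volume - implant_insertion.bone.outer.volume
        # submerged volume of both implants via their own SDF vs the crest
        submerged = 0.0
        for side in ("distal", "mesial"):
            imp = implant_insertion.placed[f"implant_{side}"]
            inter = G.mesh_boolean(
                bone_d1.outer, imp, "intersection", budget=2.0e6
            )
            submerged += inter.volume
        assert removed == pytest.approx(submerged, rel=0.05)

    def test_subtracting_nonintersecting_part_is_identity(self, bone_d1):
        far = trimesh.creation.box((2, 2, 2))
        far.apply_translation([0, 0, 50])
        out = BM.subtract_assembly(bone_d1, [far])
        assert out.outer is bone_d1.outer

    def test_result_watertight(self, implant_insertion):
        assert implant_insertion.bone.outer.is_watertight


class TestDefects:
    def test_depth_zero_is_identity(self, bone_d1):
        spec = BM.DefectSpec(depth=0.0, sites=[-15.0])
        assert BM.carve_defect(bone_d1, spec) is bone_d1

    def test_max_depth_matches_spec(self, bone_d1):
        spec = BM.DefectSpec(depth=3.0, sites=[-15.0, 15.0])
        with pytest.warns(UserWarning, match="cancellous"):
            carved = BM.carve_defect(bone_d1, spec)
        assert BM.defect_max_depth_measured(bone_d1, carved, 15.0) == \
            pytest.approx(3.0, abs=0.05)

    def test_mesiodistal_extent_matches_width(self, bone_d1):
        spec = BM.DefectSpec(depth=2.0, sites=[-15.0, 15.0])
        carved = BM.carve_defect(bone_d1, spec)
        ext = BM.defect_extent_measured(bone_d1, carved, -15.0)
        assert ext == pytest.approx(10.0, abs=0.2)

    def test_carving_is_idempotent(self, bone_d1):
        spec = BM.DefectSpec(depth=2.0, sites=[-15.0])
        once = BM.carve_defect(bone_d1, spec)
        twice = BM.carve_defect(once, spec)
        assert np.allclose(once.outer.vertices, twice.outer.vertices)

    def test_defect_volume_strictly_increases_with_depth(self, bone_d1):
        vols = []
        for depth in (0.0, 1.0, 2.0, 3.0):
            spec = BM.DefectSpec(depth=depth, sites=[-15.0, 15.0])
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                carved = BM.carve_defect(bone_d1, spec)
            vols.append(carved.outer.volume)
        assert all(a > b for a, b in zip(vols, vols[1:]))

    def test_sites_required(self, bone_d1):
        with pytest.raises(G.GeometryError):
            BM.carve_defect(bone_d1, BM.DefectSpec(depth=1.0))


class TestTrimPdl:
    def test_trim_top_coincides_with_crest(self, tooth_insertion, bone_d1):
        pdl = tooth_insertion.placed["pdl_mesial"]
        trimmed = BM.trim_pdl(pdl, tooth_insertion.bone)
        assert trimmed.is_watertight
        local = bone_d1.frame.to_local(trimmed.vertices)
        cut = tooth_insertion.bone.cut_height(local[:, 0], local[:, 1])
        overhang = local[:, 2] - cut
        assert overhang.max() < 0.05

    def test_area_monotone_in_defect_depth(self, tooth_insertion):
        pdl = tooth_insertion.placed["pdl_mesial"]
        areas = []
        for depth in (0.0, 1.0, 2.0, 3.0):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                carved, _ = pl.carve_defects(tooth_insertion, depth)
            areas.append(BM.trim_pdl(pdl, carved).area)
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_pdl_above_bone_rejected(self, bone_d1, premolar_pdl):
        floating = premolar_pdl.copy()
        floating.apply_translation([0, 0, 100.0])
        with pytest.raises(G.GeometryError):
            BM.trim_pdl(floating, bone_d1)


class TestLayering:
    @pytest.mark.parametrize("quality, expected",
                             [("D1", 2.5), ("D4", 1.0)])
    def test_cortical_thickness_realised(self, quality, expected):
        seg = fx.make_bone_fixture(quality)
        assert BM.cortical_thickness_measured(seg) == pytest.approx(
            expected, rel=0.02
        )

    def test_interfaces_nested_inside_outer(self, bone_d1):
        s1 = sdf.MeshDistance(bone_d1.outer).signed(
            bone_d1.interface_cortical.vertices[::29]
        )
        # interior vertices strictly inside; end-cap rims may sit on the
        # segment's cut planes
        assert (s1 < 1e-6).all()
        assert (s1 < -1e-3).mean() > 0.9
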