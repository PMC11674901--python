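"""End-to-end orchestration: align, detect, generate support, insert into
bone, carve defects, export a solver-ready manifest.

The stages mirror the clinical modelling workflow: an imported bridge is
aligned to its own anatomy, the support type is read off the lumen shapes,
the matching support stack is generated per side (mesial = first premolar,
distal = second molar for tooth support), the assembly is seated in a bone
segment with a fixed supracrestal gap, and crestal bone loss of the
requested depth is carved around both supports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import bone as bone_mod
from .alignment import FpdModel, FpdLandmarks, align_to_global, analyse
from .classify import CiReport, detect_support_type
from .geometry import Frame, GeometryError
from .implant import (
    ImplantParams,
    make_abutment,
    make_implant_body,
    make_screw,
)
from .materials import bone_quality
from .tooth import (
    CementLayer,
    ToothParams,
    make_cement_layer,
    make_pdl_for,
    make_single_root,
    make_two_root,
)

D_BONE_DEFAULT = 2.8  # supracrestal gap between distal margin and crest, mm


@dataclass
class SupportBuild:
    """All generated support parts plus bookkeeping."""

    support_type: str
    parts: dict[str, trimesh.Trimesh]
    cavity_part_names: list[str]
    landmarks: FpdLandmarks
    datums: dict[str, float]  # margin datum z per side
    ci_report: CiReport | None = None


def build_support(
    aligned: FpdModel,
    support_type: str = "auto",
    tooth_params: dict | None = None,
    implant_params: ImplantParams | None = None,
    budget: float = 2.5e6,
) -> SupportBuild:
    """Generate the full support stack for an aligned restoration.

    ``support_type='auto'`` routes through the circularity classifier.
    Tooth support: cement + premolar (mesial) / molar (distal) + PDL.
    Implant support: cement + abutment + implant body + screw per side.
    """
    lm = analyse(aligned)
    report = None
    if support_type == "auto":
        report = detect_support_type(aligned, lm)
        support_type = report.support_type
    if support_type not in ("tooth", "implant"):
        raise GeometryError(f"unknown support type {support_type!r}")

    parts: dict[str, trimesh.Trimesh] = {}
    cavity: list[str] = []
    datums: dict[str, float] = {}

    if support_type == "tooth":
        tp = tooth_params or {}
        params = {
            "mesial": tp.get("mesial", ToothParams.premolar()),
            "distal": tp.get("distal", ToothParams.molar()),
        }
        for side, lumen in (("mesial", aligned.mesial),
                            ("distal", aligned.distal)):
            p = params[side]
            cem = make_cement_layer(lumen, p.d_cement)
            datums[side] = float(cem.c_interior.points[:, 2].min())
            parts[f"cement_{side}"] = cem.mesh
            if p.bezier_t is None:
                sup = make_single_root(cem, p)
            else:
                sup = make_two_root(cem, p, budget=budget)
            parts[f"tooth_{side}"] = sup.solid
            pdl = make_pdl_for(sup, p.d_pdl, budget=budget)
            parts[f"pdl_{side}"] = pdl
            cavity.append(f"pdl_{side}")
    else:
        p = implant_params or ImplantParams()
        for side, lumen in (("mesial", aligned.mesial),
                            ("distal", aligned.distal)):
            cem = make_cement_layer(lumen, p.d_cement)
            z0 = float(cem.c_interior.points[:, 2].min())
            datums[side] = z0
            centre = cem.c_interior.centroid()[:2]
            parts[f"cement_{side}"] = cem.mesh
            parts[f"abutment_{side}"] = make_abutment(cem, p)
            imp = make_implant_body(p, z_neck=z0 - p.l_a1)
            imp.apply_translation([centre[0], centre[1], 0.0])
            parts[f"implant_{side}"] = imp
            parts[f"screw_{side}"] = make_screw(p, z_datum=z0, centre_xy=centre)
            cavity.append(f"implant_{side}")

    return SupportBuild(
        support_type=support_type,
        parts=parts,
        cavity_part_names=cavity,
        landmarks=lm,
        datums=datums,
        ci_report=report,
    )


@dataclass
class InsertionResult:
    bone: bone_mod.BoneSegment
    placed: dict[str, trimesh.Trimesh]
    bone_frame: Frame
    fpd_frame: Frame
    sites: list[float]  # support x positions in bone-local coordinates


def insert_into_bone(
    build: SupportBuild,
    aligned: FpdModel,
    bone_seg: bone_mod.BoneSegment,
    d_bone: float = D_BONE_DEFAULT,
    subtract: bool = True,
    budget: float = 6.0e6,
) -> InsertionResult:
    """Place the restoration + support into the bone segment and subtract
    the cavity-bounding parts from the bone solid."""
    lm = build.landmarks
    span = float(np.linalg.norm(lm.p_mesial - lm.p_distal))
    bone_frame, _, _ = bone_mod.build_bone_frame(bone_seg, span)
    fpd_frame = Frame.identity()  # aligned restorations live in the global frame
    all_parts = dict(build.parts)
    for name, m in aligned.to_solids().items():
        all_parts[f"fpd_{name}"] = m
    placed = bone_mod.place_assembly(all_parts, fpd_frame, bone_frame, d_bone)

    # support sites on the bone-local mesiodistal axis
    sites = []
    for pt in (lm.p_distal, lm.p_mesial):
        world = trimesh.transformations.transform_points(
            [pt], bone_frame.matrix @ np.linalg.inv(fpd_frame.matrix)
        )[0] + d_bone * bone_frame.z
        sites.append(float(bone_seg.frame.to_local(world)[0, 0]))

    out_bone = bone_seg
    if subtract:
        cavity = [placed[n] for n in build.cavity_part_names]
        out_bone = bone_mod.subtract_assembly(bone_seg, cavity, budget=budget)
    return InsertionResult(out_bone, placed, bone_frame, fpd_frame, sites)


def carve_defects(
    result: InsertionResult, depth: float, width: float = 10.0,
    fillet: float = 0.4,
) -> tuple[bone_mod.BoneSegment, bone_mod.DefectSpec]:
    spec = bone_mod.DefectSpec(
        depth=depth, width=width, fillet_radius=fillet, sites=list(result.sites)
    )
    return bone_mod.carve_defect(result.bone, spec), spec


_PART_MATERIALS = {
    "cement": "cement",
    "tooth": "abutment_tooth",
    "pdl": None,  # hyperelastic; flagged separately in the manifest
    "abutment": "abutment",
    "implant": "implant",
    "screw": "implant_screw",
    "fpd": "zirconia_fpd",
    "bone": None,
}


def part_material(name: str) -> str | None:
    return _PART_MATERIALS.get(name.split("_")[0])


def assembly_manifest(
    build: SupportBuild,
    quality: str,
    defect: bone_mod.DefectSpec | None = None,
    d_bone: float = D_BONE_DEFAULT,
) -> dict:
    """Solver-ready description: parts + materials, bonded interfaces and
    the boundary-condition recipe (fixed base, frictionless sides, 105 N
    over three occlusal patches near the middle connector)."""
    q = bone_quality(quality)
    parts = []
    for name in sorted(build.parts) + ["fpd", "bone"]:
        mat = part_material(name)
        entry = {"part": name, "material": mat}
        if name.startswith("pdl"):
            entry["material_model"] = {
                "type": "ogden_1st_order",
                "mu1_MPa": 0.006,
                "alpha1": 29.8,
                "d1_per_MPa": 0.0,
            }
        if name == "bone":
            entry["material_model"] = {
                "type": "layered_graded",
                "quality": q.label,
                "cortical_thickness_mm": q.cortical_thickness,
                "transition_thickness_mm": q.transition_thickness,
                "e_cortical_GPa": q.e_cortical,
                "e_cancellous_GPa": q.e_cancellous,
            }
        parts.append(entry)
    sides = ("mesial", "distal")

    def tag(part: str, side: str) -> str:
        return part if part in ("fpd", "bone") else f"{part}_{side}"

    if build.support_type == "tooth":
        chain = ["fpd", "cement", "tooth", "pdl", "bone"]
        extra: list[list[str]] = []
    else:
        chain = ["fpd", "cement", "abutment", "implant", "bone"]
        extra = [[f"screw_{s}", f"abutment_{s}"] for s in sides] + [
            [f"screw_{s}", f"implant_{s}"] for s in sides
        ]
    bonded = [
        [tag(a, s), tag(b, s)]
        for s in sides
        for a, b in zip(chain, chain[1:])
    ] + extra
    manifest = {
        "support_type": build.support_type,
        "bone_quality": q.label,
        "d_bone_mm": d_bone,
        "parts": parts,
        "bonded_interfaces": bonded,
        "boundary_conditions": {
            "fixed": "lower surface of the bone segment (all DOF)",
            "frictionless": "both mesiodistal side surfaces of the segment",
            "load": {
                "total_N": 105.0,
                "patches": 3,
                "location": "occlusal surface near the middle connector",
                "direction": "parallel to the support axis (-z)",
            },
        },
    }
    if defect is not None:
        manifest["bone_defect"] = {
            "shape": defect.shape,
            "depth_mm": defect.depth,
            "width_mm": defect.width,
            "fillet_radius_mm": defect.fillet_radius,
            "sites_x_mm": list(defect.sites),
        }
    return manifest


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
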