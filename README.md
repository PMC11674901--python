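# fpdgen

Parametric, automated generation of the **support structures of a 4-unit
fixed partial denture (FPD)** — either natural-tooth support (cement
layer, Bézier-profiled abutment teeth, periodontal ligament) or implant
support (cement layer, abutment, threaded implant body, abutment screw) —
together with insertion into a layered mandibular bone segment and
carving of crestal bone-loss defects. The output is solver-ready labeled
triangle-mesh geometry plus a boundary-condition manifest for downstream
finite-element analysis of how bone loss (0–3 mm) and Misch bone quality
(D1–D4) affect the restoration.

It is aimed at dental-biomechanics researchers who need many consistent
FE-ready model variants without manual CAD work.

## What it computes

Starting from a bridge scan split into three labeled sub-meshes
(`surface`, `distal` lumen, `mesial` lumen in one multi-solid ASCII STL):

1. **Alignment** — margin-curve centres `P_distal`, `P_mesial` of the two
   lumens, the gingival face of the minimal oriented bounding box, and a
   local frame (origin `P_distal`, x toward `P_mesial`, z occlusal) that
   is mapped rigidly onto the global frame.
2. **Support-type detection** — each lumen is sliced by 100 equally
   spaced planes; the circularity index

   CI = mean over retained closed sections of 4πAᵢ/Peᵢ²

   is 1 for perfect circles. CI ∈ [0.97, 1] on both sides ⇒ implant
   support; anything else ⇒ tooth support.
3. **Support generation** — tooth variant: cement shell of thickness
   `d_cement` = 0.1 mm, a single-rooted premolar and two-rooted molar
   whose level curves are scaled by cubic Bézier profiles
   `B_x(t)`, `B_y(t)` (and translated apart by `B_T(t)·d_R` for the two
   roots), and a 0.3 mm periodontal-ligament shell. Implant variant:
   abutment loft with stepped borehole, a Ø5.0 × 8.0 mm implant body
   with an ISO-metric thread (pitch 0.5 mm, 10 turns) and an abutment
   screw, all from one parameter set.
4. **Bone insertion** — the assembly is seated on a layered bone segment
   (cortical shell per quality, 0.29 mm linearly graded transition,
   cancellous core) with a 2.8 mm supracrestal gap, and subtracted from
   the bone solid.
5. **Bone defects** — saucer-shaped crestal defects (width 10 mm, rim
   fillet 0.4 mm, depth 0–3 mm) carved around both supports.

Material models (Table-style registry, Misch D1–D4 cortical thickness and
cancellous stiffness, the graded transition modulus and the first-order
Ogden PDL stress σ(λ) = μ₁(λ^α₁ − λ^(−α₁/2))) are exposed as evaluable
functions and written into the assembly manifest.

Because the original scanned master model is not distributable, a
deterministic synthetic-fixture module generates stand-ins: a
tooth-variant bridge with lobed lumen sections (CI ≈ 0.92) and an
implant variant with near-circular sections (CI ≈ 0.997), plus the
parametric mandibular segment.

## Worked example

```bash
$ fpdgen fixtures make-fpd --type tooth --seed 0 -o fpd_tooth.stl
tooth fixture written to fpd_tooth.stl
$ fpdgen detect fpd_tooth.stl
CI distal=0.926 mesial=0.931 -> tooth support

$ fpdgen fixtures make-fpd --type implant --seed 0 -o fpd_implant.stl
$ fpdgen detect fpd_implant.stl
CI distal=0.997 mesial=0.997 -> implant support

$ fpdgen materials --quality D3 --json
{
  "label": "D3",
  "cortical_thickness_mm": 1.5,
  "e_cortical_GPa": 13.7,
  "e_cancellous_GPa": 1.6,
  "transition_thickness_mm": 0.29
}
```

The CI readings mean: the tooth-variant lumens are clearly non-circular
(0.93 < 0.97 on both sides, so natural-tooth support is generated), the
implant-variant lumens are near-perfect circles (0.997, machined
abutment copings). The D3 row gives the cortical-shell thickness and the
cancellous stiffness used to layer the bone segment.

A full assembly (support + bone + defect + manifest):

```bash
fpdgen insert fpd_implant.stl --type auto --quality D2 --depth 2 -o out/
```

writes one STL per part and `out/assembly.json` with part materials,
bonded-interface pairs and the loading recipe (fixed base, frictionless
sides, 105 N over three occlusal patches near the middle connector).

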