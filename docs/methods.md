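# Methods

This note records the modelling conventions, numerical choices and known
limitations of fpdgen, in the order of the pipeline.

## Geometry carrier and conventions

All geometry is indexed triangle meshes in millimetres (`trimesh`
objects). Frames are right-handed and orthonormal; after alignment +z is
the occlusal direction, +x runs from the distal to the mesial support.
Planes are represented as a frame whose z-axis is the normal.
Constructive solids (shells, lofted roots, solids of revolution) are
built *ring-welded*: consecutive cross-section rings share a point count
and correspondence, so the mesh is watertight by construction rather
than by repair.

## Distance queries and Booleans

No exact Boolean kernel is assumed. The package carries its own stack:

* **Signed distance** by the angle-weighted pseudonormal construction:
  exact point–triangle closest points (escalating k-NN candidate search
  with a completeness bound based on local triangle circumradii), sign
  from the pseudonormal of the closest feature. Elongated triangles are
  subdivided on construction so candidate search stays local. A numba
  kernel accelerates the inner loop when numba is importable; a pure
  numpy path gives identical results.
* **Booleans**: disjoint or fully nested watertight inputs are resolved
  exactly by classification (triangle–triangle intersection tests for
  the broadphase verdict, pseudonormal containment for nesting). When
  surfaces truly intersect, the solids are combined on a signed-distance
  voxel grid (min/max of fields) and the zero level set extracted with
  marching cubes. The field is exact within ~2.2 cells of each surface
  and sign-correct elsewhere (distance transform + flood fill), so the
  reconstructed surface is sub-voxel accurate away from sharp
  intersection edges. Grid pitch is chosen from a voxel budget (default
  4·10⁶ cells, clamped to [0.008, 0.3] mm); volume errors on unit-scale
  box pairs measure well under 0.1 %.

The trade-off: Boolean outputs are remeshed (marching-cubes topology),
which is acceptable here because every Boolean in the pipeline feeds
either a volume/containment check or an FE preprocessing export, not
further exact construction.

## Alignment

The margin curve of each lumen is its longest naked-edge loop; its
"centre" is the mean of 256 arc-length-resampled points so scanner
vertex density cannot bias it. The minimal oriented bounding box is
computed after rotating the vertex set into its principal-axis frame
with sign-canonicalised axes (third moments) and quantising coordinates
to 10⁻⁸ mm: the discrete orientation search then sees bit-identical
input in every world pose, which makes alignment pose-invariant and
idempotent to ~10⁻¹³ mm — the property the rest of the pipeline relies
on. The frame's x-axis is the distal→mesial line projected into the
gingival plane (the two need not be orthogonal on a real scan); the
z-sign is chosen so +z points occlusally.

## Support-type detection

100 slicing planes span the gingival-to-occlusal line of the bounding
box inclusive of endpoints; only closed section curves are kept and the
first and last retained curves are dropped as margin/tip artefacts.
Areas and perimeters are computed by the shoelace formula on the curve
resampled to 256 points and projected into its section plane;
self-intersecting polygons are excluded with a warning. The index is the
arithmetic mean of 4πA/Pe² over retained curves — a true mean is the
only convention under which perfect circles read exactly 1. The implant
band [0.97, 1] is inclusive at 0.97; a mixed reading (one side
implant-like) classifies as tooth with a warning, since homogeneous
supports are assumed.

## Tooth support

* Cement: inward vertex-normal offset of the lumen by `d_cement`
  (default 0.1 mm), closed by a band between the corresponding margin
  loops. Offset distance is the plain per-vertex displacement, faithful
  to "new vertices parallel to each original vertex"; on smooth lumens
  the realised mean wall thickness is within ~2 % of nominal.
* Roots: the interior margin loop is projected onto `n_levels` = 20
  planes spaced uniformly along the root axis (first level ε = 0.15 mm
  below the margin's lowest point, axis length `d_tooth`), scaled per
  level by the cubic Bézier values B_x(tᵢ), B_y(tᵢ) about the projected
  curve's own centroid (keeps the root centred under the lumen — the
  scaling origin is otherwise unconstrained), then lofted and capped.
  The two molar root stacks are additionally translated by ±B_T(tᵢ)·d_R
  (d_R default 4.0 mm, a configuration default: it must merely separate
  two roots within a molar-scale lumen) and merged with a voxel union.
* PDL: outward offset shell of the root surface (0.3 mm) with a
  constant-thickness correction — in concave root grooves a plain
  normal offset lands nearer the opposite wall than the nominal
  thickness, so each displacement is rescaled (3 fixed-point steps)
  until the true closest-point distance equals `d_PDL`. For the molar
  the per-root shells are unioned and the tooth solid subtracted in one
  voxel pass, removing the shell portions that dive through the
  neighbouring root.

## Implant support

Axial datum: depths are measured downward from the plane of the interior
margin's lowest point; the implant neck plane sits `l_a1` below it.

* Abutment: one ring-welded tube — interior cup, loft through the three
  abutment circles (ring points generated at the same polar angles as
  the margin loop so bands never twist), bottom annulus, stepped blind
  bore ending in a disk at the datum plane. No Boolean needed.
* Implant body: a lathe profile (apex fillet `r_f`, outer wall, neck
  chamfer, stepped internal bore) revolved with adaptive axial sampling.
  The printed bore depths are read as cumulative below the neck; the
  Ø2.6 bore section is deepened when necessary so the abutment post and
  screw seat fully — the printed abutment and bore depths are otherwise
  mutually inconsistent (post 6.0 mm below neck vs. a 4.0 mm bore).
  The neck chamfer (`r_c` = 1.5 mm) is realised as an internal
  45° funnel from the platform edge down to the upper bore: it keeps
  the outer diameter at the neck plane at the full 5.0 mm and matches
  how the abutment taper seats into the implant.
* Thread: an exact radial displacement of the outer wall. Depth follows
  the ISO-metric external V form for the pitch (depth 0.61343·p, 60°
  flanks, p/8 crest flat) in the helical phase u = z/p + θ/2π, fading
  over half a turn at each end (the milling tool's tangential
  run-in/run-out). This is geometrically the same surface a swept-cutter
  subtraction produces, but watertight and with machine-exact pitch; a
  swept cutter solid is still available for cross-checks.
* Screw: turned part — cylindrical head filling the Ø1.6 abutment seat
  (the simplest solid satisfying the bore contract; no head geometry is
  otherwise prescribed), shaft Ø1.1 extending `l_s` = 4.5 mm below the
  seat. `r_b` (0.2 mm) is accepted as a parameter for the internal bore
  step blend but the default profile realises the step sharp; the blend
  has no effect on any exported quantity.

## Bone segment, insertion, defects

The synthetic segment is an extruded cross-section (crest arc radius
10 mm over a ±5 mm ridge top, flaring to a 16 mm-wide base, 24 mm tall,
40 mm long) following a gentle dental-arch curve (R = 200 mm). Layer
interfaces are exact 2D insets of the profile (shapely buffer, round
joins) extruded the same way, so cortical thickness is constant at the
quality's value and the segment's cut ends stay flat, as a segment cut
from a longer mandible would. The crestal patch is defined as the
ridge-top band (face normals within ~14° of vertical).

Placement builds a frame on the centre curve (two points at arc distance
equal to the restoration span, projected up to the crest), maps the
restoration frame onto it and raises everything by `d_bone` = 2.8 mm.
The cavity is bounded by the PDL outer surfaces (tooth) or the implant
bodies (implant), subtracted from the bone solid on the voxel grid; the
layer *interfaces* are metadata surfaces and are not re-cut by the
cavity (a solver export would intersect layers with the final solid).

Defects are applied as a height-field cut: the crest function minus the
saucer profile — a circular arc through (±w/2, 0) and (0, −depth) with
an exactly tangent rim fillet (r = 0.4 mm) — and vertices above the cut
are clamped onto it. This preserves mesh topology, which makes depth-0
an identity, re-carving idempotent, and the deviation measurable
vertex-by-vertex against the intact mesh. The PDL trim clamps the same
way, so trimmed-PDL area decreases strictly with defect depth.

## Materials

Registry values are the elastic constants of each component (zirconia
framework 210 GPa/0.27, Ti grade 4 abutment+implant 104.5/0.37, Ti
grade 5 screw 114/0.33, glass-ionomer cement 15.9/0.33, polyurethane
abutment tooth 3.525/0.33, cortical bone 13.7/0.3, cancellous bone per
quality). The graded transition modulus is linear from 13.7 GPa at the
cortical boundary to the quality's cancellous value over 0.29 mm,
continuous on both ends. The PDL uses the classical first-order Ogden
form W = (μ₁/α₁)Σ(λᵢ^α₁ − 3) with μ₁ = 0.006 MPa, α₁ = 29.8, fully
incompressible (D₁ = 0): uniaxial Cauchy stress μ₁(λ^α₁ − λ^(−α₁/2)),
zero at λ = 1, small-strain modulus 3μ₀ with μ₀ = μ₁α₁/2. The convention
is verified against the finite-difference derivative of the energy
rather than a literature stress value, because published parameter sets
do not state the energy normalisation.

## Synthetic fixtures: what they do and do not show

The generators emulate the *shape classes* the algorithms must handle:
lobed tooth preparations whose circularity lands near 0.92 (lobe
amplitudes chosen once at design time and frozen), machined near-circular
abutment copings near 0.997, a smooth bridge hull, and a ridge-shaped
bone segment. All randomness (lobe phases, pose, ripple phase) flows
from one seeded generator; equal seeds give byte-identical STL output.
They do not contain scan noise, undercuts, margin chipping or anatomical
root curvature — passing tests therefore demonstrate the pipeline's
contracts (alignment invariances, classification thresholds, realised
thicknesses and dimensions, watertightness) on clean geometry, not
robustness to degraded scans.

## Problem sizes

Defaults used by the test-suite and the acceptance script: lumen rings
128 × 16, bone segment ≈ 35 k vertices (0.1 mm mesiodistal sampling in
the defect band), voxel budgets 2.5·10⁶ cells for molar/PDL Booleans
and 4·10⁶ for bone subtraction, 100 slicing planes, 256-point section
resampling. The 2 (support types) × 4 (qualities) × 4 (depths) property
grid reuses one support build per type and one bone subtraction per
type; defect carving and trims run per cell.

## Known limitations

* Boolean results are voxel-remeshed; sharp intersection edges are
  chamfered at the sub-voxel scale.
* The abutment/implant internal datum chain follows the package's own
  convention (see above); other implant systems differ.
* No automatic segmentation of an unlabeled scan into the three parts;
  the multi-solid STL labels are an input contract.
* Tooth roots are idealised (straight axis, smoothly tapering lobes);
  no three-rooted or dilacerated variants, no PDL fibre architecture.
* The FE solve itself (meshing, contact, loading) is out of scope; the
  package exports labeled solids and the boundary-condition manifest.
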