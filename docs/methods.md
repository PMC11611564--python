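# Methods

## Representation

Every solid in the workflow is a narrow-band signed-distance field
(level set) on a cubic voxel grid: value = distance in mm to the nearest
material surface, **negative inside**, clamped to ±`band_width · h`
(default band 3 voxels) away from the surface. Outside the band only the
sign is meaningful. The voxel size `h` is the single resolution input of
the whole workflow; every stage inherits it, so geometries from different
stages compose seamlessly.

Grids are anchored to a global lattice (origins are snapped to integer
multiples of `h`). Any two fields with equal `h` can therefore be padded
onto a common bounding box without resampling, which is what makes the
Boolean kernel exact at indicator level: `union = min`, `intersection =
max`, `difference = max(φ_A, −φ_B − ε)` with ε = 10⁻⁶·h, so voxel centers
exactly on the subtrahend's surface stay in the result and
difference/intersection partition the minuend exactly. CSG results carry
exact distances on the outward side of the surface and conservative
(upper-bound) distances near seams; `redistance` rebuilds a true distance
field from the current zero contour (sub-voxel crossings located by linear
interpolation, KD-tree distances within the band, sign-only beyond) when a
later large offset needs true depths — `offset` invokes it automatically
whenever |d| exceeds the usable band.

### Mesh ⇄ level set

Mesh → level set: inside/outside by parity of surface crossings along grid
columns (robust for watertight input; a deterministic sub-voxel jitter of
the column coordinates removes edge/vertex ties), then exact
point-to-triangle distances on the narrow band, with candidate faces taken
from the 12 nearest face centroids. This is exact when face sizes are
locally comparable; every mesh this package generates bounds its edge
lengths (the tube fixtures subdivide walls at 3 mm) to keep that guarantee.
Measured accuracy: unit cube at h = 0.05 within 0.8 % volume, sphere r = 5
at h = 0.25 within 0.2 %.

Level set → mesh: marching cubes at iso level 0 with a fixed case table
(bit-identical across runs). Field values within 10⁻³·h of zero are nudged
off zero first — this fixes the topology deterministically and prevents
sliver triangles from crossings collapsing onto grid corners. The
`adaptive` flag extracts on a 2× coarsened sampling (fewer faces, reduced
fidelity). Extracted meshes pass all printability checks by construction;
the test suite asserts this for every exported mesh.

### Volume measure

`volume()` sums a per-voxel occupancy fraction `clip(1/2 − φ/h, 0, 1)` — a
linear ramp across the boundary layer, exact for an axis-aligned planar
interface and second-order for smooth surfaces. A consequence worth
knowing: a CSG difference whose two surfaces coincide leaves a half-weight
"skin" in this measure even though its indicator is empty. The guided
cavity fill suppresses such phantom skins explicitly (voxels not connected
to the cavity mouth are floored to +h), and the closing-based pipeline fill
stands off the bone by h/4 for the same reason.

## Design stages

**ROI and resection.** The ROI cylinder and the resection masks are
analytic signed-distance solids (sphere, box, capped cylinder) or imported
meshes. The mask stack is an ordered, immutable list with unique ids;
`resected_union` is the Boolean union of all committed masks, applied as a
single difference. Undo removes the last commit; on an empty stack it
warns and does nothing. Conservation (kept ∪ removed = defect, exactly at
voxel level) is a tested invariant.

**Minor cavity fill** is morphological closing: `offset(+d)` then
`offset(−d)`, finished by a union with the input — the union is a no-op in
the continuum (closing is extensive) and makes extensivity hold
voxel-for-voxel despite redistancing error. Crevices narrower than 2d
fill; the mouth where a crevice meets the outer surface keeps a fillet of
radius ≈ d (the meniscus), which is inherent to closing, so "fully filled"
is asserted on the region deeper than d and the refill fraction is
expected around 0.8–0.95 of the crevice volume depending on its
surface-to-volume ratio.

**Segmental fill.** The two section planes are intersected with the defect
mesh; segments are chained into closed curves with a welding tolerance of
10⁻⁶ of the mesh scale and ordered by enclosed area (the outer curve is
used when a section is hollow; the others are reported by a warning).
Both curves are arc-length resampled to `max(64, perimeter/h)` points, and
the moving curve's cyclic start index and orientation are chosen to
minimise the summed squared correspondence distance — this removes loft
twist and is deterministic. Intermediate sections are linear blends of the
two centered curves, scaled by the Bezier profile `s(t)` about their
centroid and placed on the centroid path (straight line, or the arc-length
parameterised guide curve with its endpoints pinned to the section
centroids; guide endpoints must come within `snap_tol`, default 5 mm, of
the centroids). Profile semantics: a scalar scale factor, end control
values pinned to 1 so the end sections mate with the bone exactly; a
waisted profile therefore scales the mid-section area by s(t)². The loft
(side strips plus centroid-fan caps) is voxelised by the standard mesh
conversion. Fan caps assume the section curves are star-shaped about their
centroid, which holds for long-bone cross sections; strongly non-convex
sections would need a real cap triangulation.

**Guided cavity fill** closes one-sided pockets: the mouth curve is the
smallest intersection loop whose centroid lies in void; the cavity side is
found by ray casting from the mouth centroid along the plane normal, and
the pocket depth from the farthest hit (a through-hole has no hit and
requires an explicit `depth`, giving a plug). The cap is flat by default;
guide curves lift it outward into a cone whose apex height is the largest
guide elevation above the plane (volume is monotone in that lift). The
fill is the mouth-connected component of (capped prism − bone).

**Insertion sweep and scaffold assembly.** With insertion travel direction
d (unit, toward the bone), the scaffold at a pose t mm before seating is
S − t·d, which collides with obstruction O iff S meets O + t·d: the
forbidden region is O swept *along* d for length L = `sweep_factor` ×
extent(obstruction along d), `sweep_factor` default 1.5. The sweep uses
the compounding schedule — steps h, 2h, 4h, … plus one final partial step,
`⌈log₂(L/h + 1)⌉` unions in total; axis-aligned steps are lattice-exact
(the suite asserts voxel-for-voxel equality with a brute-force per-voxel
union), oblique steps resample trilinearly. The scaffold is
`fill − offset(sweep(O, d, L), clearance)`: clearance (default 0.1 mm) is
applied by dilating the swept shadow, not by eroding the scaffold, so
flange and outer surfaces are preserved. Multi-piece designs split the
fill by half-space sign cells of the segmenting planes (voxel centers on a
plane go to the "below" cell; pieces are disjoint and union back exactly)
and each piece gets its own approach. Fixation flanges are user solids
unioned on; the demarcation plane (normal toward the flanges) marks the
region that later stays solid during porous conversion.

## Porous architectures

TPMS sheets: material where |F(2πx/cell)| ≤ iso. The iso ↔ wall-thickness
map is calibrated numerically once per variant: iso = t·π·⟨|∇F|⟩/cell with
⟨|∇F|⟩ the mean gradient magnitude on the F = 0 surface estimated from a
fixed-seed dense sampling of one period (gyroid ≈ 1.22). A network-solid
variant (F ≤ iso) is available behind the `sheet` flag. Lattices: distance
to the unit-cell edge network (SC = cube edges, BCC adds body diagonals,
FCC adds face diagonals), evaluated on coordinates folded modulo the cell
— by periodicity this equals the distance to the infinite tiling (verified
against explicitly tiled segments) — thresholded at half the strut
diameter. The lattice phase anchors at the solid's interior bounding-box
minimum corner. Voronoi: seeds drawn uniformly from interior voxels with
the spec's RNG seed (bit-reproducible), finite ridge edges clipped to the
solid bounds, struts shorter than one voxel dropped, thickened like
lattice struts. All architectures are intersected with the solid; an
optional outer contour shell (solid minus its erosion by
`shell_thickness`) is unioned on, and the flange region is restored to
full solid.

## Evaluation

Porosity = 1 − material/envelope with the sub-voxel volume measure. Pore
sizes use granulometry: the inscribed-sphere radius field (Euclidean
distance transform of the pore space), swept from the largest radius down;
a pore voxel's diameter is that of the largest opening containing it.
The histogram is voxel-counted (h³ per voxel), so it conserves the binary
pore volume exactly; boundary-open pores are included. Virtual insertion
retraces the scaffold backwards along −d in `steps` lattice-snapped poses
and reports the deepest reach of scaffold-interior voxel centers into the
obstruction's signed distance. Poses being lattice-snapped, a design built
by the shaping sweep measures exactly 0; the default collision tolerance
is h/2 — center sampling understates true depth by up to one voxel, so a
full-voxel tolerance could mask a genuine one-voxel violation, while h/2
still absorbs resampling noise of externally supplied geometry.

## DICOM overlay

The workflow never recenters or rotates anything, so scaffolds share the
CT's patient frame and the overlay needs no registration. Voxels whose
centers fall inside any scaffold mesh (same parity rasteriser, run in the
volume's index space via the direction cosines, so gantry-tilted series
work) receive +delta, saturating at the stored-type maximum; all other
voxels are bit-identical, and subtracting delta inside the mask recovers
the original data exactly. Export writes a fresh series (new Series/SOP
UIDs, geometry tags preserved); anonymisation clears a fixed list of
patient-identifying tags (name, ID, birth date, physician, institution,
…) shipped in `dicom_overlay.ANONYMISED_TAGS`. The default delta in the
demo case, 300, is ≈ 30 % of the synthetic CT's soft-tissue-to-bone range;
it is configuration, not a constant of the method.

## Synthetic fixtures

The generators emulate the three clinical situations end to end at adult
long-bone scale: `segmental_tube` (cortical tube, outer radius 15 mm, wall
6 mm, length 120 mm, 40 mm mid-shaft gap; exact watertight mesh),
`notched_tube` (the same tube with four 1 × 3 × 10 mm radial crevices, the
closing testbed), `cranial_plate` (spherical shell patch, curvature radius
60 mm, 5 mm thick, 10 mm through-hole) and `hardware_rod_plate`
(intramedullary rod plus plate and screws). The synthetic CT labels
air/soft/bone/metal by voxel-center containment with metal > bone > soft >
air precedence and optional seeded Gaussian noise. What these fixtures do
**not** emulate: real cortical/trabecular texture, segmentation noise and
staircase artefacts, HU calibration, or anatomically irregular defect
margins — passing tests demonstrate the geometric contracts of the
workflow, not segmentation robustness.

## Problem sizes and numerical choices

The default working resolution in the demo cases is h = 0.5–0.8 mm
(clinical CT order); the clearance validation designs the segmental
scaffold at h = 0.1 mm over a 33 × 33 × 50 mm window around the gap
(~55 M voxels), the finest grid the realised 0.1 mm clearance can be
meaningfully measured on. The closing-axiom validation runs on a 60 mm
notched tube at h = 0.25 mm: the closing operation is local to the
crevices at mid-shaft, so shaft length adds cost without information. Degenerate-face threshold 10⁻¹⁰ mm² (far below
h² for any sane h); printability self-intersection testing is exact
segment-triangle crossing over centroid-KD-tree candidate pairs, excluding
pairs sharing a vertex index; purely coplanar overlaps without an edge
crossing are not flagged (the duplicated-face check catches the common
case). All randomness (Voronoi seeds, CT noise, test oracles) flows
through explicit integer seeds; re-running a case file reproduces meshes
and reports bit-identically.

## Known limitations

- Voxel CSG: all guarantees are at the resolution h; sub-voxel features
  are lost and off-lattice rigid motions resample trilinearly.
- Fan caps in the segmental loft require star-shaped sections.
- The printability checker reports but does not repair; no slicing/GCode.
- No mechanical (FEA) evaluation of the designs.
- The Bezier profile acts as a scale about the section centroid; normal
  offsetting of the section curve is a plausible alternative semantics
  that was not adopted.
- When a section plane cuts a hollow bone, the outer intersection curve
  drives the loft (the medullary canal is bridged solid).
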