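# Methods

## Problem and model

A lateral closed-wedge high tibial osteotomy is modeled as two half-plane
cuts through a watertight triangle mesh of the proximal tibia, followed by
a rigid rotation that closes the resected gap. Everything is expressed in
a right-handed anatomical frame built from four landmarks (medial and
lateral plateau edge points, joint center, anterior direction): +x medial
→ lateral, +y anterior, +z distal → proximal, origin at the joint center,
millimetres throughout, degrees at interfaces and radians internally. The
superior-inferior axis is defined as the joint-plane normal, so "d mm
distal to the joint line" always means a perpendicular offset from the
(possibly tilted) joint plane; this is the reproducible reading of
cut-level prescriptions when the joint line is not horizontal.

### Plane constructions

* **Conventional** — proximal cut parallel to the joint plane, 10 mm
  distal to it; hinge at the medial end of the cut chord (medial cortex).
* **Oblique** — proximal cut through the medial cortex point 15 mm below
  the joint line and the lateral cortex point 35 mm below it; hinge at
  the medial cortex point.
* **Hybrid 3:1 / 2:1** — same oblique proximal cut; hinge at fraction
  f = 1/(1+r) of the chord from its medial end (f = 1/4 and 1/3). The
  ratio is read as lateral:medial, which is the reading under which the
  2:1 wedge is smaller than the 3:1 wedge and the medial-gap/lateral-wedge
  ratio is 1/9 for 3:1 on uniform sections; the alternative
  (medial:lateral) reading reverses the volume ordering and is rejected.

Cortex points are the extreme ML vertices of the mesh cross-section at
the given joint-plane-parallel level, projected to the coronal mid-plane;
hence both cutting planes contain the AP axis and the correction is purely
coronal (no slope change is modeled). The distal plane is the proximal
plane rotated by the correction angle θ about the AP line through the
hinge, signed so that it dives distally on the lateral side. The dihedral
angle between the planes therefore equals θ to machine precision, which
the plan validator enforces at 1e-9.

### Cutting and volumes

Slicing classifies vertices against the plane (vertices within 1e-9 mm
are snapped onto it) and is delegated to trimesh's half-space cut; the
open cross-section is then capped in-package: once-used directed edges
are chained into boundary loops, each loop is triangulated in the plane
chart (fan triangulation when the loop is convex, ear clipping with a
degenerate-ear fallback otherwise), and cap triangles reuse boundary
vertex indices so edge pairing — and hence topological watertightness —
holds by construction. Volumes come from the divergence theorem (signed
tetrahedra), exact for polyhedra up to floating point. Because both
halves of every cut are capped on the same polygon, volume conservation
(proximal + wedge + distal = original) holds to ~1e-12 relative and is
asserted at 1e-6 in tests. The saw kerf defaults to 0 mm, matching the
simulated protocol; a positive kerf symmetrically thickens each cut for
sensitivity studies (conservation then intentionally excludes the kerf
slabs). No mesh repair is ever attempted: a non-watertight input is an
error, because silent repair would corrupt the conservation checks.

The resected wedge is the dihedral region below the proximal plane and
above the distal plane; it lies lateral of the hinge automatically since
the planes cross along the hinge axis. The **medial gap** of a hybrid
closure is defined as the mirror dihedral: the region of the intact bone
above the proximal plane and below the medial extension of the distal
plane — the opening as measured in the distal fragment's frame. Under
this definition gap and wedge scale identically with the local bone
section, so on a uniform prism gap/wedge = (f/(1−f))² exactly (1/9 for
3:1, 1/4 for 2:1). The physically swept gap measured in the proximal
fragment's frame differs by a factor
(tan(θ−φ)+tanφ)/(tan(θ+φ)−tanφ), with φ the obliquity of the proximal
cut; the distal-frame definition is adopted because it is the one for
which the hinge-ratio arithmetic is exact and section-independent.

### Closure and non-overlap

Closure is the rotation by θ about the hinge axis mapping the distal
plane onto the proximal plane (verified as an isometry with < 1e-6 mm
point-plane deviation). Both cut faces are then 2D polygons in a common
chart of the proximal plane (hinge at the origin, +u along the
medial→lateral chord, +v anterior). Reported quantities:

* boolean overlap area and total proximal-minus-distal difference area
  (shapely);
* a scanline decomposition: at AP stations every 0.25 mm (checked against
  a 0.125 mm step), the ML length of the proximal face lying lateral
  (resp. medial) of the distal face's boundary, integrated over stations
  where *both* faces are present. Rim slivers where only one face exists
  contribute to the boolean difference but not to the lateral/medial
  strips — the decomposition isolates the clinically meaningful cortical
  step-off from anterior/posterior rim effects;
* mirror overhangs of the distal face beyond the proximal one, with a
  tag naming the protruding fragment (on a uniform prism the closed
  distal face is the longer one, by W(1/cosθ − 1)·D);
* a signed non-overlap: positive lateral overhang for conventional and
  oblique closures, negative medial opening for hybrids.

## Phantoms and the synthetic cohort

The parametric tibia is a stack of elliptical (optionally rectangular)
cross-sections whose ML width tapers from the plateau value to the shaft
value by a monotone smoothstep over the flare length, with AP depth
scaled proportionally (default depth/width = 0.75, a typical plateau
aspect ratio). Defaults: plateau width 70.8 mm, shaft width 32 mm
(≈ 0.45 × plateau, a typical diaphysis), flare length 70 mm, model height
110 mm — the metaphyseal flare of an adult tibia, under which the bone is
widest at the conventional cut level (10 mm) and still narrowing through
and below the oblique cut window (15–35 mm). That single feature drives
every qualitative technique difference: deeper-diving cuts remove less
bone (conventional > oblique > hybrid 3:1 > hybrid 2:1 in wedge volume)
and distal faces cut from narrower bone leave the proximal face partly
uncovered laterally. Varus enters only as a joint-plane tilt of
(90° − MPTA) about the AP axis; only the joint-line orientation enters
any plane construction, so shaft bow is not modeled. Condyles, the
tibial tuberosity, the fibula and cortical/cancellous distinction are
deliberately absent — none enters the plane constructions.

The cohort generator samples per-knee width, MPTA, JLCA, HKA and age from
truncated normals whose means, SDs and truncation bounds reproduce the
emulated population (width 70.8 ± 6.2 mm on [60.4, 80.7]; MPTA 82.1° on
[75.9, 87.7]; JLCA 4.4° on [0.1, 10.1]; HKA 10.5° on [5.1, 16.5]); where
only a mean and range are published the SD is back-computed as range/4
and left configurable. Sex is sampled at 5:6 male:female; body size and
sex are sampled independently, so sex-difference subgroup effects present
in real cohorts are *not* reproduced — subgroup machinery is exercised,
but its effect sizes on synthetic cohorts are uninformative. Each mesh is
deterministic given its record, and the whole cohort is bit-reproducible
from one seed.

Passing cohort-level tests therefore demonstrates the geometric
invariants (conservation, nesting, orderings, sign conventions) on
realistic morphology — not agreement with any particular patient series.
Absolute areas and volumes depend on individual bone geometry and are
expected to differ from published patient tables; what transfers are the
ratio semantics and orderings, which is what the acceptance checks pin.

## Statistics

Summaries report mean ± sample SD (n−1; undefined and reported missing
for n = 1) per technique × angle. Percent columns are ratios of cell
means — not means of per-knee ratios — because that is the convention the
emulated tables follow; display rounding is one decimal. Comparisons
default to the Mann–Whitney U test (exact null distribution when
min(n) ≤ 8 without ties, tie- and continuity-corrected normal
approximation otherwise), with pooled and Welch t-tests, uncorrected
Pearson χ² and the two-sided conditional Fisher exact test available;
all via scipy, cross-checked in tests against brute-force enumeration
oracles for every two-group design with group sizes up to 8.
Significance is p < 0.05, strict. Subgroup thresholds are inclusive on
the pathological side: MPTA ≤ 83° is vara, JLCA ≥ 7° is high.

## Numerical choices and problem sizes

* Phantom discretization: 64 points per ring, 2 mm ring spacing
  (≈ 7k faces). The multi-seed sweep test uses 32 points / 3 mm, a pure
  discretization choice that leaves all tested invariants intact.
* Scanline step 0.25 mm; tests that check only signs or identities use
  coarser steps.
* Tolerances: watertightness and winding are hard requirements; plan
  validation at 1e-9 (angles) and 1e-6 mm (incidence); conservation
  asserted at 1e-6 relative; closed-form prism oracles at 1e-6 relative.
* Tie-breaks: vertices on a cutting plane count as the positive side;
  extreme-cortex ties on flat silhouettes resolve to the same ML
  coordinate, and the point is projected to the coronal mid-plane before
  use.
* Degenerate inputs: empty cross-sections, planes missing the mesh,
  collinear landmarks, inverted orientation and non-manifold boundaries
  all raise typed errors rather than being repaired.

## Known limitations

* The phantom is convex-sectioned and unimodal; real tibiae have
  non-convex sections (tuberosity) and per-patient asymmetry, so absolute
  metric levels are not transferable.
* The medial-gap definition is exact for the hinge-ratio arithmetic but
  is one of several defensible readings of "the medial opening"; the
  proximal-frame swept volume is smaller by the factor given above.
* Non-overlap of hybrid closures counts the whole uncovered medial strip
  of the proximal face; operational definitions that exclude part of that
  strip would report smaller magnitudes. The scanline/boolean/strip
  decomposition is reported in full so any such convention can be
  recovered downstream.
* Biplanar (tuberosity-sparing) cuts, fibular osteotomy, posterior slope
  changes, fixation hardware and any mechanics (hinge fracture, contact)
  are out of scope.
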