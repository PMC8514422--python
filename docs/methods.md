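# Methods

## Model

A motion segment is two watertight triangle meshes (mm units) in a manually
articulated neutral pose — endplates parallel, facets maximally overlapped —
plus a joint coordinate frame and ten anatomical landmarks.  The frame's
origin is the centre of rotation (COR); its x-axis is the centrum long axis
(axial rotation), y dorsoventral (lateral bending), z mediolateral (sagittal
bending).  The anterior vertebra is fixed; the posterior vertebra, with its
five landmarks, is one rigid body.

Bending is a pure rotation about one frame axis through the COR.  At every
probe angle θ = k·increment the rotation is composed fresh from the neutral
pose (never accumulated increment-by-increment), eliminating floating-point
drift.  Probing continues until a constraint is violated; the result is the
last non-violating angle — the pose actually attainable — and the violating
labels.  When no constraint fires the run stops at the cap.  Coupled
motions (simultaneous rotation about two axes) are out of scope.

### Constraints

* **Bony intersection.**  The surface area of the boolean intersection
  solid of the two meshes, compared against
  `intersection_threshold × mean vertebral surface area`.  Surface area is
  the thresholded quantity by default; volume is recorded alongside and a
  config switch (`intersection_measure`) allows thresholding on volume
  instead, since "area of the intersection object" is ambiguous for legacy
  workflows built on DCC-tool booleans.
* **Zygapophyseal strain.**  s = (d − d₀)/d₀ on the craniocaudal (frame-x)
  component of the separation of one left-side facet landmark pair,
  referenced to neutral.  s below the lower bound labels
  `zyg-disarticulation`, above the upper `zyg-overlap`.  The absolute value
  of the x-component is used so landmark ordering cannot flip signs.  An
  optional bilateral mode is not enabled by default, mirroring the
  single-pair protocol the landmark schema encodes.
* **Centrum strain.**  The same fractional-change test on the Euclidean
  distances of the four endplate pairs (dorsal, ventral, left, right);
  any pair beyond the upper bound labels `centrum-tension`, below the lower
  `centrum-compression`.

All enabled constraints are evaluated in all six directions — which
constraint stops which direction is an outcome of the geometry, not
hard-coded.  Simultaneous violations are all recorded; for single-label
reporting (result CSVs, tallies) ties resolve by the fixed priority
intersection > zygapophyseal > centrum.

### Translation relief

Optionally, when *only* intersection fires at a probe angle, the posterior
body is shifted perpendicular to the rotation axis toward the side it is
swinging (dorsal/ventral along y for sagittal bending, mediolateral along z
otherwise), and the same angle is re-tested once.  The shift persists for
subsequent angles.  `translation_fraction` is the **total** budget as a
fraction of √(mean area); the default step consumes the whole budget in
one relief, and `translation_step_fraction` allows smaller steps under the
same cap.  Whether rotation may continue past several successive reliefs
is a genuinely open protocol question; one-relief-per-angle with a capped
total is this package's declared interpretation, and it is configurable.
Translation defaults to 0 (off).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `increment` | 0.5° | probe step; stop angles are multiples of it |
| `max_angle` | 45° | cap when no constraint fires |
| `intersection_threshold` | 0.0025 | fraction of mean vertebral surface area |
| `zyg_bounds` | (−0.5, +0.5) | facet strain band |
| `centrum_bounds` | (−0.5, +0.5) | endplate-pair strain band |
| `translation_fraction` | 0 | total relief budget, fraction of √area |

The defaults are the best-estimate modelling conditions for amniote trunk
joints: COR within the disc, no translation, ~50% strain permitted at both
facet and centrum, and a small nonzero intersection allowance.  The
sensitivity design varies joint spacing by ±10% of mean spacing,
intersection threshold between 0.25% and 0.5%, and both strain bands
between ±45% and ±55% — a 2³ factorial, eight bending runs per joint.
"Spacing" is quantified as the mean of the four centrum landmark-pair
distances, and a spacing change translates the posterior body along frame
x and re-references all strains to the shifted pose.

## Geometry backends

No mesh-boolean library is part of the dependency set, so intersection
measurement is implemented here with two backends:

* **convex-exact** — used when every connected component of both meshes is
  convex (true for all synthetic fixtures).  Each cross pair of components
  is intersected as a halfspace system: hull planes from both pieces, a
  Chebyshev-centre LP for a strictly interior point (LP radius ≤ 1e-9 ⇒
  empty or merely touching ⇒ area 0), then `scipy` halfspace intersection
  and convex hull for exact area and volume.  Components within one body
  are kept disjoint, so summing pairwise results is exact.
* **voxel** — fallback for non-convex or non-watertight bodies: occupancy
  sampling on a grid (ray-parity point-in-mesh, vectorized
  Möller–Trumbore), marching-cubes surface area and voxel-count volume.
  Default pitch √(mean area)/200, chosen so 0.25%-of-area thresholds are
  resolvable; the grid is coarsened above 2×10⁶ cells.  Voxel results are
  flagged in statuses, manifests, and result rows.

Sphere fitting for COR placement solves the linear algebraic system; four
points give the exact interpolating sphere, more give the least-squares
sphere, and coplanar/coincident configurations are rejected (rank test)
rather than guessed.

## Synthetic segments

`make_block_segment` emulates a motion segment with two cuboid centra
(defaults 10 × 8 × 15 mm — a mid-lumbar joint of a mid-sized quadruped)
separated by a 2 mm gap, plus dorsal zygapophyseal tabs whose craniocaudal
overlap (2 mm) is the facet reference length and whose dorsoventral
clearance (0.4 mm) forms the facet joint space.  The COR sits at mid-gap on
the centrum axis (the disc-centred convention).  Landmarks are placed
analytically: the four centrum pair distances all equal the gap, every
landmark lies on the mesh, and neutral strain and intersection are exactly
zero.  Optional seeded vertex jitter (re-hulled per component, so pieces
stay convex) reproduces the "uneven surfaces stop motion prematurely"
rationale for nonzero intersection thresholds; jitter forfeits the analytic
ground truth, which is reported as `None`.

Because every rigid piece is a box and each bending rotation preserves one
coordinate, first bone-contact angles reduce to 2D rotating-rectangle
problems solved in closed form: candidate angles where a vertex trajectory
crosses an edge line (a·cosθ + b·sinθ = c), screened for true penetration a
short step (2×10⁻⁴ rad) past each candidate, since penetration area grows
only quadratically past a grazing event.  The closed form agrees with a
0.01° fine-sampling oracle to better than 0.02°.

`make_vertebra_segment` is a realistic-shape smoke fixture (cylindrical
centrum, arch block, facet tabs) assembled from disjoint closed convex
primitives rather than a fused union, keeping the exact backend applicable.

What the generator does *not* emulate: concave articular surfaces
(procoelous ball-and-socket joints), asymmetric or obliquely oriented
facets, natural surface roughness at realistic amplitude, and
craniocaudally varying morphology.  Passing tests therefore demonstrate
the correctness of the kinematics, constraint logic, and bookkeeping — not
that any particular biological magnitude is recovered for real vertebrae.

## Analysis conventions

* Lateral and axial mobility are reported as left + right (identical to
  the mean of the two sides doubled); sagittal as dorsiflexion +
  ventroflexion.  The identities are exact, not approximate.
* Constraint tallies count each (joint × variant × direction) run once,
  under the priority rule, so proportions per direction sum to 1.
* Effect sizes are sequential (type-I) sums of squares from an OLS fit
  (joint, direction, joint×direction, then the factorial parameters coded
  low/high).  Only balanced tables are accepted — there all classical
  ANOVA types coincide — and imbalance is an error naming the offending
  cell, never a silent reinterpretation.  No p-values are reported.
* The stiffness force proxy is the rectangle cross-section h×w to the
  power 3/2 (the arithmetic of the reference example forces the rectangle,
  not an ellipse).  `printed_arithmetic=True` rounds the force and the
  final quotients to integers, matching the reference calculation chain
  digit for digit; full precision is the default for analysis.  Because
  the published phrasing "logged and scaled by centrum length" is
  ambiguous, both `log10(v)/L` (default) and `log10(v/L)` normalizations
  are implemented and the mode is recorded in output metadata.

## Numerical choices

* Strains at neutral are exactly 0 by construction (references are cached
  from the same coordinates the evaluator reads).
* LP/hull degeneracy tolerance 1e-9 mm; frame orthonormality tolerance
  1e-6; rigid transforms preserve pairwise distances to 1e-9 relative.
* Stop angles are exact multiples of the increment; determinism is total
  (no randomness anywhere in the engine; the only seed in the package
  belongs to the synthetic generator's jitter).
* Hierarchical chaining composes world transforms cranial→caudal for
  export and visualization, but per-joint oROM is always computed from the
  joint's own neutral pose: a rigid rotation upstream cannot change a
  downstream joint's admissible angles, and per-segment evaluation keeps
  results independent of column context.

## Test problem sizes

The oracle-equivalence suite uses 20 randomized block segments (centra
6–14 mm, gaps 0.5–2.5 mm) against a 0.01° separating-axis fine-sampling
oracle; property suites use 5-segment batches.  These sizes give full
six-direction coverage while keeping the default test run in well under
two minutes.

## Known limitations

* No coupled-axis motions; each direction is probed independently.
* Strain bands assume uniform soft-tissue properties across joints,
  directions, and species.
* The voxel backend's area estimate carries marching-cubes surface bias
  (~a few percent at default pitch); it is flagged, and thresholds near
  the flagged regime deserve a convex re-mesh or a finer pitch.
* Real neutral-pose articulation (endplates parallel, facets maximally
  overlapped) is a curation step upstream of this package; garbage
  articulation yields garbage oROM.
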