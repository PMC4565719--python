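# Methods

## Geometric conventions

All geometry is in centimetres, masses in kilograms, densities in kg m⁻³
(the cm³→m³ factor 10⁻⁶ is applied inside `mass_properties`). Meshes are
`trimesh.Trimesh` objects constructed with `process=False`, so vertex and
face order — and therefore every downstream number — is deterministic.
Watertightness is a hard precondition for mass properties (violations
report the open-edge count); elsewhere it is only needed where containment
is queried. The body frame is x cranio-caudal (cranial positive),
y medio-lateral, z dorso-ventral, origin midway between the hips in the
reference pose.

## Mass-property kernel

Volume and volume centroid come from the divergence theorem over surface
triangles (via trimesh). Mesh–mesh intersection, minimum distance and
containment are computed with the package's own exact triangle primitives:
Möller–Trumbore segment–triangle piercing (inclusive at borders, so
touching counts as contact), the 15-feature triangle–triangle distance
(6 vertex–triangle + 9 edge–edge), and generalized winding numbers for
point containment, all under AABB broadcast pruning. Containment counts as
intersection: a bone entirely inside another is a collision. Sphere fitting
uses the linear algebraic least-squares formulation — exact on noise-free
spherical data, deterministic, initialisation-free — with an optional
geometric (orthogonal-residual) refinement stage; reproducibility is the
reason the algebraic route is the default.

## Body-shape model

A hoop is an octagon with cardinal vertices at ±a (lateral) and ±b
(dorso-ventral) and diagonal vertices at k·(±a/√2, ±b/√2). Its area has the
closed form 2√2·k·a·b. k interpolates the cross-section profile: 1/√2 is a
diamond, 1 an ellipse-like octagon, √2 a square. The calibration factors
for "intermediate" profiles are midpoints of the elliptical factor and the
extreme: (1+√2)/2 ≈ 1.2071 (ellipse–square) and (1+1/√2)/2 ≈ 0.8536
(ellipse–diamond), i.e. the 120.7% / 85.3% diagonal scalings.

Lofting joins corresponding vertices of consecutive hoops with quad strips
(split to triangles) and closes the ends with fans; for prisms the volume
is exactly hoop area × length, and for linearly tapered segments the quad
split's slivers cancel, so the loft volume equals the slice integral
∫A(t)dt exactly — both facts are exploited as test oracles. A heuristic
warns when consecutive hoop planes tilt enough to self-intersect. Hoop
count and placement are user inputs (synthetic bodies default to 8–16 per
segment); cavities (oropharynx, lungs) are handled by mass-property
subtraction — V ← V−V_c, CoM ← (V·r − V_c·r_c)/(V−V_c) — after a
containment check, which is exactly equivalent to a boolean subtraction
for contained cavities and numerically far more robust.

The outline envelope applies max (semi-axes ×1.2, k = 1.2071) and min
(semi-axes ×1.0, k = 0.8536) variants about each hoop's own centre. The
canonical whole-body models are max-overall, min-overall, max-cranial
(max neck/trunk/pectoral with min pelvic/tail) and max-caudal (the
converse); the mean model is the arithmetic mean of the min- and
max-overall models' mass and CoM, the reading that reproduces the published
mean values. The head is held at its single configured outline in all four
combinations because published segment tables list a single head row; the
library still accepts pre-varied head specs if a user wants to vary it.
Bilateral segments (count = 2) contribute mirrored CoMs (x, ±y, z), which
cancels the whole-body y-coordinate exactly for symmetric bodies.

## Retrodeformation

The deformation model is a single global affine map, which is exact under
the homogeneous-deformation assumption for a fossil-bearing stratum; the
free-form lattice deformers used interactively in modelling software reduce
to this affine map when the lattice is driven only by the axis triad.
Rule 1 computes the unique affine map sending the fitted (distorted) triad
vectors onto an orthonormal target triad and origin onto origin; if the
specimen was distorted by D and the triad is fitted as D applied to the
true axes, the correction is exactly D⁻¹, hence the machine-precision
round-trip tests. Rule 2 measures a section's lateral and dorso-ventral
diameters as extents of the section polyline along given directions (a
deterministic operationalisation of "looks round" — no ellipse fit) and
stretches along the dorso-ventral axis by lateral/dorso-ventral, which
forces post-correction roundness 1 and preserves perpendicular extents
exactly. The reciprocal cross-check stretches a reference element along its
own compaction axis by the same factor and compares per-axis extents at a
configurable relative tolerance (default 5%).

## Joint mobility

The ACS origin is the fitted sphere centre of the selected proximal
joint-surface vertices (vertex selection is an explicit input — there is no
robust automatic definition of "the joint surface"). Axes are built by
Gram–Schmidt: the long-axis hint is taken exactly as x, the up hint
projected to y, z = x×y (y flipped if needed so z points cranially).
Directions map as: abduction +z, adduction −z, retraction +y, protraction
−y, LAR ccw +x, cw −x (right-hand rule; cw/ccw labelled for a right limb
seen from the right with the head to the right).

Joint space is imposed by translating the bone (and its rotation centre)
outward along the line from a socket reference point through the head
centre — under this reading mobility grows monotonically with joint space,
the pattern observed in practice. Each of the six directions is swept
independently about a single fixed ACS axis from the reference pose in
fixed increments; the reported limit is the last collision-free multiple of
the increment (conservative by ≤ 1 increment), with caps of 360° for LAR
and 180° otherwise by default. A collision already at the reference pose
reports 0° with a flag. Sweeps are entirely deterministic.

Collision testing exploits an invariant of single-axis sweeps: rotation
about the ACS axis preserves every point's cylindrical coordinates (height
along the axis, radius from it), so feature pairs whose (h, ρ) intervals
are disjoint can never collide in any pose and are pruned once per sweep;
surviving pairs get an AABB filter plus exact piercing per pose. This makes
dense sweeps of finely meshed joints tractable on one CPU.

The default increment is 0.1°; the shipped tests and the acceptance script
sweep at 1.0° with a 0.1° brute-force sweep as the agreement oracle, a
resolution at which fixture faceting (well under 0.5° of contact-angle
error at the default mesh resolutions) stays below one increment.

## Synthetic specimens

`synthetic_specimen` generates every fixture procedurally and attaches its
ground truth, so the full pipeline is testable without fossil data:

* **toy body** — six regions of prismatic hoop segments (trunk+tail about
  half a metre, a few kg at unit density: small sprawling tetrapod scale);
  prisms make volume and CoM closed-form.
* **socket joint** — spherical head (radius 1 cm) with faceted shaft
  (neck radius 0.35 cm) in a spherical-shell cup (clearance 0.05 cm,
  default coverage 90° from the pole); an optional rim lip extends coverage
  over an azimuthal sector. The analytic first-contact angle of the shaft
  against the rim — atan2 of the rim point relative to the offset head
  centre minus arcsin(neck radius / distance) — is exact for the smooth
  geometry and is the certification oracle for the sweeps. Cups covering
  more than 90° overhang the head, which genuinely limits how much joint
  space can be imposed before contact; lipped fixtures therefore keep total
  coverage at 100°.
* **vertebra / skull pair** — a circular-centrum cylinder stand-in and a
  bilaterally symmetric ellipsoid-with-bosses skull stand-in (synthetic,
  mirror plane y=0) for the distortion rules.
* **distortion** — uniaxial compaction followed by shear, with the exact
  inverse recorded; random distortions are seeded and re-drawn only if the
  shear determinant falls below 0.05 (ill-conditioned).

What these fixtures do *not* emulate: real bone shapes, fragmented or
incomplete elements, heterogeneous deformation, CT segmentation artefacts,
or soft-tissue constraints on joints. Passing tests therefore certify the
geometric operators and their composition, not the anatomical judgement
(hoop placement, joint-surface selection, triad fitting) that real
specimens require. Absolute mobility angles of any real taxon are outside
scope: they require the actual bone meshes.

## Numerical choices and limitations

* Contact tolerance 10⁻⁹ cm; piercing tests are inclusive at triangle
  borders so grazing contact counts as collision (distance 0 ⇔ intersect).
* Reflections flip face winding on application so outward orientation (and
  positive signed volume) is preserved.
* Degenerate inputs raise explicit errors: coplanar sphere-fit points,
  singular transforms, non-advancing hoop centres, coincident socket/head
  centres, cavities not contained in their segment.
* Whole-body composition is exact arithmetic; its accuracy on real data is
  limited by the segment volumes, i.e. by outline choices — hence the
  min/max envelope rather than a single estimate.
* The sweep reports bone-on-bone limits only; translational joint motion
  and soft tissues are deliberately ignored.
* Problem sizes used by the shipped tests and acceptance script (joint
  meshes of ~2–4 k triangles, 1° sweeps, 6 joint spaces) were chosen so the
  faceting error stays well inside one sweep increment while the whole
  suite remains comfortably fast on a single CPU.
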