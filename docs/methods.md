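# Methods

## Problem

In transtibial posterior cruciate ligament (PCL) reconstruction a bone tunnel
is drilled through the proximal tibia so that the graft exits at the tibial
PCL attachment on the posterior intercondylar slope. Steeper tunnels reduce
the "killer turn" — the sharp graft bend at the posterior aperture — but an
over-inclined tunnel breaches the posterior tibial cortex and endangers the
popliteal neurovascular bundle. The quantity of interest is therefore the
**permissive safe angle (PSA)**: the largest angle between the tunnel
centerline and the medial tibial plateau plane such that a 5-mm-radius
cylinder with its exit fixed at the PCL attachment leaves the posterior
cortex intact. Alongside it the pipeline reports the **tunnel height TTH**
(entry point to plateau plane) and **tunnel depth TTD** (entry-to-exit
length), for each of the five classical entry approaches:

| approach | entry position |
|---|---|
| T1 | anterior 1/3 of the anteromedial cortical flat |
| T2 | midpoint of the anteromedial flat |
| T3 | midpoint of the tibial crest |
| T4 | anterior 1/3 of the anterolateral flat |
| T5 | midpoint of the anterolateral flat |

The "anterior 1/3" is measured from the crest-side end of each flat.

## Synthetic anatomy

Clinical CT data are not required: the `synthetic` module builds parametric,
watertight proximal-tibia meshes with analytic ground truth. The axial
cross-section is the classical rounded triangle of the proximal tibial
shaft: an oblique anteromedial flat (default 50° to the posterior tangent),
a near-perpendicular anterolateral flat (default 84°), a filleted crest
(radius 8 mm) and a shallow posterior parabolic arc (sagitta 3 mm over a
56-mm posterior width). The profile is lofted along the shaft axis with a
mild linear distal taper (0.92 at the distal end), a metaphyseal flare
(×1.10) and a "condylar rounding" morph that blends the polar radii of the
outline toward a circularly smoothed version over the top 18 mm, so the
plateau outline is convex and oval rather than triangular. The plateau cap
is a plane with a configurable posterior slope (default 6°).

The posterior metaphysis carries a champagne-glass drop-off: the posterior
rim overhangs, and below it the surface recedes anteriorly at
`facet_tilt_deg` (default 10°) until the straight posterior cortex resumes
at a corner ring `attachment_facet_height` (default 21 mm) below the rim.
The PCL attachment center **B** sits on that sloped facet
`attachment_depth` (default 4.5 mm) below the rim, slightly medial of the
midline (`attachment_x_offset`, default +5 mm). The chamfer is tapered in
the medial–lateral direction (full within ±10 mm of the attachment, zero
beyond ±22 mm) so the condyles flanking the fossa keep their posterior
extent. B is computed on a mesh vertex track, so it lies exactly on the
surface; the corner ring, cortex-flat directions, plateau rim polyline,
plateau-plane normal and per-level cross-section areas are stored as ground
truth for the downstream stages' tests.

`global_scale` multiplies every vertex coordinate, giving an exact isotropic
scaling law. The cohort sampler draws sex (38% male), age (uniform 16–60),
sex-conditional heights (male 1.72 ± 0.055 m, female 1.60 ± 0.055 m), maps
height to scale affinely (proportional, unit scale at 1.66 m), and jitters
the shape parameters subject-to-subject. The attachment facet parameters are
divided by the subject's scale, i.e. the facet has a roughly fixed absolute
size across statures — ligament insertions vary far less than bone length —
which is what makes the cohort PSA independent of height while TTH and TTD
grow with it.

### Calibration

The default shape parameters were calibrated once, and frozen, so that the
five approach-mean PSAs of the default cohort fall in the clinically
reported band (≈46–62°, anteromedial > crest > anterolateral ordering).
The ordering is not imposed; it emerges from the entry azimuth relative to
the attachment's sagittal plane: because B sits slightly medial,
anteromedial entries are nearly sagittal while anterolateral entries
approach the exit obliquely, which lowers their tangency angle.

## Pipeline

1. **Cross-sections and entry tracks.** Axial slices (trimesh plane
   sections) give closed outlines; maximal straight vertex runs
   (chord-deviation growth, tolerance 0.25 mm, minimum 5 mm, endpoints
   refined against a total-least-squares line) identify the two flats; the
   posterior tangent is the support line perpendicular to the anterolateral
   flat; the crest arc is the shorter polygon path between the flats'
   anterior ends. Entry points per slice give one polyline track per
   approach (1-mm spacing, linearly interpolated); circumferential identity
   is kept by the fractional position along each flat.
2. **Plane M.** The medial plateau rim is the boundary of the largest
   connected upward-facing surface patch (normals within 45° of +z)
   restricted to x > 0; a total-least-squares plane orients the frame, a
   least-squares circle (Kåsa fit plus one Gauss–Newton step) halves the rim
   into anterior/posterior parts; E and G are the rim vertices of maximal
   elevation in each half (ties broken toward the anterior/posterior
   extreme), F the most medial rim vertex; plane M passes through E, F, G
   with a proximally oriented normal.
3. **Tunnel solving.** The posterior cortex is sampled deterministically:
   per eligible face (outward normal within a cone of the posterior
   direction, below plane M) a barycentric lattice (≥ 4 points/mm² by
   default; the cohort pipeline uses 24 points/mm²),
   plus all face vertices and edge midpoints so sharp cortical edges are
   exact. The clearance of a candidate tunnel is the minimum point-to-segment
   distance minus the radius. The exit-aperture region is exempted: a sphere
   of radius + 1 mm around B, and — on facet-bearing anatomy — the facet
   band above the cortex corner within a horizontal radius (default 16 mm)
   of the exit, because the oblique drill exit is an oval that can run far
   along the facet and is aperture, not breached cortex. The solver scans the
   track from its proximal end distally (2-mm steps) and bisects the first
   sign change of clearance to 0.01 mm; the result is the most distal — most
   inclined — feasible entry, tangent to the cortex within the clearance
   tolerance (0.05 mm). A non-monotone scan (possible for strongly azimuthal
   approaches whose shallow end grazes the wall) falls back to a full-grid
   search and is flagged.
4. **Measurement.** PSA = arcsin(|axis · n̂_M|); the classical witness
   (plane N through the centerline perpendicular to plane M, S the
   centerline–plane intersection, P on the M∩N line, PSA = ∠ASP) is built
   for parity and agrees with the closed form to 1e−9 degrees. TTH is the
   unsigned entry-to-plane distance, TTD the entry-to-exit length. When the
   exit lies on plane M, TTD·sin(PSA) = TTH exactly; on solver output the
   residual of that identity equals the exit's off-plane offset.
5. **Statistics.** One-way fixed-effects ANOVA, pooled-variance t-tests and
   ICC(2,1) (two-way random, absolute agreement, single measure; graded
   poor / fair-to-good / excellent at 0.40 / 0.75) are computed from sums of
   squares; compact letters use the insert-and-absorb algorithm over a Tukey
   HSD p-matrix (scipy); sample size inverts noncentral-F power
   (λ = f²N, df = (k−1, N−k)). The subgroup report tabulates sex t-tests and
   age-group (16–30 / 31–45 / 46–60) and height-group (<1.60 / 1.60–1.70 /
   >1.70 m) ANOVAs for PSA/TTH/TTD × T1–T5.

## Numerical choices

- Slice step 1 mm (scaled with the subject); flatness tolerance 0.25 mm;
  run-endpoint refinement tolerance 0.05 mm.
- Posterior sampling is fully deterministic (no RNG), so solves are
  reproducible bit-for-bit and robust to mesh I/O round-trips; STL/PLY store
  float32, which perturbs a re-measured PSA by well under 0.001°.
- The pipeline widens the posterior normal cone to 75° and places the
  aperture cutoff 0.5 mm above the cortex corner so that face membership and
  the binding ring do not sit on a threshold knife-edge.
- Bisection tolerance 0.01 mm ⇒ PSA resolution ≈ 0.003°; halving the
  pipeline sample density and doubling the bisection tolerance moves PSA by
  < 0.2° (grazing anterolateral contacts are the binding case for this).
- Left knees are mirrored across the sagittal plane into the right-knee
  frame on input.

## Problem sizes used in the shipped checks

The test-suite and the acceptance script run: the slab oracle at four gap
values (~60 k samples each), one default subject, a 30-subject cohort
(five approaches each), 120 random shape draws for the watertightness
property, 10 000 Monte-Carlo ANOVA draws for the power cross-check, and 200
permutations for the null-uniformity check.

## What the synthetic cohort does and does not show

The generator reproduces the geometric mechanisms — entry-azimuth dependence
of the safe angle, scale dependence of lengths but not angles, the
tangency condition at the posterior cortex — and the calibrated defaults
place the approach means in the clinically reported band with the reported
ordering. It does not model real cortical thickness, subject-specific
plateau morphology, osteophytes, or the manual variability of locating the
attachment on sagittal images; absolute TTH/TTD levels depend on the
stylized profile (the crest approach, T3, is noticeably deeper here than in
clinical tables because the stylized crest sits far anterior). Passing tests
therefore validate the algorithms and their invariances, not clinical
values.

## Known limitations

- The breach criterion is sample-based; its aperture exemption
  (sphere + facet band) is a modeling choice standing in for the visual
  "no breakage" check of the original workflow.
- PSA is not exactly size-free on a full re-solve of a scaled subject,
  because the drill radius and aperture allowances are fixed in mm; the
  cohort-level independence of PSA from height is a property of the
  population model (fixed-size facet), not of single-bone scaling.
- The compact-letter display can require multiple letters per level for
  intransitive significance patterns; such patterns are flagged.
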