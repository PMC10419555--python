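# Methods

This note documents the models, conventions and numerical choices behind
`craniosym`, and what its synthetic cohorts do and do not establish about
real data.

## Canonical head frame

All measurements and asymmetry scores are expressed in a canonical frame:
midsagittal plane `{x = 0}`, +x toward the anatomical left, +y superior,
+z anterior, origin at the otobasion-inferius (earlobe-attachment)
midpoint projected onto the plane. The plane is estimated from the 11
bilateral landmark pairs: its normal is the dominant singular direction of
the sign-aligned unit right-minus-left difference vectors, and it passes
through the centroid of the pair midpoints. This gives a closed-form,
testable estimator with the midpoint property (translating one side by d
along the normal moves the plane by d/2).

Only the axis *signs* are anatomically forced (vertex above gnathion,
pronasale anterior of opisthocranion); the in-plane rotation is a
convention. We take the anterior axis from the projected
pronasale–opisthocranion chord — the anthropometric horizontal — and get
the vertical by right-handedness. Deriving "up" from the vertex–gnathion
chord instead would tilt the frame by 10–20° (the vertex sits well
posterior of the chin) and bias the head-height metric H by several mm.
All 14 measurements are rigid-motion invariant, so the convention only
matters for the asymmetry origin and for H/L/W, which are frame-relative
by definition.

Signed line-offset parameters (Sn ⊥ N-Pg, Pg ⊥ N-B) take their sign from
the intrinsic anterior direction (unit pronasale-minus-opisthocranion),
positive = anterior, so maxillary/mandibular retrusion is representable;
cohort tables report the signed value. The measurement of a mirrored
subject is identical parameter-by-parameter because every parameter is
either midline-defined or reported as the left/right mean (gonial angle
and mandibular body length are computed per side).

## Symmetric template and correspondence

The analysis template is an analytic, exactly mirror-symmetric head: a
superellipsoid (semi-axes 80/112/90 mm, exponent 1.90) blended with
azimuth-even Gaussian nose and chin protrusions, sampled pole-to-pole on
an azimuth × polar grid (default 48 × 32, 1490 vertices) and built as a
half mesh plus its exact mirror copy. The mirror map is an exact
involution on vertex indices; the quad diagonal split is itself mirrored
across the midsagittal plane so the piecewise-linear *surface*, not just
the vertex set, is exactly symmetric (without this, quad non-planarity
leaves a ~7 µm left/right discrepancy that destroys exact-null
asymmetry). The shape exponent is calibrated so a generated head at the
published mean height/length/width encloses the published mean cranial
volume (~3.54 × 10³ cm³).

Anchors for the 37 anatomical landmarks sit at nominal anatomical
directions snapped to distinct grid vertices (right side snapped, left
side the exact mirror vertex); 40 skull-layer anchors (4 rings × 10
azimuths between the otobasion-superius level and the vertex) complete
the 77-point control set. Fitting a subject proceeds in three steps:

1. **Size**: anisotropic scaling matching the gonion-pair width, the
   vertex–gnathion height and the pronasale–opisthocranion depth. The x
   scale acts symmetrically about the plane, so the mirror pairing
   survives exactly.
2. **Warp**: a 3D thin-plate spline on the 77 paired landmarks, kernel
   U(r) = r, solved from the standard augmented linear system with
   vanishing zeroth/first kernel moments. λ = 0 (exact interpolation) by
   default and configurable; bending energy is −tr(WᵀKW) ≥ 0, zero
   exactly for affine control relations.
3. **Project**: every template vertex finds the globally nearest point on
   the subject's triangulated surface (point-to-triangle Voronoi-region
   projection). The search is accelerated by a KD-tree on face centroids
   with a provably safe candidate radius (exact distance to the k nearest
   centroids bounds the answer from above; every face whose centroid lies
   within that bound plus the largest centroid-to-corner radius is
   checked exactly), so it is bit-identical to the brute force, including
   the lowest-face-index tie-break. The method is single-pass by design;
   an opt-in iteration count re-projects the deformed template.

## Asymmetry scoring

For each off-midline mirror pair (i, m(i)) the score is
|‖p_i − o‖ − ‖p_(m(i)) − o‖|, the absolute difference of the matched
surface points' distances from the canonical origin; midline
(self-paired) vertices are excluded. AH is the mean over all pairs, AF
the mean over pairs whose representative lies in the facial region
(distance to pronasale ≤ distance to gnathion, boundary inclusive — a
half-space test against the perpendicular bisector plane). A
point-to-point alternative (mirror the left match, measure its distance
to the right match) is available behind a flag for sensitivity analysis.
Heat maps assign each vertex its pair value (midline 0) on a fixed 0–5 mm
colour scale so maps are comparable across subjects and groups; group
maps average per-vertex values over the class.

One property of this statistic deserves emphasis. For a radial surface
offset δ about the origin, closest-point projection of a query that does
not lie on the offset surface slides tangentially and recovers
δ·cos²θ, where θ is the local angle between the surface normal and the
origin ray; about the otobasion-level origin the head-averaged cos²θ is
≈ 0.92, and warp non-tracking between landmarks dilutes a hard radial
offset further (to ≈ 0.8 δ through the full pipeline). The recovery tests
therefore isolate the statistic on surfaces the correspondence can track
(template versus an independently, more finely sampled copy of the same
analytic surface), where the error is faceting/obliquity-dominated
(−5…−7% across δ = 0.5–4 mm). Relative comparisons between groups, which
is how the asymmetry summaries are used, are unaffected by a common
multiplicative response.

Head metrics: H = y(vertex) − y(gnathion) (landmark-based), L and W are
the mesh z/x extents, V the signed-tetrahedron enclosed volume, reported
in cm³ (a watertight mesh is required and enforced).

## Synthetic cohort generator

The generator is the study-conditions stage: everything downstream is
exercised against cohorts whose structure matches the published group
statistics of 139 Taiwanese 9-year-olds (class I 38 M / 36 F, class II
24 / 26, class III 4 / 11; ages 9–10 with P(10) = 0.13).

**Parameter draws.** Each class × sex cell draws the 14 parameters from
normal distributions with the published cell means and SDs, truncated at
±4 SD. The vertical chain needs care: the printed means satisfy
N-Sn + Sn-Sto ≈ N-Sto + 0.2 mm, so independent draws violate the triangle
inequality about half the time, and rejection would bias cohort means by
~0.8 mm. Instead (N-Sn, Sn-Sto, Sto-Gn) are drawn jointly normal with a
minimal moment-matched covariance and the chain heights are derived:
N-Sto = N-Sn + Sn-Sto − δ₁ and N-Gn = N-Sto + Sto-Gn − δ₂, where δ₁, δ₂
are the positive collinearity defects implied by the configured means.
All five parameters then reproduce their configured means and SDs exactly
in expectation while every draw is geometrically realisable. Configured
mean sets whose defects are non-positive are rejected at validation.

**Constructive placement.** Landmarks are placed to satisfy the drawn
values exactly (gnathion at the origin of construction, midline in the
x = 0 plane): the chain N → Sto → Sn by circle intersections; the
pogonion on the ray from Sn at the drawn facial-convexity angle, with its
distance solved in closed form from the drawn Sn-to-N-Pg offset (the
offset's sign selects the rotation side); the pronasale on the
inscribed-angle arc over N-Pg (every arc point realises the drawn
soft-tissue convexity), positioned at the anatomical nose-tip height; the
sublabiale from the drawn submental-plane angle and Pg-to-N-B offset by
the same closed-form pattern; lips and columella on exact rays. The
mandible places the gonion at the drawn Go-Gn distance along the
template's gonion direction and rotates the template's
otobasion-inferius offset in its own plane to realise the drawn gonial
angle exactly. All remaining landmarks are the sized template anchors, so
generator and analysis warps share consistent controls. Rare extreme-tail
draws that make a solve near-degenerate (e.g. facial convexity near 180°)
are redrawn with an anatomic bound (pogonion within 50 mm of the
gnathion); this conditions only the >3.5σ tail. Re-measuring a generated
subject reproduces every drawn target to better than 10⁻⁶ (observed
~10⁻¹¹), in both landmark-only and mesh modes.

**Head surface.** The subject mesh is the base template sized to the
drawn H/L/W (width and length pinned exactly as mesh extents, height via
the vertex anchor) and TPS-warped through the 37 anatomical landmarks, so
the surface passes through them. Asymmetry is injected as a
normal-direction displacement field with amplitude t/(2 n̂·x̂) — a
parallel-surface offset whose closest-point feet do not slide, so each
surface point's origin-distance moves by exactly ±t/2 (left out, right
in; extents preserved by antisymmetry). The field tapers smoothly to zero
at the midsagittal seam (tanh, 12 mm scale) and blends between the facial
and skull regions (sigmoid over the bisector-plane distance, 10 mm
scale); the two regional amplitudes solve a 2 × 2 moment system so the
facial mean equals the drawn AF and the head mean the drawn AH. Full
pipeline recovery of the configured magnitudes is ≈ 0.99 (AH) / ≈ 0.92
(AF) per subject.

**Raters.** Inter-rater reliability is emulated two ways: landmark-space
(each rater perturbs every landmark isotropically, parameters
re-measured) and parameter-space (rating = truth + noise with SD a fixed
fraction of the between-subject SD). The reliability check uses the
parameter-space form at a 25% noise fraction, 31 subjects × 2 raters,
giving a true ICC(2,1) of 1/(1 + 0.0625) ≈ 0.94; with n = 31 the
estimator's sampling spread means any single parameter's ICC can
occasionally leave a fixed band, so band coverage is asserted per
parameter across seeds.

**What passing tests do and do not show.** The generator emulates group
means/SDs, roster structure, rater noise, and controllable regional
asymmetry on analytic head surrogates. It does not model inter-parameter
correlations beyond the geometric necessities above, skin texture or
capture artifacts, missing or occluded landmarks, or real craniofacial
shape variation beyond the 14-parameter + head-norm family; pipeline
correctness on these cohorts therefore demonstrates algorithmic
correctness and calibration, not clinical validity on real scans.

## Statistics layer

Two-sample t tests (pooled Student by default — the common contemporary
software default — Welch by flag; both accept raw samples or printed
summary statistics), fixed-effects one-way ANOVA (F equals t² for two
groups; constant-group degeneracies resolved by an explicit round-off-
scale convention: identical constant groups give F = 0, p = 1), and
ICC(2,1) (two-way random effects, absolute agreement, single measurement)
from the mean-squares decomposition, with ICC(3,1) by flag. p ≤ 0.05 is
flagged with no multiple-testing correction, matching the reproduced
study design. Group tables compute Total rows from raw per-subject
values, never from rounded subgroup summaries; cells with n < 2 are
marked NA with a warning.

## Problem sizes and defaults

Default template 48 × 32 (1490 vertices, 2976 faces); subject meshes
40 × 28; cohort 139 subjects. The full simulate → measure → correspond →
asymmetry → statistics run completes in well under a minute at these
sizes, which are sufficient for the faceting-dominated tolerances used
throughout (e.g. sub-percent volume error against the analytic solid).
Ray casting for layer landmarks uses exact Möller–Trumbore intersection
with the farthest hit; degenerate inputs (coplanar or duplicate TPS
controls, non-watertight volumes, missing landmarks, rays that miss the
mesh) raise typed errors naming the offending entity.

## Known limitations

- The closest-point asymmetry statistic carries the cos²θ projection
  response discussed above; absolute asymmetry magnitudes are therefore
  method-relative, as they are in the reproduced workflow.
- The canonical frame depends on two landmarks (PRn, Op) for its in-plane
  orientation; gross digitisation error in either tilts the frame and
  biases H/L/W (not the 14 measurements).
- Head surrogates are smooth closed surfaces without ears, hair or neck
  openings; layer-landmark ray casting on real scans with open bottoms
  may need masking.
- The generator's nominal (non-parameter-driven) landmarks are
  template-derived; their absolute positions are plausible but not
  calibrated to population data.
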