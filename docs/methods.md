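# Methods

This note records the models, conventions and numerical choices behind
`softcongruence`, in the spirit of a statistics-package methods
appendix: what is computed, under which assumptions, and where the
design was genuinely open.

## Coordinate frame and units

All geometry is in millimetres.  The aligned head frame follows the
anthropometric convention used throughout: x antero-posterior (positive
anterior), y lateral, z cranio-caudal (increasing cranially).  Nothing
in the pipeline rescales: surgery does not change head size, so only
proper rigid motions (rotation + translation, det = +1) are ever
fitted.

## Superimposition

**Basic alignment.** The protocol this package operationalises requires
a landmark-free pre-alignment before reference points are placed.  The
original GUI tool's algorithm is unpublished, so we define it
deterministically: translate centroids together and align
principal-axis frames of the vertex covariance, with axis signs
disambiguated by the third central moment along each axis (an
intrinsic, rotation-equivariant quantity; the largest-component sign is
the fallback for skew-free shapes).  The choice is immaterial to the
final pose whenever landmarks exist, because the subsequent
least-squares fit is a global optimum, not an iterative refinement.

**RPS alignment.** The 15 paired landmarks (3 antero-posterior, 4
zygomatic, 8 orbital) enter an unweighted Kabsch fit: SVD of the
cross-covariance with the usual determinant correction excluding
reflections.  The axis roles attached to the point groups are kept as
metadata only — the protocol assigns them descriptive meaning ("mainly
for the antero-posterior dimension") but prescribes no weighting, and
inventing one would change results invisibly.  Acceptance follows the
strict rule: accepted iff **every** per-pair residual is < ε
(default 0.1 mm).  Whether the original criterion was per-pair or
aggregate is not documented; per-pair max is the conservative reading
and is what we implement.  A rejected alignment warns and proceeds by
default (batch runs cannot re-pick landmarks interactively, which is
how the original protocol resolved rejections); `strict` mode aborts.
No ICP refinement follows: none is described in the protocol, and
iterating over surgically changed regions would bias the distance map
toward the deformation.

## Signed distance map

Distances are evaluated at the vertices of the **simulation** surface
against the triangle set of the scan (the error map conventionally
lives on the prediction; the opposite direction is exposed behind a
flag).  Each query returns the exact closest point on any triangle —
face interior, edge or vertex, by the Voronoi-region
closest-point-on-triangle construction — never a nearest-vertex
approximation.  The KD-tree acceleration is lossless: a triangle can
only beat the current best if its centroid lies within
(best + max centroid-to-vertex radius), so the ball query cannot
discard the minimiser; the test suite asserts equality with an
exhaustive all-triangles oracle at 1e-9 mm.

Sign uses the angle-weighted pseudo-normal of the closest feature,
which is well defined on edges and vertices where the face normal is
not.  The raw convention is "positive = query on the outward side of
the reference"; the pipeline reports the clinically intuitive
"positive = actual tissue beyond the prediction", which for a
scan-referenced map is the negation.

Query vertices whose closest scan point lies on an open boundary edge
or vertex of the scan (the ~200° ear-to-ear capture rim) are flagged
invalid: their closest point is an extrapolation artifact, not a
correspondence.  Invalid vertices are excluded from every downstream
statistic.

**Artifact trimming.** The original workflow removed scattered
radiation artifacts by hand in a GUI.  The reproducible stand-in is a
masking rule: `robust` invalidates vertices with |d − median| > k·MAD
(default k = 6), `absolute` invalidates |d| > cut.  Values are masked,
never deleted, and the count is logged.  Note the robust rule assumes
genuine deviations are not the majority *and* not the only spread: on
synthetic cases whose background error is pure scanner noise, the MAD
is a fraction of a millimetre and a genuine multi-millimetre surgical
deviation would itself be trimmed.  The synthetic-validation protocol
therefore runs with `absolute` at a generous cut (20 mm; real scatter
artifacts sit centimetres off the face) or with trimming off, and the
robust default is intended for clinical maps whose spread is dominated
by real prediction error.

## Aesthetic units

The seven analysis regions plus face-total follow the facial
aesthetic-unit scheme: nose (1), upper cheek (2), upper lip (3), lower
lip (4), lower cheek (5), chin (6), both lips (3+4), face total
(1+…+6).  The source protocol segments these in a GUI without stating
boundary geometry, so the fences here are declared conventions, fixed
by landmarks:

* horizontal planes through subnasale (nose/upper-lip), stomion
  (upper/lower lip), sublabiale (lips/chin), the exocanthion level
  (cranial cap) and menton (caudal cap);
* per-side oblique alare→cheilion lines separating lips from cheeks
  (continued vertically below the cheilion), vertical cheilion lines
  bounding the chin, a cheilion-level plane splitting upper from lower
  cheek, and vertical zygion lines bounding the face patch laterally.

Vertices exactly on a fence go to the more cranial, then more medial
unit — a fixed tie-break that makes segmentation deterministic in a
given frame.  (Exact fence coincidence is, unavoidably, sensitive to
float round-trip noise of order 1e-13 mm; the partition invariants hold
in any single frame.)  The elementary units are pairwise disjoint,
`both_lips` is exactly their lip union, `face_total` exactly the union
of all six; these are asserted, not assumed.  Segmentation runs on the
surface hosting the distance map.

## Metrics

For the valid signed distances d₁…dₙ of a region:

* IO% = 100 · #{|dᵢ| ≤ τ}/n, τ default 2.0 mm.  The comparison is
  **inclusive**; whether the original used ≤ or < at exactly 2 mm is
  unknowable and affects only measure-zero cases.  IO% counts vertices
  unweighted; an area-weighted variant (barycentric vertex areas) is
  available behind a flag for sensitivity analysis, since the original
  tool's basis is unstated.
* MTL is the **signed** mean.  The field's customary label for this
  quantity reads "mean absolute", yet it is reported with negative
  values in practice; a mean of absolute values cannot be negative, so
  the signed mean is the only consistent definition.  Flagged here and
  in the API docs deliberately.
* RMS = √(mean d²); SD uses the sample (n−1) denominator, hence the
  identity RMS² = MTL² + SD²·(n−1)/n, asserted on every report row.
* Empty regions are reported as missing (n = 0, NaN), never as zeros.

## Cohort statistics

"Multivariate analysis (general linear model)" over a 20-patient
cohort with five factors is interpreted as **per-region univariate
OLS** with all five main effects and no interactions — the only design
consistent with a one-p-per-factor-per-region grid at that sample
size; a true MANOVA is out of scope.  Factors are categorical with
sum-to-zero contrasts and each factor's p comes from its Type-III
F test (with main effects only, Type III coincides with Type II and is
coding-invariant).  The implementation is statsmodels OLS + anova_lm,
verified against R `car::Anova(type=3)` to 1e-13 on a frozen fixture.
The screen refuses aliased (perfectly confounded) factor pairs by
name, requires ≥ 2 patients per used level and more observations than
parameters, and warns when residual degrees of freedom < 10 — with
n = 20 and 8 parameters the screen is fittable but weak, which is why
the synthetic calibration cohorts default to n = 40.

Shapiro–Wilk is scipy's Royston implementation, cross-checked against
R `shapiro.test` to 1e-9 on frozen samples.  Box-plot summaries use
linear-interpolation quartiles (quartile conventions differ across
software; this one is numpy's default) and grade outliers moderate
(1.5–3×IQR beyond the quartiles) or extreme (>3×IQR).  No
multiple-testing correction is applied across the 40 grid cells,
matching conventional reporting of such screens.

## Synthetic data

The generator emulates the *measurement situation*, not human
anatomy statistics.  The face is an analytic height field
x = f(y, z): half-ellipsoid base (default 140 × 160 × 55 mm) plus
nose ridge (12 mm), lip rolls (3 mm) and chin boss (5 mm), triangulated
on a 61 × 75 grid (≈ 4.6 k vertices; every elementary unit is required
to contain ≥ 50 vertices).  All 15 RPS landmarks and 14 segmentation
anchors are placed at closed-form parametric positions on the analytic
surface, and every vertex carries its true unit label — so
segmentation, alignment and metrics can all be checked against ground
truth.  Identical specs produce bit-identical bundles.

The deformation engine deliberately simplifies the mass-tensor model
family behind commercial predictors: "join" vertices are Dirichlet
constraints (the target region moves with the planned displacement;
everything outside a graph-dilation collar, default 6 rings, stays
put) and "free" vertices relax to the discrete harmonic interpolant of
the uniform graph Laplacian, each Cartesian component independently.
The solve is a sparse factorisation polished by Jacobi sweeps until
the largest update falls below a dynamic threshold (1e-8 mm), which
guarantees mean-of-neighbours stationarity to that tolerance and
preserves the discrete maximum principle.  It is a surface solver with
no volumetric tetrahedra and no tissue-specific stiffness — it supplies
controllable ground truth for the *validation pipeline* and makes no
fidelity claim about any commercial algorithm.  Gaussian-bump and
rigid-follow modes exist for smooth and worst-case (discontinuous)
deformations respectively.

Scanner noise is iid along-normal Gaussian, default SD 0.1 mm — half
the < 0.2 mm RMS accuracy stated for the stereophotogrammetry system
being emulated.  The mis-pose draws a random axis, an angle up to 6°
and a 10 mm translation.  Scan-side landmarks follow the anatomy (base
position + true displacement of the nearest vertex) and are exact by
default; `landmark_sd` adds picking noise when rejected-alignment
behaviour is the thing under test.  The regional truth summary is the
pipeline's own distance/segmentation/metrics chain evaluated on the
noise-free, un-posed deformed surface, so recovery experiments isolate
exactly the errors the pipeline can introduce: alignment, noise,
trimming and rim handling.

Fast-mode cohorts skip meshes entirely: factor levels are assigned
with marginal counts proportional to the reference 20-patient
composition (9/11, 10/10, 8/7/5, 11/5/4, 10/10), and per-region IO%
is a baseline (graded cranial-to-caudal, e.g. nose 92, lower lip 75)
plus configured factor effects plus Gaussian noise (default SD 5 IO%
points), clipped to [0, 100].  Under a zero-effect configuration the
factor screen's p-values are exactly uniform, which the calibration
tests exploit.

What the generator does **not** emulate — and hence what passing tests
cannot show about clinical data: realistic human shape variation
(no morphable model), open-mouth/ear/neck topology, CBCT scatter
artifacts (trimming is tested on injected spikes instead), swelling
asymmetry between scan dates, and landmark-picking bias of a human
operator.

## Problem sizes and tolerances in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: 200 random rigid recoveries (< 1e-6 mm), 100 random mesh pairs
against the exhaustive distance oracle (< 1e-9 mm), closed-form offset
planes (exact to 1e-12), chin-deformation recovery at amplitudes
0–5 mm under 0.1 mm noise (MTL within 0.15 mm; the default-resolution
face keeps this under half a minute per case), harmonic checks against
the 1-D closed form, and 500 forty-patient null cohorts for the
5 × 8-cell calibration of the factor screen.  These sizes were chosen
as the smallest that make the statistical assertions meaningful;
everything is seeded and deterministic.

## Known limitations

* Basic alignment needs covariance skew for sign disambiguation;
  perfectly symmetric shapes fall back to a component-sign rule that is
  deterministic but arbitrary.  Irrelevant when landmarks exist.
* The robust trim can eat genuine large deviations on otherwise
  near-perfect maps (see above); choose `absolute` or `none` when the
  expected deviation dominates the map.
* Fence geometry is a declared convention, not a reconstruction of any
  particular operator's GUI segmentation; absolute regional values on
  real data depend on it, comparisons across cases using the same
  fences do not.
* The per-vertex map assumes export-density simulation meshes; a
  midpoint `densify` pass is provided for coarse meshes but no
  curvature-adaptive sampling.
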