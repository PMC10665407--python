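# Methods

## The measurement problem

In a real-world pointing test, a seated subject memorizes a 3×3 matrix of
wall targets (100 cm spacing, 192 cm viewing distance, so neighboring
targets subtend atan(100/192) ≈ 27.5° and the matrix spans 55° × 55°) and
then points at each target, called in randomized order, with eyes closed —
once facing the wall and again after passive 90° whole-body yaw rotations
to either side. Two preceding calibration runs (with visual feedback)
anchor each subject's baseline. Classical analysis reduces each response
to its angular deviation; it cannot distinguish a *misaligned but intact*
mental map (uniformly shifted or magnified, large deviations, correct
shape) from a *deformed* one (similar deviations, broken shape). This
package quantifies the shape directly: the eight perimeter responses are
projected to a plane and treated as a polygon — the *figure frame* —
whose morphology is then measured and compared across groups.

## Projection and frame assembly

Per-axis pointing angles (azimuth `a`, polar `p`, degrees) are projected
onto the frontal plane at unit distance: `x = tan a`, `y = tan p`. For
this angle convention the projection exactly inverts the wall geometry —
a perfect pointer maps to a perfect square of side 2·100/192 ≈ 1.0417
tangent units — and is strictly monotone per axis. Angles within 89° of
the rim are rejected: the tangent projection degenerates there, and such
responses do not occur in a forward-facing task. Vertices are ordered by
a fixed perimeter walk of target labels (top-left → top-mid → … →
mid-left), never re-sorted by geometry, so a subject who swaps two
targets produces a faithfully self-crossing polygon. The center target is
kept for deviation analysis but excluded from the polygon. Deviation
summaries (signed per-target test-minus-reference differences, mean and
sample SD of their absolute values) default to the retinotopic
calibration as reference.

## Rasterization and descriptors

The raster is the canonical measurement domain because self-intersecting
frames only have a well-defined area under a fill rule. Frames are filled
on a square canvas (default 2000 × 2000 px over a ±1.2 tangent-unit
window; pixel centers tested) under the even–odd rule, with
nonzero-winding available. The canvas scale is an implementation choice,
so pixel-valued outputs are comparable only within one configuration;
dimensionless descriptors (circularity, solidity) and world-unit outputs
are scale-free. A polygon that encloses no pixel center yields an empty,
flagged raster; descriptor records carry NaN fields with reasons rather
than aborting a cohort run.

Descriptors: pixel-count area; Cauchy–Crofton perimeter; circularity
4πA/P² (clamped at 1, raw value retained); largest Feret diameter and
angle (all-pairs maximum over convex-hull vertices of the boundary-pixel
set; ties broken toward the smaller angle; a single pixel has diameter
0); mean caliper diameter over 180 directions; solidity = pixel count /
pixel count of the filled convex hull (union with the region, so
discretization can never push it above 1); maximum inscribed disc (argmax
and maximum of the Euclidean distance transform); moment-equivalent
ellipse (semi-axis = 2σ along each principal axis; orientation reported
as 0 when the axes are equal within 10⁻⁴ relative, as for discs and
squares); bounding box and centroid.

Two deliberate choices:

* **Crofton directions.** The classical 4-direction estimator
  (ImageJ/MorphoLibJ weights) is exact on discs but biased −5.2% on
  straight edges at unsampled orientations (continuous limit
  π(1+√2)/2·s vs 4s per square side), which distorts circularity by
  +11% on square-like frames and makes the estimate rotation-dependent
  by ~4%. The default is therefore a 32-direction digital-line
  intercept-count estimator (directions up to (5,±2) lattice steps,
  angular-Voronoi weights, perpendicular line spacing 1/√(a²+b²)): the
  orientation spread of the continuous-limit estimate on straight edges
  is 0.5% (vs 1.3% at 16 directions), ≤0.4% error on squares at any
  rotation, 0.05% on discs. Since circularity squares the perimeter,
  this keeps its rotation drift near 1%. The 2-, 4-, 8-, 16- and
  24-direction variants remain available for compatibility and speed.
  At 32 directions, features thinner than the largest sampling step
  (~5.4 px) can be under-counted.
* **Average diameter.** Defined here as the mean caliper (Feret)
  diameter over 180 equally spaced directions (4s/π for a square, d for
  a disc). The equivalent-disc diameter 2√(A/π) is also computed and can
  be selected as the reported value (`avg_diameter_method`); the two
  differ systematically (for a square, 4s/π ≈ 1.273s vs 2s/√π ≈ 1.128s).

## Cohort statistics

Group comparisons use the ANCOVA `outcome ~ 1 + covariates + group` for
a two-level factor. With a single-df effect the Type III group F equals
the squared t of the group coefficient; partial η² = F/(F + df_resid);
the adjusted difference is the group coefficient (second sorted level
minus first); Cohen's d divides it by the residual SD (a pooled-raw-SD
variant is available). With no covariates this reduces exactly to
one-way ANOVA. Post-hoc uncertainty is a stratified percentile bootstrap
(resampling subjects with replacement within groups, default 1000
replicates, seeded; BCa was deliberately not chosen at these group
sizes). Bonferroni correction multiplies p by an explicit family size m,
by default the number of contrasts in the outcome's family, since the
published analyses do not state their family sizes.

Comparison *plans* encode the two analysis families as configuration:
the sex comparison (normal-cognition subjects, outcome = frame area per
paradigm, covariate age) and the cognition comparison (five task
paradigms plus their per-subject mean as an *overall* contrast,
covariates age plus the subject's two calibration-frame areas — the
calibration areas absorb anatomical size confounders such as arm length
and shoulder width, which also carry the sex area difference, so the
sexes are pooled there).

## Synthetic cohorts

Real pointing datasets of this kind are not publicly available, so the
simulator is the package's test bed. Per response: true direction →
per-subject affine distortion (isotropic scale ~ N(1.04, 0.06) for
females, N(0.96, 0.06) for males — a phenomenological carrier of the
observed female > male area difference; shear ~ N(0, 0.03)) → angular
noise. Task paradigms get per-axis Gaussian jitter (default SD 3°
normal, 4° impaired); calibrations use 25% of it (visual feedback; the
fraction is arbitrary and documented, not fitted). With probability
`gross_error_prob` (default 0.03 normal, 0.3 impaired; tasks only) a
response becomes a *gross error*: the azimuth is redirected toward a
wrong matrix column with 6° jitter (target confusion, azimuth-dominant).
This is the error mode that breaks convexity and — because off-center
columns outnumber the center — shrinks mean caliper diameters, the
impairment signature. Purely additive zero-mean gross-error modes
(azimuth-only or isotropic) are available as switches but *increase*
expected caliper diameters and are not the default. Ages are uniform
(20–80 y normal, 60–84 y impaired, mirroring a dementia-screening
cohort) and have no effect on frames by default; an optional
age–area slope exists. All sampling is driven by one seeded generator;
cohorts are byte-reproducible.

What the simulator does not emulate: biomechanical arm/shoulder
kinematics (the narrower post-rotation frames seen in practice are only
available as explicit per-paradigm scale multipliers), vestibular
rotation dynamics, learning or fatigue across paradigms, and non-Gaussian
per-subject error structure. Passing recovery tests therefore shows the
pipeline detects the modeled signature at realistic sizes — not that
real cohorts behave like the model.

## Verification strategy and problem sizes

Every descriptor is checked against an independent oracle: shoelace area
and winding-parity fills for polygons, brute-force all-pairs Feret,
exhaustive distance search for the inscribed disc, closed forms for
discs and squares (perimeter, circularity, caliper means, moment
ellipses), and a normal-equations model-comparison fit for the ANCOVA.
Statistical calibration is checked by simulation: type-I error of the
full pipeline on 100 null cohorts (n = 12/group, 128-px canvas,
area-only descriptors), and recovery of the impairment signature on 50
cohorts (n = 30/group, 256-px canvas) requiring Bonferroni-significant
decreases of solidity and mean caliper diameter in ≥80% of replicates.
The reduced canvases in the simulation loops are a deliberate problem
size: descriptor resolution converges well before 256 px for
frame-scale structures (1000 px vs 2000 px differ by <1%), while the
oracle suite itself runs at the full 2000 px.

## Known limitations

* Absolute pixel-valued descriptors depend on canvas scale and are not
  comparable to other tools' pixel outputs without matching the window.
* The 32-direction Crofton default departs from the 2/4-direction
  convention of MorphoLibJ; use `crofton_directions=4` for
  numerical compatibility with that tool (and accept its orientation
  bias).
* Solidity is undefined (NaN) for degenerate/collinear regions; the
  vector-polygon solidity route is meaningful for simple polygons only.
* Bootstrap CIs are percentile intervals; with very small groups they
  can be narrow-biased.
* Lenient assembly drops missing vertices from the polygon, which
  changes the shape class rather than interpolating it; incomplete
  frames are flagged and should usually be excluded from cohort
  statistics.
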