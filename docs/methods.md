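# Methods

This note records the scientific and numerical choices behind the package:
what each stage models, the parameters that matter, what the synthetic
generators do and do not emulate, and the known limitations.

## Per-plane affine calibration

The simulator works with one 2-D mapping per imaging plane (AP and
cross-table lateral), each fitted from exactly three clicked point
correspondences between the camera image and the pre-loaded radiograph.
Three correspondences exactly determine the six affine parameters, so the
fit is a direct linear solve of two 3×3 systems sharing the design matrix
`[x, y, 1]` — not a least-squares fit. This is deliberate: the solve is
bit-stable, has no convergence or tolerance knobs, and makes
"interpolation exactness" (source points map onto their targets to ~1e-9
px) a hard contract rather than an approximation.

Collinearity of the three source points is the only degenerate input; it
is detected on twice the signed triangle area with a threshold of 1e-6
px². Sub-pixel clicks on any realistic frame span triangles many orders
of magnitude above this, so the threshold only catches genuinely
degenerate picks. An 8-DOF projective model and lens-distortion terms are
out of scope: the affine map is the stated mechanism of the per-plane
overlay, and residual perspective error folds into the overall px-level
tracking tolerance.

Coordinates are 0-based, `x` = column (rightward), `y` = row (downward),
origin at the top-left pixel; every file that stores points carries this
convention in a `"coords"` header field.

## Marker tracking

Segmentation is an axis-aligned box threshold in RGB: a pixel belongs to a
marker when every channel lies within a per-channel tolerance of the
target color. A hue-based model would be more robust to illumination in a
physical deployment, but the box model is deterministic, its interaction
with additive channel noise is analyzable (monotone in the tolerance), and
no color space was prescribed for the original system.

Per color, the marker is the largest 8-connected component with area at
least `min_area` (default 10 px — a disk of radius 2 already exceeds it,
while sensor speckle stays below). Ties on area are broken by the smaller
(row, column) of the component's bounding-box corner so detection is
deterministic; a strict mode raises instead. A missing component is the
occlusion signal (`MarkersNotFoundError`) — in live use the operator's
hand covering a marker. The marker position is the component's unweighted
pixel centroid, which recovers rasterized disk centers to well under half
a pixel.

Roles (proximal/distal) are assigned by color, not by geometric ordering,
because color survives partial occlusion and arbitrary wire orientation.
The tip is extrapolated from the two centroids: `tip = distal +
tip_offset · unit(distal − proximal)`. `tip_offset` (px) is a per-plane
calibration input, since the physical marker-to-tip distance depends on
how the markers are mounted; the markers are treated as rigidly collinear
with the tip — wire bending is explicitly not modeled (operators are
instructed not to bend the wire).

## Session state and counters

A session holds both calibrations and radiographs, an event log, and the
counters behind three of the five metrics.

**Exposures.** Each simulated radiograph increments one counter; AP and
CTL shots contribute to a single total (the headline metric is one
number), with the per-plane breakdown recoverable from the event log. The
overlay itself is cosmetic: a 200 px anti-aliased white segment ending at
the affine-mapped tip, drawn with `skimage.draw.line_aa`; the tested
contract is only that the drawn endpoint lands within 1 px of the mapped
tip.

**Retries.** No formal definition of a "retry" exists, so the package
defines it as hysteresis on the signed insertion depth along the
entry-point → apex axis (in radiograph px): the wire latches *inserted*
when depth exceeds `depth_on = +5` px and a retry is counted each time an
inserted wire falls below `depth_off = 0` px. The 5 px gap debounces
tremor right at the cortex — without it, jitter across a single threshold
would inflate the count — while matching the intuitive "pulled out and
re-inserted". Both thresholds are session parameters.

**Time.** Wall clock from session open to the participant-declared close;
in scripted replay it comes from trajectory timestamps. The package
records time but nothing in it optimizes for time.

## Scoring

**TAD.** The clinical standard magnification correction uses the wire
itself as the scale reference: per plane, the tip-to-apex pixel distance
is multiplied by `D_true / D_apparent` (true wire diameter in mm over its
apparent diameter in px), and the two plane components are summed. When no
apparent diameter is available — e.g. scoring synthetic radiographs with a
known scale — a direct `mm_per_px` factor is used instead; both paths are
tested, and scaling all pixel quantities of one plane by any k > 0 leaves
the diameter-corrected TAD invariant. The wire's true diameter is a
configuration parameter (a typical DHS guide-wire is 2.5 mm).

**Cut-out curve.** The TAD → cut-out-risk relationship is modeled as a
two-parameter logistic on the logit scale, `COR(t) = 100·σ(a + b·t)`,
b > 0. The curve's published form is a figure, not a formula, so the
package calibrates the logistic exactly through the two extreme reported
(TAD, COR) median pairs, (24 mm, 2.6 %) and (47 mm, 55 %): a two-equation
linear solve in (a, b), giving b ≈ 0.1663 per mm and a ≈ −7.614. The
shape check is that the curve, fitted to the extremes only, passes within
0.5 percentage points of the third reported pair (28 mm, 4.7 %) — it
evaluates to 4.9 %. The anchors are swappable; risk is reported to one
decimal place.

## Validity statistics

Cohorts are assigned from the DHS caseload alone: novice < 10,
intermediate 10–39, expert ≥ 40 (40 cases being the UK competency
benchmark). Medians use the standard even-n midpoint convention.

The omnibus test is Kruskal–Wallis with mid-ranks and tie correction; its
p-value comes from the χ²(k−1) approximation, or — for pooled n ≤ 8, and
on request — from exact enumeration of every relabeling of the pooled
values into the observed group sizes (fraction with H ≥ H observed).
Post-hoc pairwise comparisons are two-sided Mann–Whitney U tests; for
pooled n ≤ 12 the p-value is exact (fraction of all C(n, n_a) relabelings
whose U deviates from the null mean n_a·n_b/2 at least as much as
observed), otherwise the tie-corrected normal approximation with
continuity correction is used. The n ≤ 12 default keeps the exact path
cheap while covering small pilot cohorts; `exact=True` forces enumeration
for larger n. The U statistic follows the standard convention
U_a = #{a > b} + ½·#{ties} = R_a − n_a(n_a+1)/2.

Multiplicity correction is fixed-family Bonferroni with k = 3 (the three
cohort pairs): adjusted p = min(3p, 1). Percent differences between
cohort medians are reported as integers, `round_half_up(100·|m₁−m₂| /
max(m₁, m₂))` — the larger median as denominator. Among the simple
conventions (larger / smaller / mean denominator, half-up / half-even)
this is the one that reproduces the most of the published pairwise table
from the published medians; the cells it cannot reproduce (they were
presumably computed from unrounded medians, and the retry row from
near-zero medians where no median-based convention is stable) are
reported but never asserted. Likert agreement is the count and proportion
of responses ≥ 5 on the 7-point scale.

## Synthetic data

The generators exist so that every stage is testable without hardware:

- **Frames**: two exact-color disks on a plain background, rasterized by
  center-of-pixel inclusion (pixel (row, col) is in the disk iff its
  center, at integer coordinates, lies within the radius) so pixel counts
  and centroids are exactly computable; optional clipped Gaussian channel
  noise. Defaults (640×480, radius 6 px, red/green markers on a dark
  background) emulate a webcam view of bright markers.
- **Radiographs**: a bright femoral-head disk and shaft band in grayscale,
  with the apex annotation on the head boundary along the neck axis and
  the entry annotation on the lateral cortex; 0.25 mm/px by default
  (a typical hip radiograph scale).
- **Trajectories**: waypoint/event scripts with strictly increasing
  timestamps and the implied ground-truth counters attached;
  `insertion_waypoints` scripts a known number of withdraw–reinsert
  cycles along the entry→apex axis.
- **Cohorts**: per-cohort target medians default to the reported study
  values (TAD 47/28/24 mm, time 190/206/222 s, radiographs 16/26/28,
  retries 0/1/2, n = 8/7/11). TAD is log-normal with μ = ln(median) so the
  population median equals the target and values are positive and
  right-skewed; COR is *derived* from each participant's TAD through the
  default curve, never sampled independently, preserving the deterministic
  TAD→COR coupling; time is normal about its median; the two counters are
  Poisson-shifted about theirs and clamped at zero; caseload is uniform
  within the cohort's defining range. The log-scale dispersion default of
  0.3 (≈ 30 % coefficient of variation) is a plausibility choice made for
  test power — the real study's dispersions are unpublished — and the
  Likert agreement probability of 0.85 matches the reported ~22/26
  agreement rates.

Every generator is a pure function of its spec including the seed;
identical inputs give bit-identical outputs, and no global random state is
touched.

What the generators do **not** emulate: photorealistic radiographs (no
ray-cast DRRs), surgical tremor or human motion models, lens distortion,
marker bending, illumination drift, or inter-metric correlations beyond
the TAD→COR coupling. Passing tests therefore demonstrate that the
pipeline's logic and numerics are correct under its stated assumptions,
not that the color thresholds or hysteresis constants are tuned for any
particular physical camera rig.

## Problem sizes and numerical choices

Randomized checks use fixed seeds throughout. Accuracy bounds are checked
over 100 random affine correspondence sets (round-trip within 1e-9 px) and
100 synthetic frames with channel noise σ ≤ 8 (centroids within 0.5 px).
Exact-test agreement with brute-force enumeration is verified for every
group-size configuration with pooled n ≤ 8, on continuous and tied data.
The construct-validity recovery experiment uses 100 seeded replicates of
50-per-cohort populations at the default medians and dispersion, asking
that Kruskal–Wallis (TAD and COR) and the adjusted novice-vs-expert
Mann–Whitney reject at α = 0.05 in at least 90 % of replicates; at these
effect sizes the observed rate is 100 %. Floating-point comparisons in the
permutation tests use a 1e-12 slack on the "at least as extreme" predicate
so that ties in the statistic are never dropped to rounding.

## Limitations

- The raw per-participant data of the original study are unpublished, so
  its exact medians and p-values cannot be recomputed — only the
  functional relationships among its published numbers (percent-difference
  table, TAD→COR curve consistency) and the pipeline's discriminative
  behavior on synthetic cohorts of the same structure.
- The per-plane 2-D affine mapping is the implemented mechanism; a stereo
  3-D reconstruction of the wire is a different (companion) system and out
  of scope, as are live video capture, temporal filtering, drill/haptics
  simulation and screw-length gauging.
- The retry definition, marker colors/geometry and wire diameter are
  configuration, not published constants; defaults are documented above.
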