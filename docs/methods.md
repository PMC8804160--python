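# Methods

This note documents the models, parameter choices and numerical decisions
behind `fundusvasc`, and what the synthetic validation does and does not
establish about real photographs.

## Coordinate and unit conventions

All grids are (row, col), 0-based, with pixel centers at integer
coordinates. Lengths, widths and distances are in pixels; angles in
degrees. Orientation of an undirected line is measured against the column
axis and reduced to [0°, 180°); the acute angle between two orientations a,
b is min(|a−b|, 180−|a−b|) ∈ [0°, 90°].

## Regions of interest

The general cover is the centered axis-aligned ellipse whose semi-axes keep
the frame's aspect ratio, scaled so the included-pixel fraction equals the
requested share (default 0.43; the largest inscribed such ellipse reaches
π/4 ≈ 0.785). A pixel belongs to the cover iff its center satisfies the
ellipse inequality; the analytic scaling keeps the measured fraction within
±0.005 of the request for frames ≥ 200×200. Patient images are further
split by a region cover in which nonzero pixels mark the detached region as
a filled mask (a helper flood-fills covers supplied as closed boundary
curves); both partition masks are intersected with the general cover and
together tile it exactly.

## Vessel extraction

Extraction operates on the green channel, where vessel/background contrast
is strongest; the HSV value channel (per-pixel max of R, G, B) serves only
to locate the bright optic disc, and a red-free grayscale ((G+B)/2,
rounded) is provided for completeness. The pipeline:

1. green-only grayscale;
2. background flattening: subtract a local average over a window of
   min(rows, cols)/8 — large relative to any vessel, small relative to the
   vignetting scale;
3. Sobel gradient magnitude, hysteresis-thresholded at the 80th/93rd
   percentiles of the gradient inside the ROI;
4. morphological closing (disk radius 2 px) merges each vessel's paired
   edges, hole filling produces solid bodies, and an Otsu cut on the
   flattened intensity trims the bright halo of edge pixels lying just
   outside the true (dark) vessel;
5. components under 64 px are dropped, and when the optic disc is known a
   disk of 1.2× its radius is excluded — the disc's bright rim otherwise
   closes into a large false component;
6. intersection with the ROI.

A stricter percentile pair such as 90/97 fails at realistic vessel
densities: with vessels at 11–18% of the ROI, true edge pixels alone
exceed 10% of the ROI, so a 90th-percentile floor discards real edges and
recall collapses. The 80/93 defaults give Dice overlap with ground truth
of 0.95–0.98 across seeds at noise levels 0–5 gray levels, and all
thresholds remain config keys. Because the percentile statistics are ROI-relative,
shrinking the ROI can shift thresholds slightly; foreground containment in
the ROI is strict, and near-monotonicity under ROI shrinkage holds to
within a few percent of foreground pixels.

Optic-disc detection thresholds the value channel at its 99.5th percentile
and takes the centroid and equivalent-circle radius of the largest
component; a flat image (no candidate at least 10 gray levels above the
median) is a detection failure, and manual coordinates always override.

## Segment model

The vessel map is skeletonized; skeleton pixels with ≥3 neighbors (branch
points) are removed; each remaining branch-free arc is walked end to end
and divided into at most-30-pixel runs of near-equal length
(`segment.max_len`, chosen so a segment's rectangle long side tracks local
vessel direction). Every foreground pixel joins the segment of its nearest
run pixel, so segments partition the map exactly. Consecutive runs of one
arc are neighbors; runs meeting at a bifurcation are not — inter-segment
angles are defined along a vessel, and a bifurcation would give a segment
more than the two neighbors its type system allows. Types: I/isolated (0
neighbors), II/marginal (1), III/intermediate (2).

Each segment's minimum-area enclosing rectangle is fitted by rotating
calipers over the convex hull of its pixel centers (the optimum has a side
collinear with a hull edge, so scanning hull edges is exact); both sides
are then extended by 1 px for the unit pixel extent. Degenerate cases:
a single pixel gives L = W = 1 at 0°, collinear pixels an SVD-axis
rectangle of width 1.

Qualification (all thresholds config keys, defaults in parentheses): fill
ratio pixel-count/(L·W) ≥ 0.5; 8 ≤ L ≤ 60; acute angle between the long
side and the ray from the optic-disc center through the rectangle center
≤ 60° (retinal vessels run roughly radially from the disc; strongly
tangential blobs are artifacts); distance from the disc center ≥ 1.5× disc
radius. Tortuosity-computable segments satisfy the same predicate and are
marginal or intermediate. The distance rule interprets the qualification
ingredient "distance from the optic disk" as a minimum clearance of the
segment from the disc center; at extreme bend amplitudes the radial-angle
rule can disqualify every segment, in which case tortuosity is missing for
that image rather than zero.

## Metrics

Density is the exact integer ratio of foreground to ROI pixels. Caliber
statistics are the mean and median of rectangle widths over
caliber-qualified segments (even-count median = midpoint of the central
pair). Tortuosity variants are weighted means of the inter-segment angles
with weights 1, L·W, L, W, 1/W; the intent of each — area combines length
and width information, length compensates segmentation-size bias, width
amplifies thick vessels, inverse width reveals thin ones — pins the weight
definitions. When all rectangles are identical the five variants coincide
identically, and every variant lies within [min θ, max θ]. Undefined
metrics (no qualified segment, no qualifying angle) propagate as NaN and
are excluded from group statistics; they are never coerced to 0, which is
a valid tortuosity. Angle units are degrees; rank-based comparisons are
invariant to this choice.

## Statistics

Mann-Whitney: pooled midranks; U₁ = n₁n₂ + n₁(n₁+1)/2 − R₁ (the count of
pairs with the first sample's value below the second's, plus half-ties);
reported U = min(U₁, U₂); mean ranks MR₁ = R₁/n₁, MR₂ = R₂/n₂ are the
effect summary. For pooled N ≤ 12 the two-sided p is exact, enumerating
all C(N, n₁) assignments (p = 2·min(lower tail, upper tail), capped at 1);
otherwise the normal approximation with tie-corrected variance and 0.5
continuity correction. Wilcoxon signed-rank: zero differences dropped,
midranks of |d|, mean ranks of positive/negative differences reported, Z
from the tie-corrected normal approximation with continuity correction;
swapping the paired arguments swaps the mean ranks and negates Z. The
cohort report carries unadjusted p with stars at 0.05/0.01/0.001 and an
optional Bonferroni column (off by default). The sample-size routine uses
the exact normal quantile for the confidence level (1.959964 at 95%, not
1.96) and returns the ceiling.

## Synthetic cohort generator

The generator emulates what the downstream contracts need from a real UWF
capture: dark branching vessel trees sprouting from a bright optic disc
toward the periphery on a brighter, vignetted background. It is not
photorealistic — no eyelash/eyelid artifacts (the general cover exists to
remove them), no stereographic distortion, no capillary texture — so
passing tests demonstrate correct recovery of geometry the model encodes,
not performance on clinical photographs.

Trees are bounded-turning random walks: per 2-px step the heading changes
by Uniform(−A, +A) degrees, so A = 0 gives straight rays and the mean
absolute direction change grows as A/2; branches sprout at most twice per
polyline with probability 0.012 per step, start on the parent centerline,
and taper to 0.72× the parent width (floor 1 px). The disc radius is
min(rows, cols)/30 (≈0.35% of the frame, in line with real widefield
proportions and below the disc detector's 99.5th-percentile threshold).
Rendering: radial background falloff 190 − 60·(d/d_max)², vessels at 0.40×
background in the green channel, disc near 250, Gaussian blur σ = 0.8,
optional additive Gaussian noise. The ground-truth vessel map contains
every pixel center within half-width of a centerline.

Baseline cohort parameters model a healthy eye: 6 roots, root width 5 px,
bend amplitude 20°; per-eye variability is lognormal (σ = 0.06–0.10) and
group B's means are group A's times the CohortSpec multipliers, so a caliber
multiplier of 0.7 plants an exactly known relative effect on the
generating parameters. Detachment partitions cut the general cover along a
random chord at an exact area quantile, keeping both regions simply
connected. All outputs are pure functions of the seed.

## Problem sizes and determinism

Validation runs use 256×256 frames for extraction-fidelity checks and
160×160 frames for cohort power simulations (20 replicates of an n = 40/40
cohort), sizes at which per-image analysis takes tens of milliseconds and
whole-suite runs stay interactive while leaving every stage's behaviour
scale-representative; the scale-equivariance test verifies that metrics
transport across resolutions. Fixed seeds make every test and the
acceptance script deterministic; the demo writes bitwise-identical outputs
across reruns.

## Known limitations

- The extraction is a classical filter/edge pipeline; it does not attempt
  artery/vein separation or learned segmentation.
- Caliber is a rectangle-width estimate per short segment; sub-pixel vessel
  profiles are not modelled, so widths are integer-biased at ±0.5 px.
- The radial-alignment qualification assumes vessels radiate from the
  disc; pathologies that break this geometry reduce the qualified count.
- Tortuosity depends on the segment-cut length (default 30 px); values are
  comparable only across images analysed under one configuration.
- Synthetic validation bounds what can be claimed for clinical UWF images
  (see above); the statistical layer, however, is input-agnostic and fully
  oracle-checked.
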