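# Methods

This note documents the quantification procedures the package implements,
the synthetic-data model used to validate them, the defaults that matter,
and the design choices made where the underlying assay descriptions left
the procedure open.

## Stripe-assay guidance

**Geometry conventions.** Canvas origin is the top-left pixel corner, x
runs rightward, y downward, physical coordinates are `pixel * scale` µm.
"Vertical" stripes are lanes constant along y, so the lane label varies
with x; the orientation vector points along the lanes. All radial
quantities are measured from the neurosphere *rim*, not its center.

**Quadrants.** The plane around the sphere is divided into four 90°
sectors by the ±45° diagonals relative to the stripe direction through the
sphere center; the two sectors bisected by the stripe axis are "parallel",
the others "perpendicular". Boundaries are half-open: the fold of the
angular offset onto [−90°, 90°) is parallel iff it lies in [−45°, 45°), so
a point at exactly +45° is perpendicular and one at −45° is parallel.
This tie-break is arbitrary but fixed, and rotating the orientation by 90°
exactly swaps every label.

**Modified Sholl profile.** Concentric rings are placed every
`ring_spacing` (default 10 µm) beyond the rim. Crossings are counted by
intersecting each polyline segment with each ring circle exactly: the
quadratic `|a + t·d|² = r²` is solved per segment and every simple root
with `t ∈ [0, 1)` counts as one crossing, assigned to the quadrant of the
intersection point. Consequences of this definition:

* tangencies (double roots) count zero crossings;
* a segment that dips across a ring and back inside one step counts both
  intersections (endpoint-sign-change counting would miss these — the
  distance to a fixed point is convex along a segment, so both endpoints
  can sit outside the ring while the interior dips inside);
* the half-open `t` interval means a vertex lying exactly on a ring
  belongs to the outgoing segment's crossing, never to both.

The test suite checks these counts against a brute-force pure-Python
solver on random polyline sets for exact integer equality, and checks
rigid-rotation invariance and parallel+perpendicular conservation.

**Substratum preference.** The neurite mask (Otsu or fixed threshold of
the F-actin channel, objects < 5 µm² removed) is intersected with an
analysis region at least 100 µm beyond the rim, restricted by default to
the parallel quadrants. The score is the mask density on cue lanes
divided by the mask density on laminin-only lanes, each density being mask
area over *available* area of that substratum in the region. The density
correction makes the score exactly 1 for uniform coverage regardless of
lane widths, 0 for complete avoidance, and reciprocal under a cue/LN label
swap. Empty laminin coverage yields a flagged invalid result rather than
a division error. Whether the perpendicular quadrants should also
contribute to the area score is genuinely ambiguous in fixed-assay
descriptions; the parallel-only restriction is the default and is
exposed as a flag.

## Growth-cone morphometrics

**Masking.** The growth-cone ROI is the largest connected component of
the thresholded F-actin channel with holes filled (minimum object area
2 µm²). Zero-variance images yield an empty mask with a warning.

**Filopodia vs. veil.** The lamellipodial veil is the morphological
opening of the mask by a disk of radius 1.5 µm — thin protrusions cannot
survive the opening, so what remains is sheet-like structure. Filopodia
are skeleton branches of the residual (mask minus veil): each branch is
walked from a skeleton endpoint through degree-2 chains to the next
junction or endpoint, and its geodesic length (diagonal steps √2 px)
converted to µm. Two filters make this robust on rendered images: a
branch with a free endpoint within 2.5 µm of the image border is treated
as the axon shaft entering the field and excluded, and branches shorter
than 1 µm are pruned as skeletonization spurs. When a veil exists a
filopodium must touch it (within ~1 µm); with no veil, residual branches
near the shaft tip count instead.

**Collapse call.** A cone is collapsed iff veil area ≤ 5 µm² (veil
disassembled) AND at most 2 filopodia AND every filopodium < 10 µm. The
conjunction is deliberate: a cone with no veil but two 12-µm filopodia is
scored *not* collapsed. All three sub-criteria are carried on every call
so alternate thresholds can be recomputed without re-segmentation, and the
rule is monotone — shrinking the veil and removing or shortening
filopodia can never flip collapsed to not-collapsed.

**ROI intensity.** Mean immunolabel intensity inside the F-actin mask
minus a background estimate: median of a 2-µm dilation annulus (default)
or the field's 5th percentile. The annulus mode is exactly invariant to
additive offsets and equivariant to gain. Values are floored at zero with
a flag. Group normalization divides by the control-group mean, which
therefore equals exactly 1 after normalization (a fixed point, so the
operation is idempotent). Eligibility filters exclude growth cones
< 100 µm from the sphere rim (all assays) and < 300 µm from their cell
bodies for local-protein-synthesis intensity runs.

## Outgrowth kinetics

Fixed-culture outgrowth is the mean of the 20 longest neurite path
lengths per sphere (fewer than 20 → mean of all, flagged). Live extension
rates sum signed per-interval leading-edge displacements and convert to
µm/hr. Single very large retractions are capped at 30 µm per interval —
three times a nominal 10 µm growth-cone length — so one catastrophic
retraction does not dominate; the number of capped intervals is always
reported, and an infinite cap reproduces net displacement over elapsed
time exactly. Note the direction of the cap's effect: loosening it admits
larger retractions, so the estimate is monotonically non-increasing in
the cap value. Whether capping should apply per interval or per
multi-frame retraction episode is an open choice; per-interval is
implemented. 2-D positions are projected onto a growth axis estimated by
total-least-squares over a rolling 5-frame window, oriented along the
track's net displacement; 1-D tracks bypass projection. When a treatment
time is annotated, pre- and post-treatment rates are computed on the
interval prefix/suffix and their ratio reported (flagged when the pre
window has fewer than two frames). Between-sphere variability is compared
with a two-sided F-test on sample variances.

## FRET and G-LISA

Acceptor-photobleaching FRET efficiency uses the donor-dequenching
estimator `E = 1 − I_pre / I_post` on background-subtracted donor means
over the bleach ROI. The raw pre/post means are always emitted so other
definitions of "change in donor/acceptor" can be recomputed. The achieved
acceptor bleach fraction `1 − A_post/A_pre` gates validity: below 0.7 the
estimator is biased toward zero and the result is marked invalid rather
than raised. Estimates are deliberately not clipped at zero — a
non-transferring sensor produces estimates scattered around zero, and
clipping would bias group means upward. Per-ROI means (not per-pixel
distributions) are the measurement unit.

G-LISA absorbances are divided by their sample's protein concentration
(loading correction), then by the mean corrected absorbance of the
control condition; the control mean fold is exactly 1 and the result is
invariant to absorbance units.

## Group statistics

One-way ANOVA uses the standard sum-of-squares decomposition; Tukey
honestly-significant-difference p-values come from the studentized-range
distribution with the Tukey-Kramer standard error, which reduces exactly
to the pooled two-sample t-test in the two-group case. Fisher's exact
test is computed from first principles: conditional on the margins, cell
(0,0) is hypergeometric, and the two-sided p sums the probabilities of
all tables no more probable than the observed one (the probability-mass
convention — stated explicitly because two-sided conventions differ).
Table probabilities are compared as exact integers (binomial-coefficient
weights over a common denominator), so there is no floating-point
tie-breaking; scipy's implementation serves as an independent cross-check
in the tests, never as the implementation. The chi-squared test is plain
Pearson without continuity correction, df = K − 1 for a 2×K table, with a
flag when any expected count is below 5. The report step labels the
experimental unit of every table (growth cone vs. neurosphere) rather
than hiding a pooling decision, and writes CSVs with fixed float
formatting so identical inputs give byte-identical files.

## Synthetic-data model

The generators are pure functions of their parameter objects including
the seed, and always emit ground truth alongside rendered data.

**Scenes.** Stripes alternate equal-width cue and laminin lanes
(default 50 µm, typical of micro-molded patterns); labels are taken at
pixel centers with half-open boundaries, and a periodic analytic label is
used off-canvas. Neurites grow from a sphere of default radius 150 µm
(real spheres run a few hundred µm across) as persistent random walks:
5 µm steps, Gaussian heading jitter (SD 0.25 rad), truncation at 400 µm.
A proposed step *entering* a cue lane is accepted with probability
`exp(−β)`; on rejection the heading is redrawn up to 10 times, then the
step falls back to the lane-parallel direction nearest the current
heading. Penalizing the entering transition rather than presence on cue
matters: a neurite that happens to sprout on a cue lane can still leave
it, rather than being herded along the lane forever (which would invert
the preference score at high β). The acceptance uniform is drawn on every
proposal so that at β = 0 the vertex stream is identical under any stripe
map for a fixed seed. No quantitative turning-angle or speed
distributions exist for these cultures, so the walk parameters are
realistic free knobs, not calibrated values — recovery experiments test
the *pipeline*, not the biology. Measured behavior under the defaults:
mean preference ≈ 1.0 / 0.9 / 0.24 at β = 0 / 1 / 3.

**Rendering.** Traces are rasterized at 1-px linewidth, blurred with a
Gaussian point-spread stand-in (σ = 0.5 µm scenes, 0.4 µm growth cones),
offset by a background and given Gaussian noise. There is no
photorealistic optics model and neurosphere interiors are not drawn.

**Growth cones.** 64-µm fields at 0.25 µm/px. Spread: filled veil disc
(radius 8 µm), shaft to the field border, Poisson(8) filopodia with
Gamma(4, 3.75) lengths (mean 15 µm) radiating from the rim. Collapsed:
thin shaft plus at most two filopodia clipped below 8 µm, no veil. Default
noise SD 0.05 of peak signal over a 0.1 background. Under these defaults
the classifier recovers 100% of 200 generative labels; the acceptance
threshold is 95%.

**Tracks.** Cumulative positions advancing `rate · Δt` per frame (5-min
default), optional retraction events subtracting a fixed magnitude with a
per-frame probability, Gaussian measurement noise (default 0.5 µm).

**FRET pairs.** The cell occupies a disc ROI; donor counts are
`base·(1−E)` before and `base·(1−E·(1−f))` after bleaching fraction `f`
of the acceptor, over a flat background, with per-pixel Poisson noise.
With a full bleach the estimator inverts the generative model exactly;
at a 10⁴ photon budget the mean estimate over 100 seeds lands within
0.001 of truth.

**What passing tests do and do not show.** The synthetic model exercises
the full measurement path (rasterization, blur, noise, thresholding,
morphology, counting) but not fasciculation, uneven illumination,
out-of-focus light, stage drift, or tracing ambiguity in dense outgrowth.
Recovery results therefore validate the quantification code, not its
robustness to every real-microscopy artifact.

## Problem sizes

The validation experiments use 100 random polyline sets (Sholl oracle),
20 scenes × 200 neurites per avoidance level, 200 growth cones, 50 tracks
per rate, 100 FRET pairs per efficiency, and 2000 null ANOVA simulations —
sizes at which every Monte-Carlo band in the checks is comfortably
resolved while a full run completes in well under a minute each.
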