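# Methods

This note documents the models, defaults and numerical choices behind
each stage of the pipeline, what the synthetic data do and do not
emulate, and the design decisions taken where the underlying instrument
leaves them open.

## Synthetic scenes (`synth`)

A scene is a ground-truth list of fibers and non-fibrous particles on a
membrane-filter background, in a field of view of 660 µm × 440 µm by
default (the instrument's composite field), at a default pixel pitch of
0.33 µm/px (2000 × 1334 px). The pitch is a declared choice — the
instrument's sensor is known but not its effective sampling — and is
configurable everywhere.

**Fibers** are constant-width curved line segments: a quadratic Bézier
whose sagitta matches a circular arc of the requested curvature
(`1/µm`, 0 = straight), rescaled so its sampled arc length equals the
requested length. The fluorescence cross-profile is Gaussian with
FWHM = width. **Particles** are soft-edged disks (logistic edge of half
a pixel). Both carry a depth `z` below the filter surface; random scenes
draw depths uniformly in 0–14 µm, reflecting the few-to-fifteen-µm layer
a filter's porous surface occupies.

**Random sampling** (`sample_scene`) draws object counts Poisson with
requested means — defaults 6.5 fibers and 86.2 particles per field, the
per-image averages of the kind of annotated corpus such detectors are
built on — and geometry lognormal: length median 9 µm (log-SD 0.55),
width median 1 µm (log-SD 0.35), intensities lognormal. Everything is
deterministic under `(params, seed)`.

**Rendering** (`render_zstack`): by default 25 planes at 2 µm steps.
Each object's in-focus footprint is blurred per plane with a Gaussian of

    sigma = sqrt(sigma0² + (slope · |z_plane − z_object|)²),

sigma0 = 0.25 µm (diffraction scale for an NA 0.6 objective at ~510 nm
emission) and slope = 0.5 µm blur per µm defocus (geometric-optics
motivated). Background is a constant level plus seeded low-pass texture
(scale 5 µm, 10 % relative amplitude) emulating the entangled-cellulose
membrane; the texture is shared across planes, a deliberate
simplification (its 5 µm correlation scale changes negligibly over the
defocus range compared with the objects). Noise is Poisson shot noise on
the signal (gain 1.0; gain 0 disables it) plus additive Gaussian read
noise (default 2 % of background). Setting both to zero yields exact
noiseless renders, which several tests exploit.

**Ground-truth countability** applies the strict criteria below to true
geometry; fibers whose footprints intersect another fiber's are flagged
aggregates and not countable.

What the generator does *not* emulate: physically rigorous PSFs
(Gibson–Lanni), spectral/staining chemistry, mineral-dependent staining
efficiency, color rendering, filter-surface tilt, or spatially clustered
deposition. Passing tests therefore demonstrate correctness of the
computational chain under a plausible image model, not performance on
real micrographs.

## Focus stacking (`edf`)

Per-plane sharpness is local Laplacian energy: the sum of the squared
4-neighbour discrete Laplacian over a (2r+1)² window, r = 4 px by
default (~1.3 µm, matched to the fiber width scale). The composite takes
each pixel from the plane with maximal sharpness after Gaussian
smoothing of the decision maps (sigma 2 px, suppressing speckle in plane
selection); ties break toward the lowest plane index (nearest the filter
surface), so the operation is fully deterministic, and with smoothing
disabled it is bit-identical to a brute-force per-pixel argmax — a
property the tests verify against an independent loop implementation.
Single-plane stacks pass through unchanged. Wavelet/pyramid fusion and
plane registration are out of scope (the instrument's stage is
motorized; planes are co-registered).

A known, accepted artifact: compositing brings objects at *different*
depths into simultaneous focus, so a fiber and a nearby particle that
never touch in any single plane can merge into one segmented component
in the composite. The depth-coverage property test (composite recovers
at least whatever any single plane recovers, ≥95 % of seeded trials)
uses laterally well-separated fibers and a light particle load so that
this segmentation ambiguity — exercised separately by the recovery and
background-effect tests — does not confound the depth property.

## Detection (`detect`)

The detector is a deterministic classical chain standing in for a
trained object detector, exposing the same counting interface
(candidates, confidences, a 0.32 confidence threshold). No numeric
equivalence with any learned model is implied; its confidence is a
geometric/contrast score sharing only the threshold semantics.

1. **Background subtraction**: grey opening at 10 µm followed by
   Gaussian smoothing of the opened image, subtracted and clipped at
   zero (rolling-ball style).
2. **Threshold**: default `sigma` — median + 6 robust sigmas (MAD-based)
   of the residual. Otsu's rule (floored at that noise level) and fixed
   values are selectable; the k-sigma floor is the default because
   Otsu's threshold is unstable on sparse-object images (it can jump
   several-fold between a single plane and its composite, truncating dim
   fibers). On pure noise the 6-sigma level leaves only sub-minimum
   speckle.
3. **Components**: 8-connected labelling; components < 10 px dropped.
4. **Morphometry** (`measure_component`): the mask (padded one pixel so
   the distance transform sees a border) is skeletonized; the skeleton's
   pixel graph uses Vossepoel–Smeulders step weights (0.980 orthogonal,
   1.406 diagonal) for approximately unbiased digital path lengths.
   Side branches shorter than 2 µm (spurs — e.g. a small particle
   touching a fiber flank) are pruned iteratively; a skeleton that is a
   single open path is never shortened. Length = longest geodesic path
   plus one width (the skeleton retracts about half a width per end);
   width = 2 × (median distance-transform value − ½ px), measuring from
   the object boundary rather than between pixel centres. Endpoints are
   counted after pruning.
5. **Classification**: countable iff length > 5 µm, width < 3 µm,
   aspect ratio > 3 — all strict, so exactly-boundary objects are
   rejected — and, when aggregate exclusion is on, the pruned skeleton
   has ≤ 2 endpoints (the operational aggregate definition; ground truth
   uses footprint intersection). The first failing rule, in the fixed
   order length → width → AR → aggregate → confidence, is recorded as
   the rejection reason for reproducible audit output.
6. **Confidence**: the product of logistic factors on the three
   criterion margins (scales 1 µm, 0.5 µm, 1 in ratio; each factor is
   0.5 exactly on its boundary) and on object contrast (logistic in the
   object-to-background SNR, midpoint 3, scale 1). Monotone
   non-decreasing in every margin. Counted fibers must clear the 0.32
   default threshold.

**Evaluation harness**: greedy nearest-centroid one-to-one matching of
countable detections to countable truth fibers within 3 µm (closest
pairs first); unmatched detections are FP, unmatched countable truths
FN, and truth particles not covered by a countable detection's box TN.
Accuracy is per-object over annotated fibers + particles,
(TP+TN)/total; precision/recall/F follow the usual formulas with
undefined ratios reported as absent, never zero. The 3 µm radius and the
per-object accuracy denominator are design choices; fragmented
detections of long fibers can shift centroids by several µm, so the
qualitative depth-coverage test associates at 8 µm instead.

A per-field background flag is raised when the total number of
fluorescent objects exceeds 80 — the regime in which clusters of
contiguous particles begin to be misread as fibers, raising the
false-positive rate (the test suite demonstrates the direction of this
effect with coarser particles, median radius 0.9 µm, whose chains can
reach fiber-like dimensions).

## Concentration (`conc`)

C = A·N/(a·n·V) with A computed from the filter diameter (π d²/4) so
nonstandard filters are supported. Reported values are rounded to one
decimal place, matching instrument-style output; the raw double is
always retained. Defaults (15 mm spot, 0.66 × 0.44 mm field, one field,
200 L) give a single-fiber equivalent of 3.0426 → reported 3.0 f/L.
`required_fields_or_volume` inverts the formula for the smallest integer
field count (or air volume) achieving a target single-fiber equivalent.

## Agreement statistics (`stats`)

Relative differences are 100·(x−y)/((x+y)/2) %, bounded in (−200, 200)
for positive pairs; (0, 0) pairs have an undefined ratio and are
excluded with the exclusion counted and reported, rather than defined as
zero. Bland–Altman limits use the sample SD (n−1) and z = 1.96 by
default (95 % limits); a single value has no SD and no limits.

The counting simulation models homogeneous Poisson deposition over the
filter (uniform air mixing): each method's total count over its n
disjoint fields is Poisson(λ·n) with λ = C·a·V/A per field, converted
back to f/L through the concentration formula — so the estimator is
exactly unbiased, and inter-method disagreement arises only from
counting statistics. Instrument-specific biases (e.g. mineral-dependent
staining sensitivity) are deliberately not modelled, since no mechanism
for them is established. Consequences verified by simulation: the SD of
relative differences approaches 100·√(2/λ) % for large λ; limits of
agreement widen monotonically as λ falls (the low-count funnel); and
averaging five fields per method narrows the limits by ≈ 1/√5.

## Pipeline (`pipeline`)

One cycle = sample/load a stack → focus stack → detect → convert →
report; per-cycle seeds are master seed + cycle index, so monitoring
runs are reproducible end to end and every report's concentration
satisfies the conversion formula exactly (recomputed independently in
tests). Hardware (filter advance, staining timing, pump control) is
represented only as the cycle boundary. Reports are JSON + CSV summary +
annotated PNG.

## Problem sizes used in the test suite

Tests run the same code paths at reduced raster sizes, chosen as the
package's own trade-off between coverage and turnaround: unit scenes of
100–330 µm fields at 0.5–0.66 µm/px with 9-plane stacks; detector
recovery on 50 seeded full fields (660 × 440 µm) at 0.66 µm/px with
13-plane stacks, high SNR, 5–15 countable fibers and ≤ 40 particles per
field; the depth-coverage property on 20 seeded 220 × 165 µm scenes;
Monte-Carlo statistics at 2000 repetitions. The default full-resolution
geometry (0.33 µm/px, 25 planes) is exercised by construction — all
sizes flow through the same parameters — and by the scene-sampling
calibration tests.

## Known limitations

- The classical detector's precision/recall on synthetic fields says
  nothing quantitative about a trained detector on real micrographs.
- Near-coincident objects (lateral gaps ≲ 2 µm, any depth) merge into
  one component after compositing; attribution is then ambiguous and
  fibers can be rejected as too thick or aggregated.
- Lengths of thresholded Gaussian-profile fibers are overestimated by
  roughly 0.5–1.5 µm at high SNR (profile tails extend above
  threshold); boundary-length fibers can flip either way.
- The Poisson agreement model has no between-method systematic bias, so
  simulated mean relative differences are ~0 by construction.
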