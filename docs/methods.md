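# Methods

This note records the models, defaults and numerical choices behind
arenatrack, and what the synthetic-data validation does and does not show.

## Detection pipeline

**Background.**  The static scene is estimated as the per-pixel median of
an evenly strided frame subsample (default at most 101 samples; an odd
count is preferred so the median is a single order statistic, and an even
count uses the mean of the two central values).  The estimate is exact
whenever each pixel is animal-covered in under half of the samples, which
holds for freely moving animals at the densities the package targets.  An
optional exponential refresh `(1−w)·old + w·frame` serves slow drift in
illumination during long recordings.

**Subtraction and thresholding.**  The difference image is the absolute
per-pixel difference, so dark-on-light (ambient) and bright-on-dark
(darkfield) recordings share one code path.  Intensities are normalised to
[0, 1] regardless of source bit depth, and the threshold comparison is
strict (`diff > T`).  Low-contrast arena footage typically needs T below
0.1; when a pipeline config leaves the threshold unset it is estimated by
an Otsu split of the background-difference histogram, clamped to at most
0.1, and logged as estimated.

**Clusters.**  Connected components use 8-connectivity so diagonally
touching thin animals (larvae) remain one object.  The area gate is a
pixel count, matching how animals are characterised in practice (tens of
pixels per individual in low-quality recordings, hundreds in high-quality
ones).  "Length along the primary axis" is the peak-to-peak extent of
pixel centres projected on the principal axis of the pixel second-moment
matrix, plus one pixel, so a single pixel has length 1 and an axis-aligned
1×N bar has length N.  This projected-extent definition (rather than a
fitted-ellipse major axis) is exactly reproducible from the pixel set and
has an obvious brute-force oracle.  Orientation of degenerate
(single-pixel or isotropic) clusters is reported as 0.

## Tracker

**Cost.**  `c = w_d·d/max_move + w_A·|A−Ā|/Ā + w_L·|L−L̄|/L̄` with default
weights 1, 1, 1 (no weighting is privileged a priori; all three terms are
dimensionless and O(1) for plausible candidates).  A pair is infeasible
when the distance from the predicted position exceeds `max_move` times the
number of frames since the track was last observed.

**Prediction** is constant-velocity with one-step memory (last position
plus last displacement), falling back to the last position for
single-observation tracks — the lightest model that uses trajectory
information at all.  While a track is attached to a merged blob its
prediction is the blob's last centroid (extrapolating across the jump onto
the blob would overshoot), and its gate widens by half the blob length,
since the animal can emerge anywhere along the blob.

**Matching** is globally optimal (Hungarian via
`scipy.optimize.linear_sum_assignment`), not greedy: maximum cardinality
over feasible pairs, minimum total cost among those.  With non-negative
costs a literal minimum-cost matching would be empty, so maximum
cardinality is the intended reading and what the exhaustive-search oracle
in the tests implements.  Ties between equal-cost optima are broken toward
pairing low track ids with low cluster labels via an O(1e-12) index
epsilon; a linear index term sums to a constant over permutations, so the
tie-break uses a product term (rearrangement inequality).

**Merges.**  A cluster is treated as a merged multi-animal blob when its
area exceeds the optional `merge_area` parameter, or when at least two
tracks end up attached to it (its matched track plus unmatched tracks
whose only feasible cluster it is).  All attached tracks record the blob
position flagged `merged` and their mean area/length freeze, keeping the
identity features animal-specific.  `merge_area` is a tracker parameter
rather than the segmentation `max_area` because the segmentation gate
discards oversized components before the tracker ever sees them; users who
want merge handling set the segmentation `max_area` loose enough to keep
collision blobs and set `merge_area` between one and two animal areas.
A size-triggered blob that attracts no tracks is dropped and counted in
the run log, preserving cluster conservation
(found = matched + merged + born + dropped, checked per frame).

**Splits.**  When a merge ends, the attached tracks compete for the new
clusters in the same optimal matching, using the frozen means; matched
tracks clear the merged flag and resume updating.  With equal distances
the feature terms decide — this is what preserves identity through
collisions of animals that differ in size or shape.

**Lifecycle.**  New clusters start provisional tracks that are emitted
(retroactively, including the provisional prefix) only after `min_active`
consecutive matches; a single miss discards a provisional track as noise.
Active tracks missing for more than `max_inactive` consecutive frames are
archived; a track missed for exactly `max_inactive` frames survives and
can be rescued by a match (boundary tested on both sides).

## Trajectory statistics

Displacement is the path length (sum of Euclidean step lengths between
consecutive samples in the window) on raw positions — no smoothing; net
start-to-end distance was the other candidate and path length was chosen
as the quantity that actually reflects crawling effort.  Mean crawl
velocity is displacement over window duration.  Epochs are the maximal
constant-state intervals of the stimulus record intersected with the
trajectory's time span; they tile the span exactly (property-tested).

The paired Wilcoxon signed-rank test is authored here: differences on−off,
zeros dropped, mid-ranks for ties, W = rank sum of positive differences.
The p-value is exact for n ≤ 12 — full enumeration of the 2ⁿ sign patterns
honouring the observed tie structure, two-sided via the symmetry of the
null distribution about half the total rank sum — and uses the
tie-corrected normal approximation without continuity correction above.
All-zero differences give p = 1 by convention (the test carries no
information).  scipy's implementation is used only as an independent
cross-check in the tests.

The identity-preservation score maps tracks to animals once, by
minimum-distance matching on the first common frame, then counts the
fraction of visible, non-merged ground-truth records whose nearest emitted
track position (within `max_move`) belongs to the mapped track.  Merged
frames are excluded because no centroid-based tracker can attribute a
shared blob to one animal; the score is therefore a measure of identity
bookkeeping, not of occlusion segmentation.

## Stimulus and calibration layer

Waveforms are event lists (step functions), not dense samples, so epoch
boundaries are exact.  The intensity ramp includes the value-0 starting
event, giving `max_value + 1` events spanning `max_value · interval`
seconds.  Blinking holds 0 during the initial off period, then alternates
`brightness`/0 phases of one interval each.

The two-clock model is linear, `device = slope·host + offset`, estimated
by least squares; a constant-rate drift of a few seconds per hour
(3.96 s/h is used as the canonical magnitude in tests) is recovered to
1e-6 relative slope error noiselessly and 1e-5 under 5 ms timestamp jitter
at 10 Hz over an hour.  The simulated state log samples the waveform at
the controller's reporting period (default 100 ms, configurable — real
reporting periods are nominal) and stamps each report with the mapped host
time plus optional Gaussian jitter.  Frame-state lookup is
"latest record at or before the frame time", with 0 before the first
record.

The calibration fit is an ordinary least-squares quadratic with
R² = 1 − SS_res/SS_tot, defined as 1 when the target has zero variance;
applied values are clipped below at 0 (negative irradiance is unphysical).
The moving-average filter is causal with a partial warm-up window, so the
output length equals the input length.

## Synthetic arena generator

The generator emulates the two recording regimes: bright blobs on a dark
background (IR darkfield, default background 0.1) and dark blobs on a
light background (ambient).  Defaults mirror the low-quality regime the
package is benchmarked in — 1000×1200 px, 30 FPS, 8 individuals of ~60 px —
and tests also exercise a scaled-down analogue of the high-quality regime
(fewer, larger animals).

Animals are ellipses of the target area (semi-axes from the area and the
major/minor ratio), rasterised by centre-of-pixel inclusion, oriented
along the heading.  Motion is a persistent random walk: the heading gains
a Gaussian perturbation of standard deviation `(1 − persistence)·π/2` per
frame at constant speed, reflecting at walls with a margin that keeps
blobs fully inside.  The kinematic defaults (speed 2 px/frame,
persistence 0.8) are plausible for crawling larvae at this pixel scale but
are stand-ins, not calibrated to any species' measured statistics.
Outside scheduled collisions, pairwise separation is enforced
(candidate step, reversed step, stand still — in that order), so blobs of
different animals are disjoint by construction.

A scheduled collision linearly interpolates the two positions from their
values at the event start to the partner's start position: both pass
through the shared midpoint at mid-window (guaranteed overlap) and have
swapped positions by the event end (guaranteed separation), after which
the random walk resumes along the crossing directions.  The ground-truth
`merged` flag is set when two blobs touch under 8-connectivity — exactly
when a connected-components segmenter sees one object.

Noise is i.i.d. Gaussian per pixel (default σ = 0.01 against blob contrast
0.5 — low-noise but non-trivial for thresholding), clipped to [0, 1].
Frames are rendered canonically in bright polarity and complemented for
dark-on-light, so mirroring polarity and background level yields
bit-identical complements with the shared noise draw.  Determinism: the
trajectory generator is seeded once per call and per-frame noise is keyed
on (seed, frame), so frames can be re-rendered lazily in any order —
long high-resolution videos never need to fit in memory.

**What passing these tests does not show.**  The blobs are rigid ellipses:
no peristalsis, body bending, legs, shadows, reflections, lens distortion
or illumination gradients.  Real recordings add all of these, so 100 %
identity preservation on the synthetic arena bounds what the algorithm can
do when detection is clean; it does not predict accuracy on any particular
real video.

## Problem sizes and tolerances

The test suite and acceptance script choose sizes that exercise each claim
at full strength while staying desk-scale: 300 frames at 1.2 MP for the
no-collision identity run, 100 independent seeds for the collision study
(success = two emitted tracks and 100 % post-split identity), 1000 random
instances for the matching oracle, one simulated hour at 10 Hz for drift.
Float tolerances are 1e-9 against algebraic oracles (normal equations,
pairwise sums) and 1e-12 against enumerations; geometric checks use the
physically meaningful scales (0.5 px centroid error, 5 % area, 2/255
background intensity).

## Known limitations

- The tracker has no appearance model beyond area and length; animals of
  identical size and shape that collide are re-identified only by
  position, which degrades with long occlusions.
- Merge detection requires either a `merge_area` setting or the
  two-attached-tracks condition; two animals whose combined blob stays
  under both radars can exchange identities silently.
- The constant-velocity prediction assumes smooth motion between frames;
  erratic jumpers (startled adult flies) need a larger `max_move`, which
  in turn weakens the gate.
- Video-container input needs an imageio video backend; numbered PNG/TIFF
  sequences are the first-class format.
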