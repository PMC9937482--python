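# Methods

This note documents the conventions, models and numerical choices behind
`vrgaze`, in the order the pipeline applies them.

## Coordinate frame and geometry

All positions are points on the stimulus sphere, written as (longitude,
latitude) in degrees. Longitude 0 / latitude 0 is the world "forward"
direction, where the trial-start fixation cross sits; longitude increases
eastward, latitude toward the north pole; the unit-vector embedding is
v = (cos lat · cos lon, cos lat · sin lon, sin lat). Longitude wraps into
[−180, 180); at the poles, where longitude is undefined, it is fixed at 0.

Distances are always great-circle central angles, computed in the
atan2(‖a×b‖, a·b) form, which is exact for identical inputs and accurate
near 0° and 180° — this matters because recurrence at radius 0 must
recognize identical fixations, and arccos of a dot product cannot
guarantee that. Spherical means are normalized vector resultants; a
resultant below 1e−9 (e.g. antipodal pairs) raises a degenerate-mean error
rather than returning an arbitrary direction.

Quaternions are (w, x, y, z), unit norm, canonicalized to w ≥ 0. Slerp takes
the shorter arc (sign-flipping the second quaternion when the dot product is
negative) and falls back to normalized linear interpolation for
near-parallel inputs; rotation angle between quaternions uses the relative
rotation's atan2 form for the same small-angle accuracy reason as above.

## Preprocessing

The head stream (~70 Hz) is slerp-interpolated to the eye timestamps
(250 Hz). Outside the recorded head span the first/last orientation is held
constant, but at most one median head-frame period of extrapolation is
accepted — holding avoids fabricating rotation at trial edges. World gaze =
head rotation applied to the eye-in-head vector; head point = head rotation
applied to the forward axis. Timestamps are trial-relative milliseconds and
intervals are half-open [start, end).

Combining the eye-in-head direction with head pose is done by rotation
composition (quaternion applied to the vector); this is the only
geometrically well-defined reading of "adding" an eye vector to a head
orientation, and it makes preprocessing the exact inverse of how the
synthetic generator produces eye-in-head samples.

## Fixation detection

The detector is dispersion-threshold identification (I-DT) on the sphere.
Window dispersion is the **maximum pairwise great-circle distance** among
the window's samples. This choice (rather than longitude/latitude ranges or
distance-to-centroid) is rotation-invariant and pole-safe: a plateau at
latitude 89° with 1° of angular jitter is one fixation, whereas any
projected-coordinate criterion would shred it across longitude columns. A
window must span at least the minimum duration (80 ms, measured on the
inclusive sample span t[j] − t[i]); it is then extended sample-by-sample
while dispersion stays within the threshold (3°), the centroid is the
spherical mean of the window, and the next window starts at the first
sample past the fixation. The reported end time is half-open (one sample
period past the last sample), so durations sum like intervals. With the
inclusive-span rule a 79 ms plateau can never be accepted at an 80 ms
threshold, at any sampling phase.

The 3° threshold is treated as a dispersion *diameter* (pairwise maximum).
A centroid-radius variant would accept slightly wider windows; the pairwise
form is the stricter, more conservative reading, and the threshold is a
parameter for sensitivity analyses.

Head fixations are spherical means of the head point over each eye
fixation's [start, end). Saccade amplitudes and head shifts are angular
distances between successive centroids; exploration tendency is the mean
great-circle distance of fixations 2..n from fixation 1 (0 for a single
fixation). No minimum saccade duration is imposed between fixations.

## Spatial statistics

Per-trial spreads: longitudes are rotated so their circular mean sits at 0°,
wrapped, and given an ordinary sample SD (ddof 1); latitudes use the plain
SD. Recentering makes the longitude SD seam-independent for unimodal
distributions ({179°, −179°} gives ≈1.41°, not ≈253°), though a genuinely
bimodal antipodal trial is still summarized conservatively. Phase summaries
are medians across trials.

Heatmaps deposit exp(−d²/2σ²), σ = 4°, at every grid-cell center within 3σ
great-circle distance of a point (the truncation loses <0.2% of kernel
mass), on a 1° equirectangular grid, then normalize to unit mass. Because d
is angular, kernels remain isotropic on the sphere — mass near a pole
spreads over many longitude columns instead of pinching.

The equirectangular projection stretches area by 1/cos(latitude), so
heatmap correlations weight each cell by cos(latitude of its center) — the
exact inverse of the distortion. The weights enter the correlation only;
smoothing is already area-faithful because the kernel is angular. For
points uniform on the sphere the cos-weighted cell density is flat across
latitude bands, which the test suite verifies directly. Zero-variance maps
make the correlation undefined (nan with a warning), never silently 0.

Same-vs-different contrasts compare the mean correlation over same-scene
pairs with a seeded random derangement of scene partners, paired t across
scenes. Heatmaps are built from fixation centroids, not raw samples.

## Cross-recurrence analysis

Sequences are adjusted to equal length by truncating both to the shorter
length, keeping the leading fixations: this preserves temporal alignment
from trial onset, which the line- and CORM-based measures rely on.
Resampling would fabricate fixations. r_ij = 1 iff the angular distance
between encoding fixation i and recognition fixation j is ≤ the radius
(ties inclusive; a flag-level change would make it strict).

Measures (min_line = 2, the standard recurrence-quantification convention;
min_cluster = 8; natural-log entropy):

* REC = 100·Σr/N²;
* DET = percent of recurrent points on diagonal runs of length ≥ 2, over
  all diagonals parallel to the main one;
* vLAM/vTT = percent of points on vertical runs (consecutive encoding
  indices i at a fixed recognition index j) and their mean length;
  hLAM/hTT the same for horizontal runs — the two are exact transposes of
  each other;
* CORM = 100·Σ(j−i)r_ij / ((N−1)·Σr_ij), normalized so the extreme corner
  (i=1, j=N) gives +100; positive values mean recognition dwells on
  locations fixated early in encoding (primacy), negative means recency;
* CLUST = percent of points in 8-connected components of ≥ 8 points,
  counting points that also lie on lines;
* ENT = Shannon entropy of the diagonal run-length distribution, in nats.

Undefined cases (no recurrences, no qualifying runs) are reported as
missing (nan) and excluded listwise per measure in aggregation, with counts
visible in the summary — coercing them to 0 would bias condition means
toward dissimilarity.

Radius calibration bisects on [0°, 180°] for the smallest radius whose mean
REC over a set of sequence pairs reaches the target (7%, low enough to be
selective yet dense enough to populate the line measures). Mean REC is a
nondecreasing step function of radius; with realistically many pairs the
steps are far below 0.05 percentage points, and a coarse pair set that
jumps past the target triggers a warning. Eye and head radii are calibrated
separately (head points are smoother and differently dispersed than eye
points, so a shared radius would conflate the two).

## Synthetic study generator

The generator is the package's stand-in for raw recordings; it encodes the
paradigm's behavioural structure, not any particular image set.

* **Scenes** are mixtures of von Mises–Fisher regions of interest (ROIs):
  longitude uniform, latitude von Mises around the horizon with
  concentration κ_h = 8 (SD ≈ 20°, matching the strong horizon bias of
  panoramic viewing), 8 ROIs per scene with Dirichlet weights and
  per-ROI concentration κ = 80 (≈6.4° SD).
* **Fixation sequences**: the first target is the fixation cross at (0°, 0°);
  subsequent targets are drawn from the scene's ROIs, or with probability ρ
  (default 0.2) from the participant's 4 private ROIs — ρ is the
  image-driven vs idiosyncratic dial. Plateau durations are gamma (shape 4,
  mean 200 ms), clipped at ≥100 ms; successive targets are kept ≥5° apart;
  saccades run along great circles for 20 ms + 2 ms/deg (capped at 60 ms).
  The final plateau extends to the trial end when the remainder could not
  hold a saccade plus a full plateau. These three constraints make every
  generated plateau individually detectable, which is what lets the test
  suite demand exact ground-truth recovery in the noise-free limit.
  Within-plateau jitter is vMF with κ = 10⁴ (≈0.6° SD); κ = ∞ disables it.
* **Head**: the head target for each fixation sits at fraction g (gain ×
  a per-participant mover scale, defaults 0.8 × U(0.7, 1.3)) along the
  great circle from the trial-start direction to the eye target, and head
  transitions follow the eye's saccades with an 80 ms lag. Head orientation
  is the roll-free rotation taking forward to the head direction, sampled
  at 70 Hz. Recorded eye-in-head vectors are computed by inverting the
  *slerp-interpolated* head stream, so preprocessing reconstructs world
  gaze exactly rather than approximately.
* **Recognition narrowing**: during recognition only a fraction f (default
  0.5) of the scene's ROIs is eligible, producing the smaller spatial
  spread characteristic of recognition viewing.
* **Responses**: correctness is logistic in realized exploration — baseline
  log-odds 2.4 (≈92% accuracy), plus 0.8·z(encoding exploration) for old
  scenes, minus 1.2·z(recognition exploration). This reproduces the
  *direction* of the standard memory effects (more encoding exploration →
  later hits; less recognition exploration → correct decisions) without
  claiming their magnitudes.
* **Design**: defaults follow the reference paradigm — 80 encoding scenes,
  40 repeated + 40 new recognition trials in randomized order, 10 s trials,
  250 Hz eye / 70 Hz head. All randomness descends from one SeedSequence;
  identical config + seed reproduces the dataset bit for bit.

What the generator does **not** emulate: real image saliency, smooth
pursuit, blinks and tracker loss, vergence/depth, torso movement, and any
correlation structure between scene content and memorability beyond the
exploration-based response model. Passing tests therefore establish the
correctness and the directional behaviour of the *analysis*, not empirical
claims about human viewing.

## Statistics

Spreads and movement measures are contrasted with Mann–Whitney U tests,
exact (full permutation null) whenever both groups have ≤25 observations
and no ties, normal approximation otherwise. The 2×2 (image × participant)
repeated-measures ANOVA on per-participant condition means is standard
within-subject ANOVA plumbing; participants with missing cells are dropped
with a warning, and constant data yields nan F-values rather than an
exception. Model-based inference (mixed models, odds ratios) is
deliberately out of scope: the package's claim is measure extraction and
direction-preserving contrasts.

## Problem sizes in the test suite

Simulated studies in the tests and the acceptance script are scaled-down
versions of the full design, chosen so that the tested directions are
properties of the generative structure rather than of sample size: the
spread-direction check uses 100 studies of 24 scenes × 4 s trials; the
condition-pattern check uses 20 participants × 16 scenes at full 10 s
trials; heatmap contrasts use 40 scenes; the acceptance script runs 6
participants × 24 scenes at full trial length. Directions were verified
stable at these sizes before the thresholds were frozen.

## Known limitations

* The longitude-spread SD assumes a unimodal longitude distribution per
  trial; antipodally bimodal trials are summarized conservatively.
* Greedy I-DT segmentation is not guaranteed monotone in its thresholds in
  adversarial cases, although it behaves monotonically on plateau-structured
  gaze (tested).
* Heatmap cells are weighted by cos(latitude) at the cell center; at 1°
  resolution the within-cell variation of the weight is negligible, but at
  very coarse resolutions a cell-integrated weight would be preferable.
* Truncation-based length adjustment discards late fixations of the longer
  sequence; measures emphasizing late-trial behaviour should be interpreted
  accordingly.
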