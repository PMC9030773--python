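# Methods

`gazebiom` implements an implicit, stimulus-independent eye-movement
biometric pipeline for wearable eye-tracking recordings of pedestrians
following real-world routes, together with a synthetic cohort generator
that makes every stage testable without access to private recordings.

## Data model and quality filtering

A *recording* is one subject's event stream on one route: time-ordered
fixations, saccades and blinks, optionally backed by raw 60 Hz binocular
gaze samples on a 1280 × 960 scene-camera frame (origin top-left, y down).
Saccade direction is stored in radians with 0 = rightward and positive =
up on screen (counter-clockwise), i.e. `atan2(-dy, dx)` in image
coordinates. The *tracking ratio* — the fraction of valid samples — is the
quality measure: recordings strictly below 70% are excluded (a ratio of
exactly 0.70 is kept).

## Event detection (I-DT stand-in)

When only raw samples are available, a dispersion-threshold (I-DT)
classifier stands in for the proprietary vendor filter. A fixation is a
maximal sample window whose bounding-box dispersion
(max x − min x) + (max y − min y) stays ≤ 50 px for ≥ 80 ms; runs of
invalid samples ≥ 70 ms are blinks; remaining inter-fixation intervals are
saccades with amplitude/direction from the fixation centroids and
kinematics from finite differences. I-DT was preferred over a velocity
threshold because one sample at 60 Hz is 16.7 ms, making velocity
estimates noisy. *Saccade latency* has no conventional definition in
continuous viewing (there is no stimulus onset); it is defined here as the
time since the previous saccade's offset and documented as a stand-in.
The detector does not compensate for head movement — the main advantage of
the vendor filter — so detection quality on real walking data will be
lower than on the synthetic renderings used in tests.

## Segmentation

Each recording is divided into contiguous, non-overlapping windows of
length `T_win` starting at t = 0; the trailing remainder is discarded
(103 s at T_win = 10 s → 10 segments, last 3 s ignored). The experiment
grid sweeps T_win from 5 s to 100 s in 5 s steps (20 windows). Events are
assigned to the segment containing their onset; an event spanning a
boundary is truncated at the boundary for duration statistics, conserving
total fixation time over the covered span. Segments with zero events are
retained and yield zero-filled features: dropping them would silently
change the sample count per subject.

## Feature sets

Per segment, five named blocks (joins are by column name, never position):

1. **Basic statistical (93)** — eight statistics (mean, SD, median, max,
   min, 1/4 and 3/4 quantile, skewness) of eleven event metrics (fixation
   duration and dispersion; saccade duration, amplitude, mean velocity,
   latency, mean acceleration, acceleration peak, deceleration peak,
   velocity peak; blink duration), plus fixation/saccade/blink frequency,
   scanpath convex-hull area and scanpath length: 11 × 8 + 5 = 93.
   Quantiles use linear interpolation; SD uses the n−1 denominator (0 for
   n < 2); skewness is the biased Fisher–Pearson g1 (0 for n < 3 or zero
   variance); empty metric lists yield zeros so the forest always receives
   dense input. Frequencies are events per second, making windows of
   different T_win comparable. All spatial units are scene-camera pixels —
   no angular calibration model is available for a head-mounted scene
   camera.
2. **Pupillary response (8)** — the same eight statistics of the
   per-sample mean of left and right pupil diameter (mm); fixation-level
   mean pupil values stand in when raw samples are absent.
3. **Fixation density (400)** — an isotropic Gaussian kernel (σ = 32 px
   ≈ frame width/40, configurable) at each fixation centroid, one unit of
   in-frame mass per fixation (kernels truncated at the frame edge are
   renormalized), aggregated onto a 20 × 20 grid and flattened row-major;
   the vector sums to 1 whenever the segment has a fixation. Cell masses
   integrate the kernel exactly via separable Gaussian CDF differences;
   a midpoint shortcut exists (`exact=False`) but is coarse when σ is
   below the 64 × 48 px cell size, which is why exact integration is the
   default. Duration weighting is available but off by default.
4. **Fixation semantic (40)** — per-class fixation count (FC) and summed
   fixation duration (FD, ms) over 20 classes (19 street-scene classes
   plus 'map', the handheld paper map). Because a class that crowds the
   scene attracts gaze regardless of the viewer, FC/FD are divided by
   `N_pixel[class]`, the class's mean pixel count over the route's video
   frames (0 where N_pixel = 0: an absent class can attract no gaze);
   the adjusted variant feeds the classifier by default and both variants
   are available. Pixel statistics are keyed by (route, subject). Labels
   come either precomputed per fixation or from per-frame class rasters:
   the label is the raster class under the centroid at the frame nearest
   the fixation's temporal midpoint, with a map-region override.
5. **Saccade encoding (40)** — each saccade becomes one character from 8
   direction sectors (counter-clockwise from rightward: `r e u f l g d h`,
   a 4-sector variant exists), lowercase below an amplitude threshold and
   uppercase at/above it. Overlapping n-grams of lengths 1–3 over the
   per-segment string are *micropatterns*; the 40 most frequent in the
   training partition (ties lexicographic) form the wordbook, and features
   are wordbook-entry counts normalized by string length. The amplitude
   threshold is the training-partition median amplitude — fixed angular
   thresholds are meaningless without calibration. Both threshold and
   wordbook are *fold-fitted*: refit inside every training fold, never on
   test data; a test deliberately corrupts this guard to prove it matters.

Combined features are the five blocks concatenated by name
(93 + 8 + 400 + 40 + 40 = 581 columns; 182 features when the density map
is counted as one).

## Recognition protocols

A random forest with 500 trees and sqrt(n_features) candidate features per
split (scikit-learn) is used throughout, seeded for reproducibility.

* **Identification (one-to-many)** — multiclass over subjects. Two CV
  schemes: segment-level stratified 10-fold over the pooled routes
  (stratification by subject avoids subject-absent folds at small n;
  segments of one recording can fall in both train and test, an
  optimistic-bias caveat inherited from the protocol), and
  leave-one-route-out (LORO), which withholds every segment of one route
  so train and test stimuli never overlap — the stimulus-independence
  test. Subjects absent from a LORO training fold are scored but flagged.
* **Verification (one-to-one)** — per claimed subject: genuine = that
  subject's segments, impostors = an equal-sized uniform sample without
  replacement from the other subjects' segments, stratified 7:3
  train/test split, binary forest, genuine-class probability as score.
  The aggregate is the unweighted mean over subjects.

The full grid enumerates 39 × 20 × 6 = 4,680 verification runs and
(10 k-fold rounds + 4 LORO routes) × 20 × 6 = 1,680 identification runs.

## Evaluation

Candidates are ranked by forest class probability, ties broken by class
order. Rank-k identification rate is the fraction of test segments whose
truth is in the top k; the CMC curve traces it over k (nondecreasing,
1.0 at k = n); accuracy is its k = 1 point, and chance is 1/n subjects.
The ROC sweeps a threshold over scores; the EER is the operating point
where FPR = FNR, linearly interpolated between adjacent thresholds.
(Defining EER as "TPR = FPR" is degenerate — a random scorer satisfies it
everywhere — so the FPR = FNR convention is used.) Identification ROC is
micro-averaged one-vs-rest over candidate scores.

## Synthetic cohort generator

The generator emulates the *structure* of a wayfinding study — 39 subjects
× 4 routes by default, recording durations truncated-normal
(mean 418.58 s, SD 102.02 s, bounds 87–733 s), 60 Hz sampling, tracking
ratios normal (mean 93.37%, SD 4.99%) — and gives each subject a trait
profile the features are meant to detect: lognormal fixation durations
(base mean ≈ 0.31 s), gamma saccade amplitudes (mean ≈ 90 px), von Mises
direction bias, a "main-sequence" power law peak_velocity = c·amplitude^0.6
with subject-specific c (so velocity features carry identity), per-minute
Poisson blink and map-glance rates, a pupil baseline with slow sinusoidal
drift, a 2-D spatial-bias Gaussian, and a 20-class semantic preference
simplex. Route scene composition is a Dirichlet draw with street-scene
pseudo-counts (road/building/vegetation/sky heavy). Fixation labels are
drawn ∝ availability × preference; map glances relocate the fixation to a
lower-central frame region and label it 'map'.

The gaze path is a mixture walk: relative steps with the drawn
gamma/von-Mises displacement, occasional re-centering steps
(probability 0.2) whose endpoint is drawn from the spatial-bias Gaussian,
and map-glance jumps. Stored saccade amplitude/direction are always
recomputed from the actual consecutive centroids (clipped to the frame),
so events and scanpath are exactly consistent; sub-pixel clipped
displacements keep the drawn direction, since a geometric direction is
meaningless at that scale. A single `heterogeneity ∈ [0, 1]` knob scales
every between-subject spread: at 0 all profiles are identical, so
downstream identification must sit at chance and verification at 0.5 —
the null the acceptance suite checks; at 1 the default spreads apply.

What the generator does *not* emulate: head movement and vestibular
artifacts, route-level familiarity effects, task switching within a walk,
pixel-level scene rasters (labels are generated directly), or photometric
pupil response. A green identity-recovery test therefore establishes that
the pipeline detects the trait structure the generator encodes — not that
real wayfinding data would yield any particular accuracy.

## Numerical choices and degenerate inputs

Empty segments → zero-filled feature vectors; empty value lists → zero
statistics; < 3 non-collinear fixations → zero hull area; empty saccade
strings → zero encoding vectors; N_pixel = 0 → adjusted semantics 0.
Wordbook ties break lexicographically; candidate-ranking ties break by
class order. Quantiles are linear-interpolation; EER is linearly
interpolated. All randomness flows from explicit integer seeds
(numpy `default_rng` / SeedSequence spawning, kept below 2³¹).

## Known limitations

Real vendor event streams (head-motion-compensated) will differ from both
the I-DT stand-in and the simulator's ideal events. The 10-fold protocol
shares recordings between train and test by design. Verification impostor
sampling is one draw per subject (no repeated resampling), matching the
protocol but adding sampling variance at small cohorts. Saccade metric
units are pixels, so absolute values are not comparable across camera
geometries.
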