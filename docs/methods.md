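# Methods

This note documents the models and procedures `fomopipe` implements, the
parameter choices that matter, what the synthetic generators emulate, and
the numerical decisions taken where the design was genuinely open.

## Task structure and units

All analyses are organized around a trial schedule: cue onsets with a 10-s
tone, a 15-s transparent-barrier window, inter-trial intervals uniform in
[40, 60] s, 60 trials per session, and an initial 245-s habituation delay
before the first onset.  Video runs at 30 fps, calcium imaging at 10 Hz,
photometry at 20 Hz per channel.  Image coordinates have the origin at the
top left with y increasing downward; angles are radians; distances are
pixels (no metric calibration is attempted).

## Behavioral features

Keypoint preprocessing is linear interpolation of missing coordinates over
time (edge values held) followed by a centered moving mean, default window
5 frames; a node missing on every frame is an error rather than a guess.
The feature set and conventions:

* velocity and acceleration from torso displacement (px/s, px/s²), with the
  first frame(s) padded by the nearest defined value;
* `angle_to_port` is the unsigned angle in [0, π] between the head
  direction (ear-midpoint → nose) and the nose → port vector (the sign
  convention is not meaningful for the analyses and is not assigned);
* tortuosity over trailing (causal) 1-s and 5-s windows, defined as path
  length / net displacement, clipped below at 1; frames with an incomplete
  window, or with both path and displacement zero, take 1.0;
* turning angle is the absolute wrapped frame-to-frame change in heading;
* "change in nose–tail distance" is its first difference;
* discrete features: arena zone of the torso (1–3 from two x-edges), port
  orientation (angle ≤ `orient_angle_max`, default π/6), barrier contact
  (|nose_x − barrier_x| ≤ `barrier_contact_dist`, default 30 px), their
  conjunction, and huddle quality (cagemates within a port radius;
  constant 0 and excluded from z-scoring when no cagemate tracks exist).

Continuous features are z-scored over the full session; a zero-variance
continuous column is an error naming the column, not a silent NaN.

The attending geometry predicate — barrier contact AND port orientation —
is defined once (`features.attending_geometry`) and shared by the synthetic
generator's ground truth, which is what makes the feature stage's
`oriented_and_touching` column exactly reproducible against planted truth.
The thresholds are free parameters of the arena config, not measured
quantities.

The HMM observation subset uses four named continuous features (distance
and angle to port, velocity, turning angle) plus body acceleration as the
fifth — the set is configurable — and the two discrete features (zone,
port orientation).

Freezing/dashing velocity and acceleration thresholds, the dash threshold,
and the reward-seeking distance threshold are configuration parameters with
no privileged defaults; the scores are defined (freeze iff velocity and
|acceleration| both sub-threshold; dash iff velocity above its threshold;
dash/freeze ratio over the 0–15 s post-cue windows, undefined — NaN, never
infinite — when no freeze frames exist).

## Supervised behavior detection

The detector regresses per-class heatmaps from single grayscale frames, the
way pose-estimation networks localize keypoints.  Targets are unnormalized
Gaussian bumps (peak 1, default σ 2 px) at each point label, combined by
elementwise max.  The network is a compact fully-convolutional design in
numpy: a configurable encoder of 3×3 convolution blocks (default widths
8/16/16/16, strides 2/2/2/1), three nearest-neighbor 2× upsampling stages
each followed by a convolution, and a sigmoid head; with the default
strides the output returns to input resolution.  Training uses Adam
(lr 2·10⁻³) on positive-weighted binary cross-entropy (pos-weight 20, MSE
available), deterministic given the seed.  The small default backbone keeps
training CPU-feasible; a deeper encoder is a config choice with the same
three-upsampling/sigmoid contract.

Non-maximum suppression takes strict local maxima on the 8-neighborhood
(out-of-image neighbors are −∞), visits candidates in descending
confidence with row-major tie-breaking, and suppresses any candidate within
Euclidean distance ≤ radius of a retained peak.  Defaults: confidence 0.5,
radius 16 px at input scale (6 px on the 64-px synthetic frames).  Peak
coordinates are reported at input resolution (× output stride), without
sub-pixel refinement.  A frame is positive for a class iff it retains at
least one detection.

## Trial quantification

Per trial, attending frames are counted in the 5-s pre-cue baseline and in
three 5-s bins over 0–15 s; Δbin = bin − baseline and total Δ is their
sum.  Trial labels use the median rule: the global threshold is the median
of per-trial counts pooled over all animals and conditions; the local
threshold is the median over one animal's trials across its conditions.
"More than the threshold" is read as strict inequality, so ties fall to
not-attending and all-equal counts yield zero attending trials.  The
top-15/bottom-15 selection stably sorts trials by count (ties keep trial
order): the bottom set is the first 15, the top set the last 15, which
makes the two sets disjoint and deterministic even under heavy ties.  Lick
bouts (formalin assay) are maximal positive runs, with runs separated by
fewer than `gap_frames` negatives merged; duration is total positive
frames / fps.

## State models

`embed_and_cluster` restricts frames to the 0–15 s post-cue windows, embeds
with UMAP (2 components, seeded) and clusters the embedding with DBSCAN.
UMAP/DBSCAN hyperparameters are configuration (defaults: 15 neighbors,
min_dist 0.1, eps 0.5, min_samples 10).  Cluster annotation as
attending/not-attending is a user-supplied map in real use; for synthetic
data a heuristic auto-annotation labels clusters whose mean
`oriented_and_touching` exceeds 0.5.

The second-stage HMM observes one-hot syllable indicators concatenated with
the feature subset.  Emissions are Gaussian per state; the default
covariance is full, with a diagonal ridge (10⁻⁶) applied after every
M-step so the near-degenerate one-hot block stays invertible (EM is run by
`hmmlearn` behind this module's surface).  Fitting takes the best of
`n_init` restarts (default 5) by train log-likelihood; the EM trace is
recorded and is non-decreasing up to tolerance.

State-count selection scans K = 2..12.  Raw train log-likelihood is
monotone in K and cannot select on its own, so the default criterion is the
BIC minimum; maximizing held-out log-likelihood on a trailing 20% split is
the alternative.  All candidate scores are recorded on the returned model.
On planted 4-state data the scan recovers K = 4; the planted state means
are placed along mutually orthogonal directions at ≥ 5 within-state SDs,
because a collinear layout lets one elongated full-covariance Gaussian
cover several states and makes the K-scan answer a different question.

State metrics: occupancy (frames/fps; sums exactly to session duration),
dwell time (mean run length), stickiness (self-transitions / outgoing
transitions), and two transition-matrix normalizations — whole-matrix (all
entries sum to 1, the display convention) and row-stochastic.

## Calcium analysis

PSTHs cover [−5, +15] s at 10 Hz with per-neuron-per-trial z-scoring
against the [−1, 0) s baseline: z(t) = (F(t) − F̄m)/SD.  A zero baseline SD
flags and excludes that neuron-trial.  Note a short (10-sample) baseline
makes 1/SD upward-biased, so a planted +a step reproduces a mean z slightly
above a; the tests account for this exactly rather than pretending the
estimator is unbiased.

Responsiveness is a paired Wilcoxon signed-rank test of per-trial mean z
in the 5-s baseline vs the 5-s event window, at raw α = 0.05 (a
Benjamini–Hochberg switch exists but is off, matching the reporting
convention of the analysis this package implements); excited/inhibited is
the sign of the mean z over 0–15 s.  At least 6 trials are required.

Ensemble clustering concatenates each neuron's mean response profiles
across conditions, computes correlation distance (1 − Pearson r), builds a
Ward linkage on it, and cuts at 30% of the maximum linkage height.  Ward
formally presumes Euclidean geometry; the Ward-on-correlation combination
is used deliberately as the method's stated recipe.  Constant profiles have
undefined correlation and are excluded with a warning (label 0).

Decoding follows a strict train-set-only PCA contract: the basis is fit on
trial-averaged activity from training folds only, components are kept to
90% cumulative explained variance, and single trials are projected with
those fixed coefficients.  The GLM is L2-penalized logistic regression
(C = 1); the SVM is linear.  A classifier is trained per timepoint on a
class-balanced subsample of the training fold (majority class subsampled),
and auROC is computed per timepoint from the continuous decision values of
held-out trials; the window average (presets 0–5, 0–10, 10–15 s) is taken
per fold.  The shuffled control permutes training labels with the same
folds and seeds.  One-vs-all decoding tests each class against a
trial-matched subsample of the rest, repeated 3 times with fresh
subsamples; 5-fold cross-validation is the default (10-fold where more
trials are available).

Trajectories are trial-averaged activity projected into the 90%-variance
subspace and resampled to 100 bins; geodesic length is the sum of
Euclidean distances between adjacent bins, and between-trajectory distance
is computed bin-by-bin.  Leave-one-animal-out replicates drop all of one
animal's neurons per iteration while reusing the same PCA coefficients (the
number of iterations is the number of animals); a single-animal group is
flagged as degenerate.  Visualization would use 2–3 components but all
quantification uses the 90% subspace.

## Photometry

Both channels are median-filtered with a forward-only (causal, trailing)
200-ms window — "forward only" excludes centered windows — with partial
windows at the start.  Regression coefficients (one slope/intercept pair
per session, ordinary least squares) are fit on the [−1, 0) s pre-cue
segments averaged pointwise across trials, which keeps evoked transients
out of the fit; the fitted reference projection is then subtracted from the
signal over the whole session.  Each trial's corrected trace over
[−5, +20] s (right endpoint inclusive) is z-scored against its own
[−1, 0) s baseline, so baselines have mean 0 and SD 1 by construction, and
the whole correction is invariant to scaling both channels by a common
positive factor.  The residual itself (not a ΔF/F of it) is z-scored, per
the stated order of operations.  Trial AUCs are trapezoidal integrals of z
over sensor-specific windows: 0–20 s for dopamine and oxytocin sensors
(slower dynamics), 0–15 s for the endocannabinoid sensor.

A note on the averaged-baseline fit: averaging across trials suppresses
not only transients but also the (trial-independent) artifact variance, so
the slope estimate is noisier than a pooled fit would be; this is the
procedure as specified, and the synthetic-recovery tests pass under it.

Random-forest decoding treats (trial, timepoint) pairs in a window as
samples with the z value as the feature, partitions folds at the trial
level (no trial straddles train and test), pools all held-out predicted
probabilities into a single ROC, and repeats with trial-level shuffled
training labels on the same folds.  Defaults: 5 folds, 500 trees
(unlimited depth); tests use fewer trees for speed.

## Synthetic data

The generators emulate the study conditions: 60-trial schedules with the
cue/wall/ITI structure above; pose tracks driven by a two-state semi-Markov
bout process (geometric bout lengths, mean 1 s, cut at window boundaries)
in which attending bouts relax the nose to within barrier-contact distance
oriented at the port and other bouts wander the subject's half of the
arena; grayscale frames rendered as Gaussian blobs at the keypoints plus a
faint barrier line; calcium rasters as planted response templates (alpha
shape, τ = 2 s, amplitude 3 ± 20% vs unit noise; 30% excited / 20%
inhibited / 50% null by default) convolved at cue onsets; photometry as
transients (fast-rise, 2-s decay) plus a shared low-pass motion artifact
(SD 0.5, known per-channel gain), a slow bleach (amplitude 0.1,
τ = 600 s) and white noise (SD 0.02) in two already-demultiplexed 20-Hz
channels; and per-frame syllables drawn from per-state categorical
distributions (default: 70% of mass on a state-specific block of an
87-symbol alphabet).

Missing keypoints are injected i.i.d. per coordinate.  All draws flow from
one seed through per-stage child generators, so outputs are byte-identical
for a fixed config.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: mouse biomechanics and realistic pose error
structure (occlusion, identity swaps), video compression artifacts,
sensor-specific photometry kinetics beyond a single template, correlated
neural noise and slow drift, and any real relationship between behavioral
state and neural activity (couplings are planted explicitly where a test
needs them).  Recovery results on this fixture demonstrate correctness of
the procedures, not performance on recordings.

## Problem sizes used in validation

The test suite and the acceptance script scale simulations to desk size:
state-count recovery uses 10 sessions of 2,000 frames (tests) or 8,000
frames (acceptance script) with 5 EM restarts per candidate K; the
detector trains on 200 rendered 64×64 frames for 10 epochs and is scored
on 100 held-out frames; responsiveness calibration uses 500 null neurons
over 20 trials; decoder controls use 100 trials per path.  These sizes were
chosen so each check is statistically decisive at common-seed
reproducibility.

## Known limitations

* The numpy CNN is intentionally small; it demonstrates the
  heatmap-regression + NMS detection contract, not state-of-the-art
  detection.
* Ward linkage on correlation distance departs from Ward's Euclidean
  assumptions (kept deliberately; see above).
* The HMM's Gaussian treatment of one-hot syllable indicators is a
  numerical convenience of the cited approach; a mixed
  categorical+Gaussian emission would be the principled alternative.
* Huddle quality requires cagemate tracks; without them the column is a
  constant 0 and carries no information.
* Multi-animal tracking, camera calibration, source extraction, motion
  correction and cell registration are out of scope; co-registered neuron
  ids are inputs.
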