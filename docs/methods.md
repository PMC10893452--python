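# Methods

## Orientation representation and kinematics

Head orientation is a unit quaternion per sample (world-to-head), stored
scalar-last internally and scalar-first (`qw,qx,qy,qz`) in trace files.
The axis convention follows game-engine head tracking: Y up (rotation
about Y = yaw, a left/right turn), X left/right (rotation about X = pitch,
an up/down turn), Z forward (roll). Euler angles use the intrinsic Y-X-Z
decomposition. Quaternion double-cover is resolved by sign-aligning
consecutive samples before any geodesic computation.

Raw HMD streams have jittered timestamps; `resample_uniform` slerps onto a
uniform grid (canonical rate 90 Hz, the headset refresh) before any
derivative is taken. Derived signals:

- **angular speed** — geodesic angle between consecutive quaternions over
  the sample interval (deg/s). The first sample copies the second so all
  series stay length-aligned; derivative series use central differences
  with one-sided ends for the same reason.
- **per-axis angular velocity** — by default the derivative of unwrapped
  Euler angles (matching how engine rotation logs are analyzed), with a
  quality mask at |pitch| > 89° where Euler rates are unstable; body-frame
  rates from quaternion differencing are available via `method="body"`.
  These two notions differ away from small pitch; Euler-rate is the
  default because the axis-wise channels of the classifiers are defined
  on engine rotations.
- **head-angle magnitude** — angle between the rotated forward vector and
  world forward, in [0°, 180°].

Window durations given in milliseconds convert to samples as
`max(1, round(ms * rate / 1000))`; Savitzky–Golay windows are forced odd
by rounding up. The generic low-pass is a 4th-order Butterworth applied
forward-backward (zero phase), so filtered zero crossings are not
time-shifted — this matters for DIZCO's segmentation.

## Classifiers

**BMAT.** Per-axis velocity mean and SD are estimated on the 500 ms
stationary fixation window that starts each trial (pooled across trials);
a sample is moving when Σ_axis ((v − μ)/(n·σ))² > 1. σ is floored at
10⁻⁶ deg/s per axis; a baseline with zero variance on *all* axes is
rejected as unusable (the ellipse is undefined — in practice it means the
baseline window contains no tracker noise at all). The ellipse is
centered on the baseline mean; the robust median-based scale estimator
used in microsaccade detection is available behind
`use_median_estimator`. BMAT emits per-sample labels with no minimum
duration; `labels_to_events` converts runs to events.

**SVT.** Angular speed is Savitzky–Golay smoothed (default window 122 ms
≈ 11 samples, polyorder 3 — mild smoothing that preserves bell-shaped
speed profiles). Every local maximum of the smoothed speed above
threshold seeds an event; from the peak the algorithm walks outward to
the nearest acceleration zero. The walk is two-phase: first leave the
above-threshold region, then continue to the nearest local minimum of
the smoothed speed (the discrete acceleration zero crossing; a flat
stretch stops the walk, which realizes the |a| < 1 deg/s² plateau
tolerance). The single-phase variant stalls on pursuit plateaus, where
acceleration hovers around zero throughout. Walks are capped at the
neighboring event's boundary; strictly overlapping events merge, events
that merely touch at a shared valley sample stay distinct.

**Chen & Walton.** Raw speed is scanned with a 100 ms onset window: it
qualifies when at least ⌈0.72 · 9⌉ = 7 of its 9 samples (at 90 Hz) exceed
the threshold (default 6 deg/s) *and* no run of 3 consecutive
below-threshold samples fits inside the window; the onset is the first
above-threshold sample in the first qualifying window. The scan then
switches to a 22 ms (2-sample) offset window requiring both samples below
threshold; the offset is its first below-threshold sample, and the scan
alternates to the end of the series. The "fewer than three consecutive
below" rule is evaluated *within* the candidate window (the scope is
ambiguous in the source description; within-window is the reading that
makes the rule a property of the window being tested). An event still
open at the end of the series closes at the last sample. The streaming
implementation (cumulative-sum window counts) is checked exactly against
a naive window-by-window re-scan in the tests.

**DIZCO.** Horizontal (yaw-rate derivative, positive = rightward) and
vertical (negated pitch-rate derivative, positive = upward) angular
accelerations are low-passed at 10 Hz (zero phase). Segment boundaries
fall at zero crossings of either filtered series. Each segment gets a
per-axis state: 0 when the segment's mean |acceleration| on that axis is
below threshold, otherwise the sign of the segment mean; the state pair
maps to one of eight compass directions, or rest when both axes are 0.
The magnitude statistic (segment mean of |filtered acceleration|) and the
default threshold — the 95th percentile of rest-window |acceleration|,
falling back to the whole series without markers — are this package's
reproducible substitutes for a hand-tuned constant; both are
overridable. Note that a single bell-shaped movement yields two DIZCO
events (accelerating and decelerating phases have opposite acceleration
signs); DIZCO characterizes direction *changes*, not movement episodes.

**Decision tree.** scikit-learn's `DecisionTreeClassifier` (Gini
impurity, depth ≤ 10, fixed `random_state` for tie-breaking) on
per-sample features (smoothed speed, head angle), trained on rater
labels. Cross-validation uses contiguous time blocks, not shuffled
samples: adjacent samples are strongly autocorrelated and shuffled folds
would leak held-out information. Predicted label runs become events;
intervals shorter than half the mean rater-coded interval are discarded
(strict inequality at the cutoff).

All events use half-open [onset, offset) semantics on the uniform grid,
making touching events disjoint and label/event round trips exact; a
10⁻⁹ s tolerance absorbs float rounding of grid-aligned boundaries.

## Evaluation

Cohen's kappa is computed from the 2×2 moving/stationary contingency
table: K = (P_o − P_e)/(1 − P_e) with P_e from marginal products. When
P_e = 1 (both labelings constant and identical) kappa is reported as NaN
rather than forced to a value. Scoring respects an optional per-sample
mask (e.g. within-trial samples only); masked kappa equals kappa on the
extracted sub-series.

Ground truth for event-level comparison is the per-sample OR of all
raters; maximal runs form ground-truth events. A ground-truth event
matches the predicted event whose half-open window contains its midpoint
(computed in continuous time, not snapped to the grid); predictions
containing two or more ground-truth midpoints are removed with all their
candidate pairs, leaving only one-to-one pairs. Biases are
truth-minus-prediction means over pairs with across-pair standard
errors; duration bias equals offset bias minus onset bias by
construction. Because raters mark times only, amplitude for human-rated
events is derived from the kinematic trace between the rated times (net
angular displacement between the onset and offset orientations — a
movement returning to its start has amplitude ≈ 0 even though its path
length is positive).

The main sequence is the Pearson correlation between event amplitude and
peak velocity (scipy's two-sided p-value); it is undefined, and flagged,
under zero variance or fewer than 3 annotated events.

## Threshold fitting

For each candidate threshold the classifier runs on every subject; kappa
against each rater is averaged within subject, then across subjects.
Leave-one-out holds each subject out in turn, selects the argmax
threshold on the rest — ties break toward the smallest threshold,
favoring sensitivity — and scores it on the held-out subject. The
procedure is deterministic given data and grid. Default grids: BMAT
n ∈ {0.2, 0.3, …, 4.0}; SVT 2–40 deg/s in 0.5 steps and Chen & Walton
1–15 deg/s in 0.25 steps (speed grids chosen to bracket the plausible
range for head movements at this sampling rate). A classifier failure on
one (subject, threshold) cell becomes NaN with a warning and is excluded
from averages.

## Simulator

Each trial: 500 ms stationary fixation, one orienting movement toward a
target at a random eccentricity (10–50°) and direction (8 compass
points), an optional small corrective movement (off by default;
probability and 2–5° amplitude configurable), a hold, and a return to
center. The head covers 60% of target eccentricity (head gain < 1:
seated observers under-rotate the head relative to gaze; the value is a
modeling choice, not an estimate from data). Instant-condition movements
follow a raised-cosine speed profile — smooth, with analytic onset,
offset and peak — whose peak velocity is `slope × amplitude` (slope
default 6 (deg/s)/deg) times lognormal scatter (σ = 0.1, truncated at
±3σ so movements always fit the trial window); duration follows as
2·amplitude/peak. Pursuit movements rotate at the 20 deg/s target speed
with 100 ms cosine ramps. Orientation noise is per-axis Gaussian jitter
low-passed at 5 Hz and scaled to 0.02° SD — smooth, like tracker noise
plus postural sway, not white noise. Trial duration defaults to the
smallest window that fits the slowest admissible movement sequence.

Simulated raters perturb every ground-truth boundary with Gaussian
jitter (20 ms SD), apply optional deterministic onset/offset shifts,
miss each event with probability 0.05, and can ignore events whose peak
velocity falls below a configurable floor — the mechanism used to give a
cohort a known "effective threshold" that fitting should recover. All
randomness flows from one seed through per-trial and per-rater
substreams, so equal seeds give bit-identical output.

What the simulator does *not* emulate: eye or torso movement, vestibular
coupling, drift or overshoot in ballistic movements, head tremor
spectra, asymmetric or direction-dependent kinematics, and rater biases
beyond boundary jitter/shift/miss. Passing recovery tests therefore
demonstrates internal consistency of the classifier–evaluation–fitting
stack under controlled kinematics, not performance on human recordings.

## Validation conditions and problem sizes

The test suite and `scripts/acceptance.py` use deliberately chosen
conditions:

- **Clean-recovery checks** run noise-free with slower, larger movements
  (slope 3 (deg/s)/deg, eccentricities 30–50°) so that each movement
  spans ~60 samples: boundary smear from smoothing/filtering is a fixed
  2–3 samples per edge, so event length — not algorithm correctness —
  decides how close sample-wise kappa can get to 1. Thresholds are set
  for noise-free data (SVT 10 deg/s with a 55 ms window, Chen & Walton
  0.5 deg/s, BMAT n = 4, DIZCO 30 deg/s²). BMAT's check uses 0.005°
  jitter rather than none, since a zero-variance baseline is rejected by
  construction.
- **Threshold recovery** uses 6 subjects × 24 trials of small movements
  (slope 2, eccentricities 4–16°, peak-velocity scatter σ = 0.25) whose
  peak velocities straddle the raters' 10 deg/s floor; leave-one-out on
  the default SVT grid recovers 10.0 exactly.
- **Statistical checks** use closed-form calibration: for peak velocity
  v = 2A + ε, population r = 0.8 requires σ_ε = 1.5·σ_A; the
  independence null uses 10⁵ samples.

These sizes keep the full suite under a few seconds while leaving each
estimate's sampling error well inside the asserted bounds.

## Known limitations

- Euler-rate per-axis velocity is convention-dependent near gimbal lock;
  the mask flags but does not repair those samples.
- DIZCO's event semantics (direction changes) differ from the other
  classifiers' (movement episodes); comparing them at the event level
  conflates the two notions, which is why comparisons here are
  per-sample.
- The Chen & Walton 22 ms offset window at 90 Hz is 2 samples, so any
  2-sample dip below threshold closes an event; at other sampling rates
  the rule's behavior changes discretely with the rounded window sizes.
- `FitResult` standard errors are across-fold; with few subjects they
  understate uncertainty in the usual leave-one-out way.
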