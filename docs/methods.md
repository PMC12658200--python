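# Methods

## The screening problem

`gaitwatch` screens lateral-view gait recordings for abnormal movement
patterns without any labelled pathological data. The input is a markerless
pose-landmark stream (nine 2D body points per frame: nose, shoulders, hips,
knees, ankles, each with a visibility score); the output is a per-joint and
per-subject anomaly decision. The intended use is orthopedic/neurological
pre-screening, where conditions such as sarcopenia (muscle loss → weakened,
reduced-range gait) and Parkinson's disease (rigidity, slowed and asymmetric
gait) deviate from normal gait in joint-angle dynamics.

## Joint-angle extraction

Five sagittal-plane angle series are computed per subject, in degrees:

* **knee** (each side): interior angle at the knee between the rays
  knee→hip and knee→ankle; 180° is a straight leg.
* **hip** (each side): interior angle at the hip between hip→same-side
  shoulder and hip→same-side knee, i.e. the trunk–thigh angle. The third
  point of the hip construction is a convention of this package (the
  skeleton offers several); it is fixed and documented rather than
  configurable because every downstream statistic only needs a consistent,
  smooth, gait-modulated signal.
* **nose–shoulder**: the angle between the shoulder-midpoint→nose ray and
  the upward image vertical, capturing head/neck pitch (forward flexion is
  common in parkinsonian gait). Because it is vertical-referenced it is not
  rotation invariant, unlike the three-point angles; an alternative
  trunk-referenced construction would confound head pitch with trunk lean.

Angles are computed with `atan2(|cross|, dot)`, which is stable near 0° and
180°, and are unsigned: in monocular lateral video there is no reliable
anterior direction, so flexion/extension sign is not recoverable and is not
claimed.

## Quality control

Markerless pose estimation fails in stereotyped ways; QC runs before any
modelling.

* **Frame filtering.** A frame is dropped when any required landmark has
  visibility < 0.5, or when the inter-shoulder horizontal separation
  exceeds 0.35 × torso length — in a true lateral view the shoulders
  project nearly coincident, so a large ratio indicates the subject has
  turned. Both thresholds are config parameters; the defaults are
  deliberately permissive so QC removes gross failures, not borderline
  frames. Every drop is accounted for (retained + dropped = input).
* **Gap handling.** Gaps of ≤ 5 frames (1/6 s at 30 fps) left by dropped
  frames are filled by per-landmark linear interpolation (an inserted
  frame's visibility is the minimum of its endpoints); longer gaps split
  the stream into separate contiguous segments, and windows never straddle
  a split.
* **Triage.** A stream retaining at least 2 × window length (60) frames
  after stage 1 is class 1. Otherwise, a caller-supplied
  background-segmentation backend may be applied and filtering retried
  (class 2 on success); streams that still fail, or whose backend raises,
  are class 3 and excluded — screening reports them as *undetermined*, not
  as a guessed decision. The segmentation algorithm itself is out of scope;
  only the hook is provided.
* **Framing margins.** Per-frame subject bounding boxes (external detector
  output, or the tight box of visible landmarks) are classified against
  per-side margins as a fraction of the frame dimension: *ideal* at ≥ 20%
  top/bottom and ≥ 31% left/right; *acceptable* down to 5% and 12%;
  *insufficient* below. The recommended percentages are interpreted
  per side (the minimum over the two sides of an axis), the stricter of the
  two possible readings. Boxes spilling outside the frame clip to margin 0.

## The anomaly model

One univariate sequence autoencoder per joint, trained on normal gait only.

* **Windowing.** Angle series are cut into windows of L = 30 frames
  (1 s at 30 fps) with stride S = 15. One-second windows cover roughly one
  gait cycle at normal cadence, which is the natural unit of repetition;
  the half-window stride doubles the training set without making adjacent
  windows near-duplicates. Both are config parameters.
* **Normalisation.** Windows are z-scored with the mean and standard
  deviation of the *pooled training* values for that joint; screening
  always reuses the frozen training statistics (no leakage). A near-zero
  standard deviation is guarded to 1 so constant series normalise to zeros.
* **Architecture.** Encoder of two LSTM layers, a dense 16-dimensional
  bottleneck taken from the final encoder state, the latent vector repeated
  across all timesteps as decoder input, a mirrored two-layer LSTM decoder,
  and a per-timestep linear head back to one channel. The right knee uses
  64–32 encoder units (32–64 decoder); all other joints 32–16 (16–32).
  Inverted dropout at rate 0.2 after the first encoder and first decoder
  layer, training only.
* **Training.** Adam at learning rate 1e-4, mean squared error, fixed
  epochs per joint (right hip 200/batch 16, left hip 150/32, right knee
  150/32, left knee 200/64, nose–shoulder 150/64), no early stopping or
  validation split. The recurrent core is implemented in numpy with full
  backpropagation through time; all randomness (initialisation, shuffling,
  dropout) flows from one seeded generator, so training is bit-reproducible.
* **Scoring.** The anomaly score of a window is its mean squared
  reconstruction error in normalised units.

## Thresholds and decisions

Thresholds are calibrated on the training (normal) reconstruction errors as
**mean plus two sample standard deviations** (μ + 2σ, ddof = 1), the
classical two-sigma outlier rule; with σ = 0 the threshold degenerates to
the mean. Flagging is strict (`error > θ`); errors exactly at the threshold
do not flag.

Two calibration levels are kept per joint:

* a **window-level** threshold over all training windows, which drives the
  per-window outlier flags and the per-frame error curve (each frame takes
  the mean error of the windows covering it) used for plotting;
* a **sequence-level** threshold over the training subjects' per-recording
  mean errors, which drives the default joint decision: a joint fires when
  the screened subject's mean window error exceeds it.

The sequence-level default is a deliberate design choice. A 20 s recording
yields ~39 windows per joint, ~195 window tests per subject across five
joints; flagging a subject on *any* single window exceedance turns the
2-sigma tail into a near-certain false alarm at the subject level.
Aggregating to the recording's mean error before thresholding keeps the
two-sigma calibration meaningful at the level where decisions are made
(the gait sequence), while the window-level trace preserves localisation
for inspection. Window-level decisions (any `k_min` flagged windows) remain
available via `decision_level="window"`.

A subject is **abnormal if any of the five joints fires** (logical OR).
This rule maximises sensitivity at the cost of joint-level precision, which
is the appropriate trade for a screening tool; the per-joint counts and the
conditional co-detection matrix `M[i, j] = P(abnormal at i | abnormal at j)`
expose which joints drive the decisions. The conditioning direction is on
the column joint; with `M` computed by definition, the diagonal is 1
exactly on non-empty columns and empty columns are all zero.

## Group statistics

* **Trajectory comparison.** Subjects' angle series are linearly resampled
  to a common 100 points, averaged within group, and the two group-mean
  trajectories compared with a two-sided paired t-test across positions.
  Pairing group-*mean* trajectories is one defensible reading of a paired
  design between unequal-sized groups; it is the implemented default, and
  the degenerate case (zero variance of differences with non-zero mean) is
  reported as such rather than given a fabricated p-value. Identical
  trajectories report t = 0, p = 1.
* **Effect size.** Unsigned Cohen's d with the pooled standard deviation,
  labelled by the conventional 0.2 / 0.5 / 0.8 bands.
* **False-alarm cross-validation.** Normal subjects are partitioned into k
  seeded folds (sizes differing by ≤ 1); the full pipeline is refit on k−1
  folds and held-out normals screened, so each subject is tested exactly
  once. The table reports per-joint per-fold counts, sums, and the average
  rate with the total number of held-out subject tests as denominator.
  No multiple-testing correction is applied across joints, and ROC analysis
  is deliberately out of scope (reconstruction-error screening with a fixed
  μ + 2σ threshold has no natural operating-point sweep in this design).

## The synthetic-data generator

No clinical recordings can ship with the package, so the generator is a
first-class, tested module that defines the study conditions for every
experiment here.

Each angle channel is a fundamental sinusoid at the stride cadence plus an
optional second harmonic and i.i.d. Gaussian frame noise:
`baseline + A·sin(2πft + φ) + h₂·A·sin(4πft + 2φ) + ε`. Left and right
limbs are π out of phase. Defaults: 30 fps, 20 s, cadence 0.9 Hz, hip
baseline 165° amplitude 8°, knee baseline 160° amplitude 12°, nose–shoulder
baseline 12° amplitude 3°, second-harmonic fraction 0.2, frame noise
0.5°, and 5% log-normal between-subject variability on amplitudes and
cadence — values chosen once as representative of slow-to-normal adult
lateral-view gait and of landmark-level angle jitter, and kept fixed.

Landmarks are produced *from* the angles by a sagittal link chain (pelvis →
torso → nose; pelvis → thigh → shank per side) in y-down normalised image
coordinates, with both hips (and both shoulders) projecting to the same
point, as in a pure lateral view; the pelvis translates across the frame at
constant speed. Because the geometry inverts the angle definitions exactly,
noise-free extraction reproduces the generator's ground truth to machine
precision — the round-trip oracle used throughout the tests.

Disease-style perturbations operate on the angle trajectories: per-channel
amplitude scaling about the channel mean (reduced range of motion), cadence
time-warping (slowed gait), random-phase sinusoidal tremor at a set RMS,
constant trunk-flexion offset on the nose–shoulder channel, and a
multiplicative left-side asymmetry factor. The identity perturbation is
bit-exact. These magnitudes are test-harness parameters, not validated
biomechanical disease models.

**What the generator does not emulate:** double-bump knee flexion curves,
stance/swing asymmetries within a cycle, ground contact, camera shake,
pose-estimator-correlated noise, or out-of-plane motion. Passing the
synthetic experiments therefore demonstrates that the pipeline detects
distributional deviations of the kind injected (range, cadence, tremor,
posture) under realistic noise — not clinical performance on real video.

## Problem sizes and numerical choices

The shipped experiments fit on 30 synthetic normal subjects (≈ 1,170
windows per joint), train 50 epochs per joint, and screen 20 held-out
normals plus 20 knee-stiffness subjects (knee amplitude halved); the
monotonicity study uses 10 subjects per amplitude level. These sizes give
stable rates while keeping a full run in minutes on one CPU core.

Tie-breaks and degenerate inputs: flagging is strictly greater-than;
z-scoring guards sd < 1e-8 to 1; a series shorter than one window yields an
empty window set and a false joint decision (with a warning), never an
exception; an all-dropped QC result returns an empty sequence and triage
class 3; paired tests with zero-variance differences are flagged degenerate.
Forget-gate biases initialise to 1 and weights use seeded Glorot-uniform
draws; gradient clipping is off.

## Known limitations

* The hip and nose–shoulder angle constructions are package conventions;
  other skeleton conventions yield systematically different absolute
  values (comparisons within one convention remain valid).
* Unsigned angles cannot distinguish flexion from extension.
* The false-alarm behaviour of the μ + 2σ rule depends on the error
  distribution's tail; the two-sigma Gaussian intuition (~2.5%) is only a
  rough guide for skewed reconstruction-error distributions.
* The automatic lateral-view heuristic is a proxy for manual review; it
  cannot detect all turned or occluded postures.
* Synthetic validation does not establish clinical sensitivity or
  specificity.
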