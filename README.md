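# gaitwatch

Markerless gait anomaly screening from 2D pose landmarks.

`gaitwatch` is for researchers and clinical engineers who have lateral-view
gait video processed by a markerless pose estimator (MediaPipe-style
landmark streams) and want an *unsupervised* screen for abnormal gait — no
disease labels, no wearables. It targets conditions that alter joint-angle
dynamics, such as sarcopenia (muscle loss → weakened, reduced-range gait)
and Parkinson's disease (rigidity, slowed gait, forward neck flexion).

## Method

From the nine landmarks (nose, shoulders, hips, knees, ankles) five
joint-angle series θ(t) are extracted per subject: right/left knee,
right/left hip, and the nose–shoulder (head pitch) angle. Each series is
cut into 1 s windows (L = 30 frames at 30 fps, stride 15), z-scored with
training statistics, and passed through a per-joint **LSTM autoencoder**
(two-layer encoder, 16-dimensional bottleneck, mirrored decoder; dropout
0.2; Adam, lr 1e-4) trained **only on normal gait**. The anomaly score of a
window is its reconstruction error

```
e_w = (1/L) Σ_t (x_t − x̂_t)²,
```

and the per-joint threshold is the classical two-sigma rule calibrated on
the normal training errors:

```
θ = μ + 2σ.
```

A joint fires when the screened recording's mean window error exceeds the
sequence-level μ + 2σ threshold (window-level flagging with a `k_min` rule
is also available); a **subject is abnormal if any of the five joints
fires**. Acquisition QC (visibility/lateral-view frame filtering, gap
interpolation, triage classes, framing-margin analysis), joint co-detection
matrices, paired-trajectory t-tests with Cohen's d, and a k-fold
false-alarm harness round out the pipeline. Because clinical video is
restricted, the package ships a tested synthetic gait generator with exact
forward-kinematics ground truth; see `docs/methods.md` for the model and
its assumptions.

## Worked example

Fit a reference model set on eight synthetic normal walkers, then screen a
subject whose knee range of motion is halved and a healthy control
(`examples/screen_stiff_knee.py`, ~1 minute on one CPU):

```python
from gaitwatch import (GaitSimConfig, PerturbationSpec, simulate_subject,
                       PipelineConfig, fit_reference, screen_subject)

cfg = GaitSimConfig(duration_s=8.0)
train = [simulate_subject(cfg, seed=100 + i, subject_id=f"n{i:02d}")[0]
         for i in range(8)]
ref = fit_reference(train, config=PipelineConfig(model_overrides={"epochs": 60}), seed=0)

stiff = PerturbationSpec(amplitude_scale={"right_knee": 0.5, "left_knee": 0.5})
probe, _ = simulate_subject(cfg, stiff, seed=777, subject_id="probe")
report = screen_subject(ref, probe)
```

Output:

```
probe -> subject_decision: True
  right_hip      error=0.1868 threshold=0.2711 -> normal
  left_hip       error=0.4280 threshold=0.6805 -> normal
  right_knee     error=0.2448 threshold=0.2332 -> ABNORMAL
  left_knee      error=0.1678 threshold=1.0374 -> normal
  nose_shoulder  error=0.9691 threshold=1.0131 -> normal
control -> subject_decision: False
  ...
  right_knee     error=0.1350 threshold=0.2332 -> normal
```

The stiff-knee subject reconstructs poorly under the right-knee model
(error 0.2448 above its μ + 2σ threshold 0.2332), so that joint fires and
the any-joint rule marks the subject abnormal; the healthy control stays
below every threshold. Errors are in z-scored units², so thresholds differ
per joint with the joint's variability.

More examples under `examples/`: angle extraction and QC, margin analysis,
group statistics, and the cross-validated false-alarm table. A thin CLI
mirrors the library (`gaitwatch simulate|convert|qc|margins|extract-angles|
fit|score|report|stats|cv`).

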