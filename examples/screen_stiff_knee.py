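"""Fit a reference model set on normal walkers and screen two subjects.

One probe has its knee range of motion halved (a stiffness-like pattern);
the other is a healthy control.  Takes about a minute on one CPU.
"""

from gaitwatch import (
    JOINTS,
    GaitSimConfig,
    PerturbationSpec,
    PipelineConfig,
    fit_reference,
    screen_subject,
    simulate_subject,
)

cfg = GaitSimConfig(duration_s=8.0)
train = [
    simulate_subject(cfg, seed=100 + i, subject_id=f"n{i:02d}")[0] for i in range(8)
]
ref = fit_reference(
    train, config=PipelineConfig(model_overrides={"epochs": 60}), seed=0
)

stiff = PerturbationSpec(amplitude_scale={"right_knee": 0.5, "left_knee": 0.5})
probe, _ = simulate_subject(cfg, stiff, seed=777, subject_id="probe")
control, _ = simulate_subject(cfg, seed=888, subject_id="control")

for subject in (probe, control):
    report = screen_subject(ref, subject)
    print(f"{report.subject_id} -> subject_decision: {report.subject_decision}")
    for j in JOINTS:
        t = report.traces[j]
        verdict = "ABNORMAL" if t.joint_decision else "normal"
        print(
            f"  {j:14s} error={t.sequence_error:.4f} "
            f"threshold={t.sequence_threshold:.4f} -> {verdict}"
        )

# A joint fires when the recording's mean reconstruction error exceeds the
# mu + 2 sigma threshold calibrated on normal training gait; the subject is
# abnormal if any of the five joints fires.  Errors are in z-scored units
# squared, so thresholds differ per joint with the joint's variability.
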