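"""Group-level comparison of joint-angle trajectories.

Normal walkers vs a pathological group with forward trunk flexion (a
postural offset on the nose-shoulder channel) plus reduced knee range of
motion.  Paired t-test between group-mean trajectories and the unsigned
Cohen's d effect size per joint.
"""

from gaitwatch import (
    JOINTS,
    GaitSimConfig,
    PerturbationSpec,
    extract_angles,
    group_trajectory_test,
    simulate_subject,
)

cfg = GaitSimConfig(duration_s=10.0)
patho = PerturbationSpec(
    trunk_flexion_deg=8.0,
    amplitude_scale={"right_knee": 0.6, "left_knee": 0.6},
)

normal, patient = {j: [] for j in JOINTS}, {j: [] for j in JOINTS}
for i in range(12):
    seq, _ = simulate_subject(cfg, seed=500 + i, subject_id=f"n{i}")
    for j, s in extract_angles(seq).items():
        normal[j].append(s)
for i in range(12):
    seq, _ = simulate_subject(cfg, patho, seed=600 + i, subject_id=f"p{i}")
    for j, s in extract_angles(seq).items():
        patient[j].append(s)

print(f"{'joint':14s} {'p-value':>10s} {'Cohen d':>8s}  effect")
for j in JOINTS:
    res = group_trajectory_test(normal[j], patient[j], n_points=100)
    p_txt = "degenerate" if res.degenerate else f"{res.p_value:10.5f}"
    print(f"{j:14s} {p_txt:>10s} {res.cohens_d:8.3f}  {res.effect_label}")

# The trunk-flexion offset shifts the whole nose-shoulder trajectory, so
# that joint shows a huge effect size and p << 0.05.  The knee stiffness,
# by contrast, halves the *range* around an unchanged mean: group-mean
# trajectories barely move, so this test stays near-null at the knees --
# range-of-motion deviations are the autoencoder screen's job, while the
# trajectory test targets systematic postural differences.
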