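"""Acquisition QC: frame filtering, gap splitting, and framing margins.

A clean synthetic stream is corrupted with occlusions and a simulated turn,
then pushed through the two-stage QC workflow.
"""

import numpy as np

from gaitwatch import GaitSimConfig, margin_report, run_qc, simulate_subject

seq, _ = simulate_subject(
    GaitSimConfig(),
    seed=3,
    subject_id="noisy",
    occlusion={"right_ankle": [(100, 108)], "left_knee": [(350, 352)]},
)
# simulate a turned (frontal) posture on a few frames: shoulders separate
ls = seq.landmark_names.index("left_shoulder")
rs = seq.landmark_names.index("right_shoulder")
seq.xy[200:205, ls, 0] += 0.08
seq.xy[200:205, rs, 0] -= 0.08

segments, report = run_qc(seq)
print(f"input frames          : {report.n_input_frames}")
print(f"dropped (visibility)  : {report.n_dropped_visibility}")
print(f"dropped (non-lateral) : {report.n_dropped_lateral}")
print(f"retained              : {report.n_retained}")
print(f"segments after gaps   : {report.n_segments_after_gap_split}")
print(f"triage class          : {report.triage_class}  (1 = usable)")

# Framing-margin analysis on the subject's bounding box: per-side margins
# >= 20% (top/bottom) and >= 31% (sides) are ideal; >= 5% / 12% acceptable.
rep = margin_report(seq=seq, frame_dims=(1.0, 1.0))
counts = {c: int(np.sum(rep.classification == c)) for c in ("ideal", "acceptable", "insufficient")}
print("margin classes        :", counts)
# The walker crosses most of the frame, so side margins shrink near the
# edges of the walk and those frames classify below "ideal".
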