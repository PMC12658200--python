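"""Frame filtering, gap handling, margin classification, triage workflow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitwatch.landmark_io import REQUIRED_LANDMARKS, LandmarkSequence
from gaitwatch.preprocess import (
    MarginThresholds,
    filter_frames,
    interpolate_gaps,
    margin_report,
    run_qc,
    segmentation_hook,
)
from gaitwatch.synth_gait import GaitSimConfig, simulate_subject


class TestFilterFrames:
    def test_clean_lateral_sequence_has_zero_drops(self, clean_subject):
        seq, _ = clean_subject
        kept, report = filter_frames(seq)
        assert report.n_dropped_visibility == 0
        assert report.n_dropped_lateral == 0
        assert len(kept) == len(seq)

    def test_low_visibility_frame_dropped_with_reason(self, clean_subject):
        seq, _ = clean_subject
        j = seq.landmark_names.index("right_knee")
        seq.visibility[5, j] = 0.0
        kept, report = filter_frames(seq)
        assert report.n_dropped_visibility == 1
        assert report.drop_reasons == {5: "visibility"}
        assert 5 not in kept.frame_index

    def test_frontal_frame_dropped_as_lateral(self, clean_subject):
        seq, _ = clean_subject
        ls = seq.landmark_names.index("left_shoulder")
        rs = seq.landmark_names.index("right_shoulder")
        lh = seq.landmark_names.index("left_hip")
        # construct a frontal frame: inter-shoulder separation 0.5 x torso
        torso = abs(seq.xy[7, ls, 1] - seq.xy[7, lh, 1])
        seq.xy[7, ls, 0] += 0.25 * torso
        seq.xy[7, rs, 0] -= 0.25 * torso
        kept, report = filter_frames(seq, lateral_tau=0.3)
        assert report.drop_reasons == {7: "lateral"}
        assert report.n_dropped_lateral == 1

    def test_all_dropped_returns_empty_not_raises(self, clean_subject):
        seq, _ = clean_subject
        seq.visibility[:] = 0.0
        kept, report = filter_frames(seq)
        assert len(kept) == 0
        assert report.n_retained == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(drop=st.lists(st.integers(0, 119), max_size=30))
    def test_frame_accounting_always_balances(self, drop):
        seq, _ = simulate_subject(
            GaitSimConfig(duration_s=4.0, noise_sd_deg=0.0, subject_sd=0.0), seed=6
        )
        for f in drop:
            seq.visibility[f, 0] = 0.0
        kept, report = filter_frames(seq)
        assert (
            report.n_dropped_visibility + report.n_dropped_lateral
            == report.n_input_frames - report.n_retained
        )
        assert report.n_retained == len(kept)


class TestInterpolateGaps:
    def _gapped(self, seq, remove):
        keep = ~np.isin(seq.frame_index, remove)
        return seq.take(keep)

    def test_single_frame_gap_linear_midpoint(self, clean_subject):
        seq, _ = clean_subject
        gapped = self._gapped(seq, [100])
        segments = interpolate_gaps(gapped, max_gap=5)
        assert len(segments) == 1
        seg = segments[0]
        i = np.flatnonzero(seg.frame_index == 100)[0]
        np.testing.assert_allclose(
            seg.xy[i], (seq.xy[99] + seq.xy[101]) / 2.0, atol=1e-12
        )

    def test_inserted_visibility_is_min_of_endpoints(self, clean_subject):
        seq, _ = clean_subject
        seq.visibility[99, 2] = 0.7
        seq.visibility[101, 2] = 0.9
        seg = interpolate_gaps(self._gapped(seq, [100]), max_gap=5)[0]
        i = np.flatnonzero(seg.frame_index == 100)[0]
        assert seg.visibility[i, 2] == pytest.approx(0.7)

    def test_long_gap_splits_into_partition(self, clean_subject):
        seq, _ = clean_subject
        gapped = self._gapped(seq, list(range(50, 60)))  # 10-frame gap > max_gap 5
        segments = interpolate_gaps(gapped, max_gap=5)
        assert len(segments) == 2
        all_frames = np.concatenate([s.frame_index for s in segments])
        np.testing.assert_array_equal(np.sort(all_frames), gapped.frame_index)

    def test_identical_neighbors_give_identical_fill(self):
        names = REQUIRED_LANDMARKS
        xy = np.tile(np.linspace(0.1, 0.9, 18).reshape(1, 9, 2), (2, 1, 1))
        seq = LandmarkSequence(
            "x", 30.0, names, np.array([0, 2]), xy, np.ones((2, 9))
        )
        seg = interpolate_gaps(seq, max_gap=5)[0]
        np.testing.assert_allclose(seg.xy[1], xy[0], atol=1e-15)


class TestMargins:
    def test_ideal_margins_classified_ideal(self):
        boxes = pd.DataFrame([{"frame": 0, "x": 310, "y": 200, "w": 380, "h": 600}])
        rep = margin_report(boxes=boxes, frame_dims=(1000, 1000))
        assert rep.classification[0] == "ideal"
        assert rep.margins.iloc[0]["left"] == pytest.approx(0.31)
        assert rep.margins.iloc[0]["top"] == pytest.approx(0.20)

    def test_maximum_allowable_boundary_is_acceptable(self):
        boxes = pd.DataFrame([{"frame": 0, "x": 120, "y": 50, "w": 760, "h": 900}])
        rep = margin_report(boxes=boxes, frame_dims=(1000, 1000))
        assert rep.classification[0] == "acceptable"

    def test_box_touching_edge_is_insufficient(self):
        boxes = pd.DataFrame([{"frame": 0, "x": 0, "y": 300, "w": 300, "h": 400}])
        rep = margin_report(boxes=boxes, frame_dims=(1000, 1000))
        assert rep.margins.iloc[0]["left"] == 0.0
        assert rep.classification[0] == "insufficient"

    def test_box_larger_than_frame_clipped_insufficient(self):
        boxes = pd.DataFrame([{"frame": 0, "x": -50, "y": -10, "w": 1200, "h": 1100}])
        rep = margin_report(boxes=boxes, frame_dims=(1000, 1000))
        assert (rep.margins.iloc[0] >= 0).all()
        assert rep.classification[0] == "insufficient"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        x=st.floats(0, 600), y=st.floats(0, 600),
        w=st.floats(10, 390), h=st.floats(10, 390),
    )
    def test_mirroring_swaps_sides_and_preserves_class(self, x, y, w, h):
        W = H = 1000.0
        a = margin_report(boxes=np.array([[x, y, w, h]]), frame_dims=(W, H))
        b = margin_report(boxes=np.array([[W - x - w, y, w, h]]), frame_dims=(W, H))
        assert a.margins.iloc[0]["left"] == pytest.approx(b.margins.iloc[0]["right"])
        assert a.classification[0] == b.classification[0]

    def test_enlarging_margins_never_degrades_class(self):
        order = {"insufficient": 0, "acceptable": 1, "ideal": 2}
        prev = -1
        # progressively shrink a centered box -> margins grow monotonically
        for frac in (0.98, 0.9, 0.75, 0.5, 0.3):
            w = h = 1000 * frac
            x = y = (1000 - w) / 2
            rep = margin_report(boxes=np.array([[x, y, w, h]]), frame_dims=(1000, 1000))
            assert order[rep.classification[0]] >= prev
            prev = order[rep.classification[0]]

    def test_landmark_bounding_box_route(self, clean_subject):
        seq, _ = clean_subject
        rep = margin_report(seq=seq, frame_dims=(1.0, 1.0))
        assert len(rep.classification) == len(seq)
        assert set(rep.summary) == {"ideal", "acceptable", "insufficient"}


class TestSegmentationWorkflow:
    def test_identity_backend_is_identity(self, clean_subject):
        seq, _ = clean_subject
        assert segmentation_hook(seq) is seq

    def test_class1_input_never_invokes_backend(self, clean_subject):
        seq, _ = clean_subject
        calls = []

        def backend(s):
            calls.append(s)
            return s

        segments, report = run_qc(seq, backend=backend)
        assert report.triage_class == 1
        assert calls == []

    def test_raising_backend_triages_class3(self, clean_subject):
        seq, _ = clean_subject
        seq.visibility[:] = 0.0  # force stage-1 failure

        def backend(s):
            raise RuntimeError("segmentation failed")

        segments, report = run_qc(seq, backend=backend)
        assert report.triage_class == 3
        assert segments == []

    def test_rescuing_backend_yields_class2(self, clean_subject):
        seq, _ = clean_subject
        broken = seq.take(np.arange(len(seq)))
        broken.visibility[:] = 0.0

        def backend(s):
            fixed = s.take(np.arange(len(s)))
            fixed.visibility[:] = 1.0
            return fixed

        segments, report = run_qc(broken, backend=backend)
        assert report.triage_class == 2
        assert segments

    def test_no_backend_and_too_few_frames_is_class3(self, clean_subject):
        seq, _ = clean_subject
        short = seq.take(np.arange(10))
        segments, report = run_qc(short, min_usable_frames=60)
        assert report.triage_class == 3
        assert segments == []
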