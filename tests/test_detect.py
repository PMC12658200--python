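"""Threshold calibration, flagging semantics, decisions and count metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitwatch.detect import (
    AnomalyTrace,
    ConfusionCounts,
    SubjectReport,
    calibrate_threshold,
    co_detection_matrix,
    confusion_metrics,
    flag_anomalies,
    subject_decision,
)
from gaitwatch.kinematics import JOINTS


class TestCalibrateThreshold:
    def test_equal_errors_degenerate_to_mean(self):
        assert calibrate_threshold([3.0, 3.0, 3.0]) == pytest.approx(3.0, abs=1e-15)

    def test_hand_computed_example(self):
        # mean 4, sample sd sqrt(50/4) = 3.535534 -> 4 + 2 x 3.535534
        assert calibrate_threshold([1, 2, 3, 4, 10]) == pytest.approx(
            11.0710678, abs=1e-6
        )

    def test_large_sample_converges_to_mean_plus_two(self):
        rng = np.random.default_rng(0)
        errs = rng.standard_normal(200_000) + 10.0  # shifted positive
        theta = calibrate_threshold(errs)
        assert theta == pytest.approx(errs.mean() + 2.0, abs=0.02)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        lam=st.floats(0.01, 100),
        c=st.floats(0, 50),
        seed=st.integers(0, 10_000),
    )
    def test_scale_and_shift_equivariance(self, lam, c, seed):
        errs = np.random.default_rng(seed).random(20) + 0.5
        theta = calibrate_threshold(errs)
        assert calibrate_threshold(lam * errs) == pytest.approx(
            lam * theta, rel=1e-9
        )
        assert calibrate_threshold(errs + c) == pytest.approx(theta + c, rel=1e-9)

    def test_fewer_than_two_errors_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([1.0])

    def test_negative_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([1.0, -0.1])
        with pytest.raises(ValueError):
            calibrate_threshold([1.0, np.nan])


class TestFlagAnomalies:
    def test_no_errors_above_threshold_no_decision(self):
        tr = flag_anomalies([0.1, 0.2, 0.3], threshold=0.5)
        assert not tr.flags.any()
        assert tr.joint_decision is False

    def test_single_exceedance_fires_with_kmin_1(self):
        tr = flag_anomalies([0.1, 0.6, 0.2], threshold=0.5, k_min=1)
        assert tr.joint_decision is True
        assert tr.flags.tolist() == [False, True, False]

    def test_errors_equal_to_threshold_do_not_flag(self):
        tr = flag_anomalies([0.5, 0.5, 0.5], threshold=0.5)
        assert not tr.flags.any()

    def test_kmin_requires_enough_flags(self):
        errs = [0.6, 0.6, 0.1]
        assert flag_anomalies(errs, 0.5, k_min=2).joint_decision is True
        assert flag_anomalies(errs, 0.5, k_min=3).joint_decision is False

    def test_empty_errors_decision_false(self):
        tr = flag_anomalies([], threshold=0.5)
        assert tr.joint_decision is False

    def test_frame_curve_is_mean_of_covering_windows(self):
        tr = flag_anomalies(
            [1.0, 3.0], threshold=10.0, window_starts=[0, 5], window_length=10
        )
        # frames 5..9 covered by both windows -> mean 2.0; 0..4 only first
        i5 = np.flatnonzero(tr.frame_index == 5)[0]
        assert tr.frame_errors[0] == pytest.approx(1.0)
        assert tr.frame_errors[i5] == pytest.approx(2.0)
        assert tr.frame_errors[-1] == pytest.approx(3.0)

    def test_raising_threshold_never_turns_decision_true(self):
        rng = np.random.default_rng(1)
        errs = rng.random(30)
        for theta in np.linspace(0, 1.2, 13):
            lo = flag_anomalies(errs, theta).joint_decision
            hi = flag_anomalies(errs, theta + 0.1).joint_decision
            assert lo or not hi


def _trace(joint, decision):
    return AnomalyTrace(
        joint=joint,
        errors=np.array([1.0]),
        threshold=0.5 if decision else 2.0,
        flags=np.array([decision]),
        joint_decision=decision,
    )


class TestSubjectDecision:
    @pytest.mark.parametrize("bits", list(itertools.product([False, True], repeat=5)))
    def test_or_rule_truth_table(self, bits):
        traces = {j: _trace(j, b) for j, b in zip(JOINTS, bits)}
        assert subject_decision(traces) is any(bits)

    def test_missing_joint_named_in_error(self):
        traces = {j: _trace(j, False) for j in JOINTS[:-1]}
        with pytest.raises(ValueError, match="nose_shoulder"):
            subject_decision(traces)


def _report(sid, abnormal_joints):
    traces = {j: _trace(j, j in abnormal_joints) for j in JOINTS}
    return SubjectReport(sid, traces, subject_decision(traces))


class TestCoDetection:
    def test_all_joints_abnormal_gives_all_ones(self):
        M, counts = co_detection_matrix([_report("a", set(JOINTS))])
        np.testing.assert_array_equal(M, np.ones((5, 5)))
        assert all(v == 1 for v in counts.values())

    def test_worked_two_subject_example(self):
        A = _report("A", {"right_knee"})
        B = _report("B", {"right_knee", "right_hip"})
        M, counts = co_detection_matrix([A, B])
        i_rk = JOINTS.index("right_knee")
        i_rh = JOINTS.index("right_hip")
        assert M[i_rk, i_rh] == pytest.approx(1.0)   # P(knee | hip)
        assert M[i_rh, i_rk] == pytest.approx(0.5)   # P(hip | knee)
        assert counts["right_knee"] == 2
        assert counts["right_hip"] == 1

    def test_empty_column_convention(self):
        M, counts = co_detection_matrix([_report("a", {"right_knee"})])
        j = JOINTS.index("left_hip")
        assert counts["left_hip"] == 0
        np.testing.assert_array_equal(M[:, j], 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**25 - 1), st.integers(1, 5))
    def test_matches_brute_force_enumeration(self, packed, n_subj):
        bits = [(packed >> (5 * s + j)) & 1 for s in range(n_subj) for j in range(5)]
        dec = np.array(bits, dtype=bool).reshape(n_subj, 5)
        reports = [
            _report(f"s{i}", {j for k, j in enumerate(JOINTS) if dec[i, k]})
            for i in range(n_subj)
        ]
        M, counts = co_detection_matrix(reports)
        for i in range(5):
            for j in range(5):
                denom = dec[:, j].sum()
                expect = (dec[:, i] & dec[:, j]).sum() / denom if denom else 0.0
                assert M[i, j] == pytest.approx(expect)
                assert 0.0 <= M[i, j] <= 1.0


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp, fn, fp, tn, acc, prec, rec, f1",
        [
            (3, 0, 93, 20, 19.83, 3.13, 100.00, 6.06),
            (3, 0, 81, 32, 30.17, 3.57, 100.00, 6.90),
            (2, 1, 36, 77, 68.10, 5.26, 66.67, 9.76),
            (3, 0, 40, 73, 65.52, 6.98, 100.00, 13.04),
            (1, 2, 84, 29, 25.86, 1.18, 33.33, 2.27),
        ],
    )
    def test_joint_level_worked_examples(self, tp, fn, fp, tn, acc, prec, rec, f1):
        # agreement to the printed 2-decimal precision (tables round half up)
        m = confusion_metrics(ConfusionCounts(tp, fn, fp, tn))
        assert m["accuracy"] == pytest.approx(acc, abs=0.005 + 1e-12)
        assert m["precision"] == pytest.approx(prec, abs=0.005 + 1e-12)
        assert m["recall"] == pytest.approx(rec, abs=0.005 + 1e-12)
        assert m["f1"] == pytest.approx(f1, abs=0.005 + 1e-12)

    def test_zero_division_conventions(self):
        m = confusion_metrics(ConfusionCounts(0, 0, 0, 10))
        assert m == {"accuracy": 100.0, "precision": 0.0, "recall": 0.0, "f1": 0.0}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))
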