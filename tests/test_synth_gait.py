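"""Generator invariants: determinism, spectra, perturbations, kinematic round trip."""

import numpy as np
import pytest

from gaitwatch.kinematics import JOINTS, extract_angles, joint_angle, nose_shoulder_angle
from gaitwatch.synth_gait import (
    CHANNELS,
    GaitSimConfig,
    PerturbationSpec,
    apply_perturbation,
    forward_kinematics,
    generate_angle_trajectories,
    simulate_subject,
)


class TestAngleTrajectories:
    def test_zero_amplitude_zero_noise_is_constant_baseline(self):
        cfg = GaitSimConfig(
            amplitude_deg={c: 0.0 for c in CHANNELS},
            noise_sd_deg=0.0,
            subject_sd=0.0,
        )
        trajs = generate_angle_trajectories(cfg, 100)
        for c in CHANNELS:
            assert np.allclose(trajs[c], cfg.baseline_deg[c])

    def test_dominant_fourier_peak_at_cadence_period(self):
        # cadence 1 Hz at 30 fps -> period 30 frames -> bin n/30 of the DFT
        cfg = GaitSimConfig(
            cadence_hz=1.0, fps=30.0, noise_sd_deg=0.0, subject_sd=0.0,
            harmonic2_frac=0.0,
        )
        n = 600
        trajs = generate_angle_trajectories(cfg, n)
        for c in CHANNELS:
            spectrum = np.abs(np.fft.rfft(trajs[c] - trajs[c].mean()))
            assert np.argmax(spectrum) == n // 30

    def test_same_seed_bit_identical(self, default_config):
        a = generate_angle_trajectories(default_config, 200, seed=5)
        b = generate_angle_trajectories(default_config, 200, seed=5)
        for c in CHANNELS:
            np.testing.assert_array_equal(a[c], b[c])

    def test_nonpositive_frame_count_rejected(self, default_config):
        with pytest.raises(ValueError):
            generate_angle_trajectories(default_config, 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GaitSimConfig(fps=0)
        with pytest.raises(ValueError):
            GaitSimConfig(noise_sd_deg=float("nan"))


class TestPerturbation:
    def test_identity_spec_is_exact_identity(self, default_config):
        trajs = generate_angle_trajectories(default_config, 300, seed=3)
        out = apply_perturbation(trajs, PerturbationSpec(), seed=9)
        for c in CHANNELS:
            np.testing.assert_array_equal(out[c], trajs[c])

    def test_amplitude_scale_scales_peak_to_peak(self, clean_config):
        trajs = generate_angle_trajectories(clean_config, 300)
        spec = PerturbationSpec(amplitude_scale={"right_knee": 0.6})
        out = apply_perturbation(trajs, spec, seed=0)
        before = np.ptp(trajs["right_knee"])
        after = np.ptp(out["right_knee"])
        assert after == pytest.approx(0.6 * before, abs=1e-9)
        # other channels untouched
        np.testing.assert_array_equal(out["left_knee"], trajs["left_knee"])

    def test_trunk_flexion_shifts_nose_shoulder_mean_exactly(self, clean_config):
        trajs = generate_angle_trajectories(clean_config, 300)
        out = apply_perturbation(
            trajs, PerturbationSpec(trunk_flexion_deg=15.0), seed=0
        )
        shift = out["nose_shoulder"].mean() - trajs["nose_shoulder"].mean()
        assert shift == pytest.approx(15.0, abs=1e-12)
        np.testing.assert_array_equal(out["right_hip"], trajs["right_hip"])

    def test_unknown_channel_rejected(self, clean_config):
        trajs = generate_angle_trajectories(clean_config, 50)
        with pytest.raises(ValueError, match="unknown channel"):
            apply_perturbation(
                trajs, PerturbationSpec(amplitude_scale={"elbow": 0.5}), seed=0
            )

    @pytest.mark.parametrize("field", ["amplitude", "tremor"])
    def test_pathology_deviation_is_monotone(self, clean_config, field):
        """Stronger perturbations deviate more from the unperturbed channel."""
        trajs = generate_angle_trajectories(clean_config, 300)
        deviations = []
        levels = [1.0, 0.8, 0.5, 0.2] if field == "amplitude" else [0.0, 0.5, 1.0, 2.0]
        for lv in levels:
            if field == "amplitude":
                spec = PerturbationSpec(amplitude_scale={"right_knee": lv})
            else:
                spec = PerturbationSpec(tremor_sd_deg=lv)
            out = apply_perturbation(trajs, spec, seed=4)
            deviations.append(np.abs(out["right_knee"] - trajs["right_knee"]).mean())
        assert all(b >= a for a, b in zip(deviations, deviations[1:]))


class TestForwardKinematics:
    ANGLES = {
        "right_hip": 160.0, "left_hip": 172.0,
        "right_knee": 150.0, "left_knee": 178.0,
        "nose_shoulder": 20.0,
    }

    def test_pelvis_translation_translates_all_landmarks(self, default_config):
        f0 = forward_kinematics(self.ANGLES, default_config, (0.3, 0.5))
        f1 = forward_kinematics(self.ANGLES, default_config, (0.4, 0.6))
        for name, (x0, y0, _) in f0.landmarks.items():
            x1, y1, _ = f1.landmarks[name]
            assert x1 - x0 == pytest.approx(0.1, abs=1e-12)
            assert y1 - y0 == pytest.approx(0.1, abs=1e-12)

    def test_link_lengths_conserved(self, default_config):
        frame = forward_kinematics(self.ANGLES, default_config, (0.5, 0.5))
        seg = default_config.segment_lengths
        for side in ("right", "left"):
            hip = np.array(frame.landmarks[f"{side}_hip"][:2])
            knee = np.array(frame.landmarks[f"{side}_knee"][:2])
            ankle = np.array(frame.landmarks[f"{side}_ankle"][:2])
            assert np.linalg.norm(knee - hip) == pytest.approx(seg["thigh"], abs=1e-12)
            assert np.linalg.norm(ankle - knee) == pytest.approx(seg["shank"], abs=1e-12)

    def test_round_trip_random_frames(self, default_config):
        rng = np.random.default_rng(17)
        for _ in range(100):
            angles = {
                "right_hip": rng.uniform(100, 179),
                "left_hip": rng.uniform(100, 179),
                "right_knee": rng.uniform(90, 179),
                "left_knee": rng.uniform(90, 179),
                "nose_shoulder": rng.uniform(1, 90),
            }
            frame = forward_kinematics(angles, default_config, (0.5, 0.5))
            lm = {k: np.array(v[:2]) for k, v in frame.landmarks.items()}
            for side in ("right", "left"):
                knee = joint_angle(lm[f"{side}_hip"], lm[f"{side}_knee"], lm[f"{side}_ankle"])
                hip = joint_angle(lm[f"{side}_shoulder"], lm[f"{side}_hip"], lm[f"{side}_knee"])
                assert knee == pytest.approx(angles[f"{side}_knee"], abs=1e-6)
                assert hip == pytest.approx(angles[f"{side}_hip"], abs=1e-6)
            ns = nose_shoulder_angle(lm["nose"], lm["left_shoulder"], lm["right_shoulder"])
            assert ns == pytest.approx(angles["nose_shoulder"], abs=1e-6)

    def test_zero_length_segment_rejected(self, default_config):
        cfg = GaitSimConfig(segment_lengths={"thigh": 0.1, "shank": 0.1, "torso": 0.1, "neck": 0.1})
        cfg.segment_lengths["thigh"] = 0.0
        with pytest.raises(ValueError, match="segment"):
            forward_kinematics(self.ANGLES, cfg, (0.5, 0.5))


class TestSimulateSubject:
    def test_frame_count_matches_config(self, default_config):
        seq, truth = simulate_subject(default_config, seed=1)
        assert len(seq) == 600  # 30 fps x 20 s
        assert all(len(truth[j]) == 600 for j in JOINTS)

    def test_round_trip_through_extraction(self, clean_subject):
        seq, truth = clean_subject
        angles = extract_angles(seq)
        for j in JOINTS:
            np.testing.assert_allclose(angles[j].values, truth[j].values, atol=1e-6)

    def test_determinism(self, default_config):
        s1, t1 = simulate_subject(default_config, seed=9)
        s2, t2 = simulate_subject(default_config, seed=9)
        np.testing.assert_array_equal(s1.xy, s2.xy)
        for j in JOINTS:
            np.testing.assert_array_equal(t1[j].values, t2[j].values)

    def test_occlusion_schedule_sets_visibility(self, short_clean_config):
        seq, _ = simulate_subject(
            short_clean_config, seed=2,
            occlusion={"right_ankle": [(10, 20)]},
        )
        j = seq.landmark_names.index("right_ankle")
        assert np.all(seq.visibility[10:21, j] == 0.0)
        assert np.all(seq.visibility[:10, j] == 1.0)
        assert np.all(seq.visibility[21:, j] == 1.0)
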