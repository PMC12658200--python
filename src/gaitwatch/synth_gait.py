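"""Synthetic quasi-periodic gait landmark streams with known ground truth.

Clinical gait video cannot be redistributed, so every downstream stage is
exercised against a generative stand-in: five joint-angle channels (right/left
hip, right/left knee, nose–shoulder) are synthesised as a fundamental
sinusoid at the stride cadence plus an optional second harmonic and Gaussian
frame noise, optionally perturbed in disease-like ways (reduced range of
motion, slowed cadence, tremor, forward trunk flexion, left/right asymmetry),
and then rendered into nine 2D landmarks per frame by a sagittal-plane link
chain.  Because the landmarks are built *from* the angles, the extracted
angle series equal the generator's ground truth exactly in the noise-free
case — the round trip is the module's central invariant.

The default configuration emulates a lateral-view recording at 30 fps for
20 s with mild between-subject variability; the geometry uses normalised
image coordinates (origin top-left, y down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .kinematics import JOINTS, AngleSeries
from .landmark_io import REQUIRED_LANDMARKS, LandmarkFrame, LandmarkSequence

__all__ = [
    "CHANNELS",
    "GaitSimConfig",
    "PerturbationSpec",
    "generate_angle_trajectories",
    "apply_perturbation",
    "forward_kinematics",
    "simulate_subject",
]

#: Angle channels, in canonical joint order.
CHANNELS: tuple[str, ...] = JOINTS

_LEFT_CHANNELS = ("left_hip", "left_knee")


def _default_baselines() -> dict[str, float]:
    return {
        "right_hip": 165.0,
        "left_hip": 165.0,
        "right_knee": 160.0,
        "left_knee": 160.0,
        "nose_shoulder": 12.0,
    }


def _default_amplitudes() -> dict[str, float]:
    return {
        "right_hip": 8.0,
        "left_hip": 8.0,
        "right_knee": 12.0,
        "left_knee": 12.0,
        "nose_shoulder": 3.0,
    }


def _default_phases() -> dict[str, float]:
    # alternating gait: left limb half a cycle out of phase with the right
    return {
        "right_hip": 0.0,
        "left_hip": math.pi,
        "right_knee": 0.0,
        "left_knee": math.pi,
        "nose_shoulder": 0.0,
    }


def _default_segments() -> dict[str, float]:
    # normalised image units; a standing figure ~0.5 frame heights tall
    return {"thigh": 0.14, "shank": 0.14, "torso": 0.18, "neck": 0.08}


@dataclass
class GaitSimConfig:
    """Generative description of one synthetic gait recording."""

    fps: float = 30.0
    duration_s: float = 20.0
    cadence_hz: float = 0.9
    segment_lengths: dict[str, float] = field(default_factory=_default_segments)
    baseline_deg: dict[str, float] = field(default_factory=_default_baselines)
    amplitude_deg: dict[str, float] = field(default_factory=_default_amplitudes)
    phase_offset_rad: dict[str, float] = field(default_factory=_default_phases)
    harmonic2_frac: float = 0.2
    noise_sd_deg: float = 0.5
    subject_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("fps", self.fps), ("duration_s", self.duration_s),
            ("cadence_hz", self.cadence_hz),
        ):
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        for k, v in self.segment_lengths.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"segment length {k!r} must be finite and > 0")
        for c in CHANNELS:
            for d, label in (
                (self.baseline_deg, "baseline_deg"),
                (self.amplitude_deg, "amplitude_deg"),
                (self.phase_offset_rad, "phase_offset_rad"),
            ):
                if c not in d:
                    raise ValueError(f"{label} missing channel {c!r}")
                if not np.isfinite(d[c]):
                    raise ValueError(f"{label}[{c!r}] must be finite")
            if self.amplitude_deg[c] < 0:
                raise ValueError("amplitudes must be >= 0")
        for name, val in (
            ("harmonic2_frac", self.harmonic2_frac),
            ("noise_sd_deg", self.noise_sd_deg),
            ("subject_sd", self.subject_sd),
        ):
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class PerturbationSpec:
    """Disease-style deviations applied on top of a normal trajectory.

    The identity spec (all scales 1, all additive terms 0) leaves
    trajectories bit-identical.  Magnitudes are free parameters of the test
    harness, not validated biomechanical disease models.
    """

    amplitude_scale: dict[str, float] = field(default_factory=dict)
    cadence_scale: float = 1.0
    tremor_sd_deg: float = 0.0
    tremor_hz: float = 8.0
    trunk_flexion_deg: float = 0.0
    asymmetry_scale: float = 1.0

    def __post_init__(self) -> None:
        for c, s in self.amplitude_scale.items():
            if c not in CHANNELS:
                raise ValueError(f"unknown channel {c!r} in amplitude_scale")
            if not np.isfinite(s) or s <= 0:
                raise ValueError("amplitude_scale values must be finite and > 0")
        if not np.isfinite(self.cadence_scale) or self.cadence_scale <= 0:
            raise ValueError("cadence_scale must be finite and > 0")
        if not np.isfinite(self.asymmetry_scale) or self.asymmetry_scale <= 0:
            raise ValueError("asymmetry_scale must be finite and > 0")
        if self.tremor_sd_deg < 0 or self.tremor_hz <= 0:
            raise ValueError("tremor_sd_deg >= 0 and tremor_hz > 0 required")

    @property
    def is_identity(self) -> bool:
        return (
            all(s == 1.0 for s in self.amplitude_scale.values())
            and self.cadence_scale == 1.0
            and self.tremor_sd_deg == 0.0
            and self.trunk_flexion_deg == 0.0
            and self.asymmetry_scale == 1.0
        )


def generate_angle_trajectories(
    config: GaitSimConfig, n_frames: int, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Per-channel angle series (degrees) for one subject.

    Channel ``c`` at frame ``t`` is ``baseline_c + A_c·sin(2π·f·t/fps + φ_c)
    + harmonic2_frac·A_c·sin(4π·f·t/fps + 2φ_c) + ε_t`` with i.i.d. Gaussian
    ``ε``.  Between-subject variability (``subject_sd``) multiplies the
    amplitudes and the cadence by per-subject log-normal factors drawn before
    the noise, so the draw order is reproducible.  Deterministic given the
    seed (``config.seed`` unless overridden).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    amp_factor = {c: 1.0 for c in CHANNELS}
    cad_factor = 1.0
    if config.subject_sd > 0:
        z = rng.standard_normal(len(CHANNELS) + 1)
        amp_factor = {
            c: float(np.exp(config.subject_sd * z[i])) for i, c in enumerate(CHANNELS)
        }
        cad_factor = float(np.exp(config.subject_sd * z[-1]))
    t = np.arange(n_frames, dtype=np.float64)
    omega = 2.0 * math.pi * config.cadence_hz * cad_factor / config.fps
    out: dict[str, np.ndarray] = {}
    for c in CHANNELS:
        a = config.amplitude_deg[c] * amp_factor[c]
        phi = config.phase_offset_rad[c]
        y = (
            config.baseline_deg[c]
            + a * np.sin(omega * t + phi)
            + config.harmonic2_frac * a * np.sin(2.0 * omega * t + 2.0 * phi)
        )
        if config.noise_sd_deg > 0:
            y = y + rng.normal(0.0, config.noise_sd_deg, n_frames)
        out[c] = y
    return out


def apply_perturbation(
    trajectories: Mapping[str, np.ndarray],
    spec: PerturbationSpec,
    seed: int = 0,
    fps: float = 30.0,
) -> dict[str, np.ndarray]:
    """Apply disease-style deviations to angle trajectories.

    Order of operations: amplitude scaling (about each channel's mean,
    including the left-side asymmetry factor) → cadence time-warp (linear
    resampling of the phase axis; samples past the end clamp to the last
    value) → tremor (a random-phase sinusoid at ``tremor_hz`` with RMS
    ``tremor_sd_deg``) → constant trunk-flexion offset on the nose–shoulder
    channel.  The identity spec returns the input unchanged, bit for bit.
    """
    for c in spec.amplitude_scale:
        if c not in trajectories:
            raise ValueError(f"unknown channel {c!r} in amplitude_scale")
    out = {c: np.asarray(y, dtype=np.float64).copy() for c, y in trajectories.items()}
    if spec.is_identity:
        return out
    rng = np.random.default_rng(seed)
    for c, y in out.items():
        s = spec.amplitude_scale.get(c, 1.0)
        if c in _LEFT_CHANNELS:
            s *= spec.asymmetry_scale
        if s != 1.0:
            m = y.mean()
            y = m + s * (y - m)
        if spec.cadence_scale != 1.0:
            n = len(y)
            tq = np.arange(n) * spec.cadence_scale
            y = np.interp(tq, np.arange(n), y)
        out[c] = y
    if spec.tremor_sd_deg > 0:
        n = len(next(iter(out.values())))
        t = np.arange(n)
        for c in CHANNELS:
            if c not in out:
                continue
            phase = rng.uniform(0.0, 2.0 * math.pi)
            out[c] = out[c] + math.sqrt(2.0) * spec.tremor_sd_deg * np.sin(
                2.0 * math.pi * spec.tremor_hz * t / fps + phase
            )
    if spec.trunk_flexion_deg != 0.0 and "nose_shoulder" in out:
        out["nose_shoulder"] = out["nose_shoulder"] + spec.trunk_flexion_deg
    return out


def _fk_batch(
    angles: Mapping[str, np.ndarray],
    config: GaitSimConfig,
    pelvis_xy: np.ndarray,
) -> np.ndarray:
    """Vectorised link-chain kinematics.

    Returns landmark coordinates with shape ``(n, 9, 2)`` in the order of
    :data:`gaitwatch.landmark_io.REQUIRED_LANDMARKS`.  Both hips sit at the
    pelvis and both shoulders directly above it (a pure lateral projection),
    so extracting the five angles from the returned landmarks reproduces the
    inputs exactly.
    """
    seg = config.segment_lengths
    for k in ("thigh", "shank", "torso", "neck"):
        if k not in seg or seg[k] <= 0:
            raise ValueError(f"segment length {k!r} must be present and > 0")
    pelvis = np.atleast_2d(np.asarray(pelvis_xy, dtype=np.float64))
    n = pelvis.shape[0]
    for c in CHANNELS:
        if not np.all(np.isfinite(angles[c])):
            raise ValueError(f"non-finite angle in channel {c!r}")
    if not np.all(np.isfinite(pelvis)):
        raise ValueError("pelvis_position must be finite")

    shoulder = pelvis + seg["torso"] * np.array([0.0, -1.0])
    ns = np.radians(np.asarray(angles["nose_shoulder"], float))
    nose = shoulder + seg["neck"] * np.stack([np.sin(ns), -np.cos(ns)], axis=-1)

    coords = {
        "nose": nose,
        "left_shoulder": shoulder,
        "right_shoulder": shoulder,
        "left_hip": pelvis,
        "right_hip": pelvis,
    }
    for side, sx in (("right", 1.0), ("left", -1.0)):
        phi = np.radians(np.asarray(angles[f"{side}_hip"], float))
        # thigh direction makes the hip angle with the upward torso ray
        d = np.stack([sx * np.sin(phi), -np.cos(phi)], axis=-1)
        knee = pelvis + seg["thigh"] * d
        psi = np.radians(np.asarray(angles[f"{side}_knee"], float))
        beta = math.pi - psi  # knee flexion; rotate the thigh direction
        cb, sb = np.cos(beta), np.sin(beta) * (-sx)
        e = np.stack(
            [cb * d[:, 0] - sb * d[:, 1], sb * d[:, 0] + cb * d[:, 1]], axis=-1
        )
        ankle = knee + seg["shank"] * e
        coords[f"{side}_knee"] = knee
        coords[f"{side}_ankle"] = ankle

    out = np.empty((n, len(REQUIRED_LANDMARKS), 2))
    for j, name in enumerate(REQUIRED_LANDMARKS):
        out[:, j] = coords[name]
    return out


def forward_kinematics(
    angles: Mapping[str, float],
    config: GaitSimConfig,
    pelvis_position: Sequence[float],
) -> LandmarkFrame:
    """Place the nine landmarks for one frame from the five joint angles."""
    arr_angles = {c: np.atleast_1d(np.asarray(angles[c], float)) for c in CHANNELS}
    xy = _fk_batch(arr_angles, config, np.asarray(pelvis_position, float))[0]
    return LandmarkFrame(
        0,
        {
            name: (float(xy[j, 0]), float(xy[j, 1]), 1.0)
            for j, name in enumerate(REQUIRED_LANDMARKS)
        },
    )


def simulate_subject(
    config: GaitSimConfig,
    spec: PerturbationSpec | None = None,
    seed: int | None = None,
    subject_id: str = "sim",
    occlusion: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[LandmarkSequence, dict[str, AngleSeries]]:
    """Simulate one subject: landmark stream plus exact ground-truth angles.

    Composes :func:`generate_angle_trajectories` →
    :func:`apply_perturbation` → per-frame forward kinematics.  The pelvis
    translates at constant speed across the frame (which leaves all angles
    unchanged).  ``occlusion`` maps landmark names to inclusive
    ``(start, end)`` frame ranges whose visibility is set to 0.
    """
    if spec is None:
        spec = PerturbationSpec()
    base_seed = config.seed if seed is None else seed
    n = config.n_frames
    trajs = generate_angle_trajectories(config, n, seed=base_seed)
    trajs = apply_perturbation(trajs, spec, seed=base_seed + 1_000_003, fps=config.fps)

    t = np.arange(n, dtype=np.float64)
    px = 0.2 + 0.6 * t / max(n - 1, 1)
    py = np.full(n, 0.45)
    pelvis = np.stack([px, py], axis=-1)
    xy = _fk_batch(trajs, config, pelvis)

    vis = np.ones((n, len(REQUIRED_LANDMARKS)))
    if occlusion:
        for name, spans in occlusion.items():
            j = REQUIRED_LANDMARKS.index(name)
            for start, end in spans:
                vis[max(start, 0) : min(end, n - 1) + 1, j] = 0.0

    seq = LandmarkSequence(
        subject_id=subject_id,
        fps=config.fps,
        landmark_names=REQUIRED_LANDMARKS,
        frame_index=np.arange(n, dtype=np.int64),
        xy=xy,
        visibility=vis,
        units="normalized",
    )
    frames = np.arange(n, dtype=np.int64)
    truth = {
        c: AngleSeries(subject_id, c, config.fps, frames, trajs[c]) for c in CHANNELS
    }
    return seq, truth
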