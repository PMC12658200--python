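"""Joint-angle extraction from 2D pose landmarks.

Five sagittal-plane angle series drive the whole screening pipeline:

* ``right_knee`` / ``left_knee`` — interior angle at the knee between the rays
  knee→hip and knee→ankle (180° = straight leg);
* ``right_hip`` / ``left_hip`` — interior angle at the hip between the rays
  hip→same-side-shoulder and hip→same-side-knee (trunk–thigh angle);
* ``nose_shoulder`` — head/neck pitch: the angle between the ray from the
  shoulder midpoint to the nose and the upward image vertical (0° = nose
  directly above the shoulders).

Three-point angles are unsigned and invariant to translation, rotation and
uniform scaling of the landmark frame; the nose–shoulder angle is referenced
to the image vertical (so not rotation invariant — image coordinates are
y-down, and "up" is (0, −1)).  All angles are reported in degrees in
[0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkSequence

__all__ = [
    "JOINTS",
    "AngleSeries",
    "DegenerateGeometryError",
    "joint_angle",
    "nose_shoulder_angle",
    "extract_angles",
]

#: Canonical joint order used everywhere downstream.
JOINTS: tuple[str, ...] = (
    "right_hip",
    "left_hip",
    "right_knee",
    "left_knee",
    "nose_shoulder",
)


class DegenerateGeometryError(ValueError):
    """Coincident landmarks make an angle undefined."""


@dataclass
class AngleSeries:
    """One joint's angle trajectory in degrees over (possibly gapped) frames."""

    subject_id: str
    joint: str
    fps: float
    frame_index: np.ndarray
    values: np.ndarray  # degrees

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.frame_index.shape:
            raise ValueError("values and frame_index must have the same length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("angle values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def _angle_from_vectors(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle (degrees) between 2D vectors, atan2(|cross|, dot)."""
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    return np.degrees(np.arctan2(np.abs(cross), dot))


def joint_angle(a, vertex, c) -> float:
    """Interior angle at ``vertex`` between rays vertex→a and vertex→c.

    Uses the two-argument arctangent of |cross| / dot for numerical
    stability near 0° and 180°.  Returns degrees in [0, 180].
    """
    a = np.asarray(a, float)
    vertex = np.asarray(vertex, float)
    c = np.asarray(c, float)
    u = a - vertex
    v = c - vertex
    if np.allclose(u, 0) or np.allclose(v, 0):
        raise DegenerateGeometryError("zero-length ray at angle vertex")
    return float(_angle_from_vectors(u, v))


def nose_shoulder_angle(nose, l_shoulder, r_shoulder, reference=(0.0, -1.0)) -> float:
    """Head pitch: angle between shoulder-midpoint→nose and a reference ray.

    The default reference is the upward image vertical (image coordinates
    are y-down, so "up" is (0, −1)): 0° means the nose is directly above
    the shoulder midpoint, 90° level with it.  Passing the trunk direction
    (hip midpoint → shoulder midpoint) instead measures pitch relative to
    the trunk rather than the world.
    """
    nose = np.asarray(nose, float)
    mid = (np.asarray(l_shoulder, float) + np.asarray(r_shoulder, float)) / 2.0
    u = nose - mid
    ref = np.asarray(reference, float)
    if np.allclose(u, 0):
        raise DegenerateGeometryError("nose coincides with shoulder midpoint")
    if np.allclose(ref, 0):
        raise DegenerateGeometryError("zero-length reference direction")
    return float(_angle_from_vectors(u, ref))


# triplets: joint -> (ray-end A, vertex, ray-end C)
_TRIPLETS = {
    "right_knee": ("right_hip", "right_knee", "right_ankle"),
    "left_knee": ("left_hip", "left_knee", "left_ankle"),
    "right_hip": ("right_shoulder", "right_hip", "right_knee"),
    "left_hip": ("left_shoulder", "left_hip", "left_knee"),
}


def extract_angles(
    seq: LandmarkSequence, ns_reference: str = "vertical"
) -> dict[str, AngleSeries]:
    """Compute the five joint-angle series from a landmark sequence.

    ``ns_reference`` selects the nose–shoulder reference direction:
    ``"vertical"`` (image up, the default) or ``"trunk"`` (hip midpoint →
    shoulder midpoint).  Frames where a joint's geometry is degenerate
    (coincident landmarks) are dropped from that joint's series only.
    Raises ``KeyError`` if a required landmark is absent from the sequence.
    """
    if ns_reference not in ("vertical", "trunk"):
        raise ValueError("ns_reference must be 'vertical' or 'trunk'")
    idx = {name: seq.landmark_idx(name) for name in (
        "nose", "left_shoulder", "right_shoulder", "left_hip", "right_hip",
        "left_knee", "right_knee", "left_ankle", "right_ankle",
    )}
    out: dict[str, AngleSeries] = {}
    xy = seq.xy

    for joint, (a_n, v_n, c_n) in _TRIPLETS.items():
        u = xy[:, idx[a_n]] - xy[:, idx[v_n]]
        v = xy[:, idx[c_n]] - xy[:, idx[v_n]]
        ok = (np.einsum("ij,ij->i", u, u) > 0) & (np.einsum("ij,ij->i", v, v) > 0)
        vals = np.full(len(seq), np.nan)
        vals[ok] = _angle_from_vectors(u[ok], v[ok])
        out[joint] = AngleSeries(
            seq.subject_id, joint, seq.fps, seq.frame_index[ok], vals[ok]
        )

    mid = (xy[:, idx["left_shoulder"]] + xy[:, idx["right_shoulder"]]) / 2.0
    u = xy[:, idx["nose"]] - mid
    if ns_reference == "trunk":
        hip_mid = (xy[:, idx["left_hip"]] + xy[:, idx["right_hip"]]) / 2.0
        ref = mid - hip_mid
    else:
        ref = np.zeros_like(u)
        ref[:, 1] = -1.0
    ok = (np.einsum("ij,ij->i", u, u) > 0) & (np.einsum("ij,ij->i", ref, ref) > 0)
    vals = np.full(len(seq), np.nan)
    vals[ok] = _angle_from_vectors(u[ok], ref[ok])
    out["nose_shoulder"] = AngleSeries(
        seq.subject_id, "nose_shoulder", seq.fps, seq.frame_index[ok], vals[ok]
    )
    return {j: out[j] for j in JOINTS}
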