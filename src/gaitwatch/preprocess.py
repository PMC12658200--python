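"""Acquisition quality control for landmark streams.

Markerless pose output degrades in predictable ways — joints occluded or
misdetected (low visibility), the subject turning out of the lateral view,
and the subject drifting partially out of frame.  This module implements the
two-stage QC workflow used before any modelling:

1. **Frame filtering** drops frames with low-visibility required landmarks or
   non-lateral body orientation, with per-frame accounting.
2. **Gap handling** linearly interpolates short gaps left by dropped frames
   and splits the stream at longer ones, yielding contiguous segments.
3. An optional **background-segmentation hook** lets a caller-supplied
   backend rescue streams that fail stage 1 (triage class 2); streams that
   still fail are triaged to class 3 (excluded).
4. **Framing-margin analysis** classifies per-frame subject bounding boxes
   against recommended capture margins (per side, as a fraction of the frame
   dimension): ideal at >= 20% top/bottom and >= 31% left/right, acceptable
   down to 5% and 12%, insufficient below that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .landmark_io import REQUIRED_LANDMARKS, LandmarkSequence

__all__ = [
    "QCReport",
    "MarginReport",
    "MarginThresholds",
    "filter_frames",
    "interpolate_gaps",
    "margin_report",
    "segmentation_hook",
    "run_qc",
]


@dataclass
class QCReport:
    """Accounting for the frame-filtering stage of one sequence."""

    n_input_frames: int
    n_dropped_visibility: int
    n_dropped_lateral: int
    n_retained: int
    drop_reasons: dict[int, str]  # frame index -> "visibility" | "lateral"
    n_segments_after_gap_split: int | None = None
    triage_class: int | None = None  # 1 usable, 2 usable after masking, 3 excluded

    def __post_init__(self) -> None:
        if self.n_dropped_visibility + self.n_dropped_lateral != (
            self.n_input_frames - self.n_retained
        ):
            raise ValueError("QC drop counts do not account for every frame")


@dataclass(frozen=True)
class MarginThresholds:
    """Per-side framing margins as fractions of the frame dimension."""

    ideal_top_bottom: float = 0.20
    ideal_sides: float = 0.31
    max_allowable_top_bottom: float = 0.05
    max_allowable_sides: float = 0.12


@dataclass
class MarginReport:
    """Per-frame framing margins and their classification."""

    frame_index: np.ndarray
    margins: pd.DataFrame  # columns top, bottom, left, right
    classification: np.ndarray  # "ideal" | "acceptable" | "insufficient"
    thresholds: MarginThresholds
    summary: dict[str, float] = field(default_factory=dict)


def _torso_length(seq: LandmarkSequence) -> np.ndarray:
    mid_sh = (
        seq.xy[:, seq.landmark_idx("left_shoulder")]
        + seq.xy[:, seq.landmark_idx("right_shoulder")]
    ) / 2.0
    mid_hip = (
        seq.xy[:, seq.landmark_idx("left_hip")]
        + seq.xy[:, seq.landmark_idx("right_hip")]
    ) / 2.0
    return np.linalg.norm(mid_sh - mid_hip, axis=1)


def filter_frames(
    seq: LandmarkSequence,
    visibility_min: float = 0.5,
    lateral_tau: float = 0.35,
) -> tuple[LandmarkSequence, QCReport]:
    """Drop recognition-error frames, keeping a full per-frame account.

    A frame is dropped with reason ``"visibility"`` when any required
    landmark's visibility is below ``visibility_min``, otherwise with reason
    ``"lateral"`` when the inter-shoulder horizontal separation divided by
    torso length exceeds ``lateral_tau`` (in a lateral view the shoulders
    project nearly coincident, so a large ratio indicates a turned subject).
    An all-dropped sequence is returned empty, not raised.
    """
    if len(seq) == 0:
        raise ValueError("cannot QC an empty sequence")
    req = [seq.landmark_idx(n) for n in REQUIRED_LANDMARKS]
    vis_ok = np.all(seq.visibility[:, req] >= visibility_min, axis=1)

    sep = np.abs(
        seq.xy[:, seq.landmark_idx("left_shoulder"), 0]
        - seq.xy[:, seq.landmark_idx("right_shoulder"), 0]
    )
    torso = _torso_length(seq)
    ratio = np.divide(sep, torso, out=np.full_like(sep, np.inf), where=torso > 0)
    lateral_ok = ratio <= lateral_tau

    keep = vis_ok & lateral_ok
    reasons: dict[int, str] = {}
    for i in np.flatnonzero(~keep):
        reasons[int(seq.frame_index[i])] = "visibility" if not vis_ok[i] else "lateral"
    n_vis = int(np.sum(~vis_ok))
    n_lat = int(np.sum(vis_ok & ~lateral_ok))
    report = QCReport(
        n_input_frames=len(seq),
        n_dropped_visibility=n_vis,
        n_dropped_lateral=n_lat,
        n_retained=int(keep.sum()),
        drop_reasons=reasons,
    )
    return seq.take(keep), report


def interpolate_gaps(seq: LandmarkSequence, max_gap: int = 5) -> list[LandmarkSequence]:
    """Fill short frame gaps by linear interpolation; split at long ones.

    Gaps of at most ``max_gap`` missing frames are filled per landmark
    (visibility of an inserted frame is the minimum of its two endpoints);
    longer gaps split the sequence into separate contiguous segments.
    """
    if len(seq) == 0:
        return []
    fidx = seq.frame_index
    gaps = np.diff(fidx) - 1
    cut_after = np.flatnonzero(gaps > max_gap)
    bounds = np.concatenate([[0], cut_after + 1, [len(fidx)]])
    segments: list[LandmarkSequence] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        piece = seq.take(np.arange(b0, b1))
        segments.append(_fill_segment(piece))
    return segments


def _fill_segment(seq: LandmarkSequence) -> LandmarkSequence:
    fidx = seq.frame_index
    if len(fidx) == 0 or fidx[-1] - fidx[0] + 1 == len(fidx):
        return seq
    full = np.arange(fidx[0], fidx[-1] + 1, dtype=np.int64)
    n, k = len(full), len(seq.landmark_names)
    xy = np.empty((n, k, 2))
    vis = np.empty((n, k))
    for j in range(k):
        for d in range(2):
            xy[:, j, d] = np.interp(full, fidx, seq.xy[:, j, d])
    present = np.isin(full, fidx)
    pos = np.searchsorted(fidx, full[present])
    vis_known = seq.visibility
    # inserted frames take the min visibility of their bracketing endpoints
    left = np.searchsorted(fidx, full, side="right") - 1
    right = np.clip(left + 1, 0, len(fidx) - 1)
    vis = np.minimum(vis_known[np.clip(left, 0, None)], vis_known[right])
    vis[present] = vis_known[pos]
    return LandmarkSequence(
        seq.subject_id, seq.fps, seq.landmark_names, full, xy, vis,
        seq.units, seq.frame_width, seq.frame_height,
    )


def margin_report(
    boxes: pd.DataFrame | np.ndarray | None = None,
    seq: LandmarkSequence | None = None,
    frame_dims: tuple[float, float] = (1.0, 1.0),
    thresholds: MarginThresholds | None = None,
) -> MarginReport:
    """Classify per-frame framing margins as ideal / acceptable / insufficient.

    ``boxes`` is a table with columns ``frame, x, y, w, h`` (top-left corner
    plus size) in the units of ``frame_dims = (width, height)``.  If a
    landmark sequence is given instead, the box is the tight bounding box of
    all visible landmarks in each frame.  The margin on each side is the
    distance from the box edge to the frame edge divided by the frame
    dimension on that axis, clipped at 0 for boxes that spill outside.
    """
    if thresholds is None:
        thresholds = MarginThresholds()
    W, H = frame_dims
    if W <= 0 or H <= 0:
        raise ValueError("frame_dims must be positive")
    if boxes is None:
        if seq is None:
            raise ValueError("provide either boxes or a landmark sequence")
        frames, rects = _boxes_from_landmarks(seq)
    else:
        if isinstance(boxes, pd.DataFrame):
            frames = boxes["frame"].to_numpy(np.int64)
            rects = boxes[["x", "y", "w", "h"]].to_numpy(float)
        else:
            arr = np.atleast_2d(np.asarray(boxes, float))
            if arr.shape[1] == 5:
                frames = arr[:, 0].astype(np.int64)
                rects = arr[:, 1:]
            else:
                frames = np.arange(arr.shape[0], dtype=np.int64)
                rects = arr
    x, y, w, h = rects.T
    left = np.clip(x / W, 0.0, None)
    right = np.clip((W - x - w) / W, 0.0, None)
    top = np.clip(y / H, 0.0, None)
    bottom = np.clip((H - y - h) / H, 0.0, None)

    tb = np.minimum(top, bottom)
    lr = np.minimum(left, right)
    cls = np.full(len(x), "insufficient", dtype=object)
    cls[(tb >= thresholds.max_allowable_top_bottom) & (lr >= thresholds.max_allowable_sides)] = "acceptable"
    cls[(tb >= thresholds.ideal_top_bottom) & (lr >= thresholds.ideal_sides)] = "ideal"

    margins = pd.DataFrame(
        {"top": top, "bottom": bottom, "left": left, "right": right}, index=frames
    )
    n = max(len(cls), 1)
    summary = {
        label: float(np.sum(cls == label)) / n
        for label in ("ideal", "acceptable", "insufficient")
    }
    return MarginReport(frames, margins, np.asarray(cls), thresholds, summary)


def _boxes_from_landmarks(seq: LandmarkSequence) -> tuple[np.ndarray, np.ndarray]:
    rects = np.empty((len(seq), 4))
    for i in range(len(seq)):
        visible = seq.visibility[i] > 0
        pts = seq.xy[i, visible] if visible.any() else seq.xy[i]
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        rects[i] = (x0, y0, x1 - x0, y1 - y0)
    return seq.frame_index.copy(), rects


def segmentation_hook(
    seq: LandmarkSequence,
    backend: Callable[[LandmarkSequence], LandmarkSequence] | None = None,
) -> LandmarkSequence:
    """Apply a caller-supplied background-masking backend (identity default).

    The hook's output schema is identical to its input; the core never
    implements segmentation itself.  Exceptions from the backend propagate to
    the caller (:func:`run_qc` translates them into triage class 3).
    """
    if backend is None:
        return seq
    return backend(seq)


def run_qc(
    seq: LandmarkSequence,
    visibility_min: float = 0.5,
    lateral_tau: float = 0.35,
    max_gap: int = 5,
    min_usable_frames: int = 60,
    backend: Callable[[LandmarkSequence], LandmarkSequence] | None = None,
) -> tuple[list[LandmarkSequence], QCReport]:
    """Two-stage QC: frame filtering, optional masking rescue, gap split.

    Stage 1 filters frames; a sequence retaining at least
    ``min_usable_frames`` is triage class 1.  Otherwise, if a segmentation
    backend is supplied it is applied to the raw stream and filtering is
    retried: success yields class 2, failure (or a raising backend) class 3.
    The returned segments are contiguous after gap interpolation/splitting;
    class-3 results return no segments.
    """
    filtered, report = filter_frames(seq, visibility_min, lateral_tau)
    if report.n_retained >= min_usable_frames:
        report.triage_class = 1
    elif backend is not None:
        try:
            rescued = segmentation_hook(seq, backend)
            filtered, report = filter_frames(rescued, visibility_min, lateral_tau)
            report.triage_class = 2 if report.n_retained >= min_usable_frames else 3
        except Exception:
            report.triage_class = 3
            filtered = seq.take(np.zeros(len(seq), dtype=bool))
    else:
        report.triage_class = 3
    if report.triage_class == 3:
        report.n_segments_after_gap_split = 0
        return [], report
    segments = interpolate_gaps(filtered, max_gap=max_gap)
    report.n_segments_after_gap_split = len(segments)
    return segments, report
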