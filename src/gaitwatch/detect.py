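"""Anomaly decisions from reconstruction errors.

The anomaly threshold for a joint is the mean plus two sample standard
deviations (μ + 2σ) of the reconstruction errors observed on the normal
training set — the classical two-sigma outlier rule.  A window (or a whole
sequence) is flagged when its error strictly exceeds the threshold; a joint
fires when at least ``k_min`` of its windows are flagged; a subject is
abnormal when **any** of the five joints fires (the any-joint OR rule, which
trades precision for screening sensitivity).  Joint-level results aggregate
into per-joint counts, a conditional co-detection matrix, and the standard
confusion-count metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from .kinematics import JOINTS

__all__ = [
    "AnomalyTrace",
    "SubjectReport",
    "ConfusionCounts",
    "calibrate_threshold",
    "flag_anomalies",
    "subject_decision",
    "co_detection_matrix",
    "confusion_metrics",
]


def calibrate_threshold(training_errors) -> float:
    """μ + 2σ of training reconstruction errors (sample sd, ddof=1).

    All-equal errors have σ = 0 and the threshold degenerates to the mean.
    """
    errs = np.asarray(training_errors, dtype=np.float64)
    if errs.size < 2:
        raise ValueError("threshold calibration needs at least 2 errors")
    if not np.all(np.isfinite(errs)) or np.any(errs < 0):
        raise ValueError("reconstruction errors must be finite and non-negative")
    return float(errs.mean() + 2.0 * errs.std(ddof=1))


@dataclass
class AnomalyTrace:
    """Per-joint anomaly evidence for one subject."""

    joint: str
    errors: np.ndarray  # per-window reconstruction errors
    threshold: float  # threshold the flags were taken against
    flags: np.ndarray  # boolean, strict exceedance
    joint_decision: bool
    frame_index: np.ndarray | None = None  # frames covered by the error curve
    frame_errors: np.ndarray | None = None  # per-frame mean of covering windows
    sequence_error: float | None = None  # mean window error of the sequence
    sequence_threshold: float | None = None

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=np.float64)
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.errors.shape != self.flags.shape:
            raise ValueError("errors and flags must align")


def flag_anomalies(
    errors,
    threshold: float,
    k_min: int = 1,
    window_starts=None,
    window_length: int | None = None,
) -> AnomalyTrace:
    """Flag windows whose error strictly exceeds the threshold.

    ``joint_decision`` is true when at least ``k_min`` windows are flagged.
    If window provenance (``window_starts`` in frame units and
    ``window_length``) is given, a per-frame error curve is attached: each
    frame carries the mean error of all windows covering it, for plotting
    parity with per-frame outlier traces.  An empty error list yields a
    false decision rather than an exception.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    errs = np.asarray(errors, dtype=np.float64)
    flags = errs > threshold  # strict inequality: errors equal to θ pass
    if errs.size == 0:
        logger.warning("flag_anomalies called with no errors; joint decision is False")
    decision = bool(flags.sum() >= k_min) if errs.size else False

    frame_index = frame_errors = None
    if window_starts is not None and window_length is not None and errs.size:
        starts = np.asarray(window_starts, dtype=np.int64)
        lo, hi = starts.min(), (starts + window_length - 1).max()
        frame_index = np.arange(lo, hi + 1)
        total = np.zeros(len(frame_index))
        count = np.zeros(len(frame_index))
        for s, e in zip(starts, errs):
            sl = slice(s - lo, s - lo + window_length)
            total[sl] += e
            count[sl] += 1
        with np.errstate(invalid="ignore"):
            frame_errors = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return AnomalyTrace(
        joint="",
        errors=errs,
        threshold=float(threshold),
        flags=flags,
        joint_decision=decision,
        frame_index=frame_index,
        frame_errors=frame_errors,
    )


@dataclass
class SubjectReport:
    """All five joint traces plus the subject-level decision."""

    subject_id: str
    traces: dict[str, AnomalyTrace]
    subject_decision: bool | None  # None = undetermined (QC class 3)
    n_usable_frames: int = 0
    qc_class: int | None = None
    metadata: dict = field(default_factory=dict)

    def joint_decisions(self) -> dict[str, bool]:
        return {j: t.joint_decision for j, t in self.traces.items()}


def subject_decision(traces: dict[str, AnomalyTrace]) -> bool:
    """The any-joint OR rule over exactly the five canonical joints."""
    for j in JOINTS:
        if j not in traces:
            raise ValueError(f"missing trace for joint {j!r}")
    return any(traces[j].joint_decision for j in JOINTS)


def co_detection_matrix(
    reports: list[SubjectReport],
) -> tuple[np.ndarray, dict[str, int]]:
    """Joint anomaly counts and the conditional co-detection matrix.

    ``counts[j]`` is the number of subjects abnormal at joint ``j``;
    ``M[i, j] = P(abnormal at i | abnormal at j)`` — the fraction of
    subjects abnormal at both among those abnormal at ``j`` — with 0 where
    the conditioning count is empty (hence a unit diagonal exactly on
    non-empty columns).  Joint order follows :data:`gaitwatch.kinematics.JOINTS`.
    """
    if not reports:
        raise ValueError("need at least one subject report")
    k = len(JOINTS)
    dec = np.zeros((len(reports), k), dtype=bool)
    for r, rep in enumerate(reports):
        for j, joint in enumerate(JOINTS):
            if joint in rep.traces:
                dec[r, j] = rep.traces[joint].joint_decision
    counts = dec.sum(axis=0)
    both = dec.T.astype(np.int64) @ dec.astype(np.int64)  # both[i, j]
    M = np.zeros((k, k))
    nz = counts > 0
    M[:, nz] = both[:, nz] / counts[nz]
    return M, {joint: int(counts[j]) for j, joint in enumerate(JOINTS)}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts (positives = pathological gait)."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 in percent (unrounded).

    Zero-division conventions: precision is 0 when no positive calls were
    made, recall is 0 when there are no positive cases, F1 is 0 when
    precision and recall are both 0.
    """
    if c.total == 0:
        raise ValueError("confusion counts sum to zero")
    accuracy = 100.0 * (c.TP + c.TN) / c.total
    precision = 100.0 * c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    recall = 100.0 * c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
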