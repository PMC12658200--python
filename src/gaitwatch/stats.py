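"""Group-level statistics and the k-fold false-alarm harness.

Two kinds of evidence complement the per-subject anomaly decisions:

* **Trajectory comparison** — for each joint, subjects' angle series are
  linearly resampled onto a common length, averaged within group, and the
  two group-mean trajectories are compared position-by-position with a
  paired t-test; Cohen's d (pooled-sd, reported unsigned) quantifies the
  effect size with the conventional 0.2 / 0.5 / 0.8 bands.
* **False-alarm cross-validation** — normal subjects are partitioned into k
  folds; models are fit on k−1 folds and the held-out normals screened, so
  every subject is tested exactly once and per-joint false alarms can be
  tabulated per fold, summed, and averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinematics import JOINTS, AngleSeries

__all__ = [
    "GroupComparisonResult",
    "FalseAlarmTable",
    "resample_trajectory",
    "group_trajectory_test",
    "cohens_d",
    "effect_size_label",
    "kfold_false_alarm",
    "kfold_partition",
]


def resample_trajectory(series: AngleSeries | np.ndarray, n_points: int) -> np.ndarray:
    """Linearly interpolate a series onto ``n_points`` equally spaced positions."""
    vals = series.values if isinstance(series, AngleSeries) else np.asarray(series, float)
    if len(vals) < 2:
        raise ValueError("need at least 2 samples to resample")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    pos = np.linspace(0.0, len(vals) - 1.0, n_points)
    return np.interp(pos, np.arange(len(vals)), vals)


@dataclass
class GroupComparisonResult:
    """Paired-trajectory comparison of two groups at one joint."""

    joint: str
    t_statistic: float | None
    p_value: float | None
    cohens_d: float | None
    effect_label: str | None
    n_points: int
    n_a: int
    n_b: int
    degenerate: bool = False


def _paired_t(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test from the vector of paired differences."""
    n = len(diff)
    sd = diff.std(ddof=1)
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def group_trajectory_test(
    group_a: list[AngleSeries],
    group_b: list[AngleSeries],
    n_points: int = 100,
) -> GroupComparisonResult:
    """Paired t-test between two groups' mean joint-angle trajectories.

    Each subject's series is resampled to ``n_points``; within-group
    pointwise means form the two trajectories, and the test is paired across
    the positions.  Identical trajectories give t = 0, p = 1 (no effect); a
    constant non-zero difference has zero variance and is reported as
    degenerate rather than assigned a fabricated p-value.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    joint = group_a[0].joint
    mean_a = np.mean([resample_trajectory(s, n_points) for s in group_a], axis=0)
    mean_b = np.mean([resample_trajectory(s, n_points) for s in group_b], axis=0)
    diff = mean_a - mean_b
    d_val = label = None
    try:
        d_val = cohens_d(mean_a, mean_b)
        label = effect_size_label(d_val)
    except ValueError:
        pass
    if diff.std(ddof=1) == 0.0:
        if np.all(diff == 0.0):
            return GroupComparisonResult(
                joint, 0.0, 1.0, d_val, label, n_points, len(group_a), len(group_b)
            )
        return GroupComparisonResult(
            joint, None, None, d_val, label, n_points, len(group_a), len(group_b),
            degenerate=True,
        )
    t, p = _paired_t(diff)
    return GroupComparisonResult(
        joint, t, p, d_val, label, n_points, len(group_a), len(group_b)
    )


def cohens_d(a, b) -> float:
    """Unsigned Cohen's d with the pooled standard deviation.

    ``d = |mean_a − mean_b| / s_p`` with
    ``s_p² = ((n_a−1)s_a² + (n_b−1)s_b²) / (n_a+n_b−2)``.  Scale- and
    shift-invariant; raises on a zero pooled sd.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0.0:
        raise ValueError("pooled standard deviation is zero (degenerate groups)")
    return abs(float(a.mean() - b.mean())) / pooled


def effect_size_label(d: float) -> str:
    """Conventional interpretation bands: 0.2 small, 0.5 medium, 0.8 large."""
    d = abs(d)
    if d >= 0.8:
        return "large"
    if d >= 0.5:
        return "medium"
    if d >= 0.2:
        return "small"
    return "negligible"


# ---------------------------------------------------------------------------
# k-fold false-alarm harness

@dataclass
class FalseAlarmTable:
    """Per-joint, per-fold false alarms on held-out normal subjects."""

    counts: dict[str, list[int]]  # joint -> one count per fold
    n_subjects: int
    fold_sizes: list[int]

    @property
    def sums(self) -> dict[str, int]:
        return {j: int(sum(c)) for j, c in self.counts.items()}

    @property
    def rates(self) -> dict[str, float]:
        """Average false-alarm rate per joint: sum / total held-out subjects."""
        return {j: s / self.n_subjects for j, s in self.sums.items()}

    def to_frame(self) -> pd.DataFrame:
        k = len(self.fold_sizes)
        df = pd.DataFrame(self.counts, index=[f"fold{i+1}" for i in range(k)]).T
        df["SUM"] = [self.sums[j] for j in df.index]
        df["AVG"] = [f"{100 * self.rates[j]:.0f}%" for j in df.index]
        return df


def kfold_partition(n: int, k: int, seed: int) -> list[np.ndarray]:
    """A seeded shuffle split of range(n) into k folds with sizes differing by <= 1."""
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and at least k subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


def kfold_false_alarm(
    normal_subjects: list,
    k: int = 5,
    config=None,
    seed: int = 0,
) -> FalseAlarmTable:
    """Cross-validated per-joint false alarms on normal gait.

    For each fold the full pipeline (QC → angles → windows → training →
    threshold calibration) is refit on the other k−1 folds; each held-out
    normal subject flagged at joint j counts one false alarm for (j, fold).
    """
    from .pipeline import PipelineConfig, fit_reference, screen_subject

    if config is None:
        config = PipelineConfig()
    folds = kfold_partition(len(normal_subjects), k, seed)
    counts = {j: [0] * k for j in JOINTS}
    for f, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train = [s for i, s in enumerate(normal_subjects) if i not in test_set]
        ref = fit_reference(train, config=config, seed=seed + f + 1)
        for i in sorted(test_set):
            report = screen_subject(ref, normal_subjects[i])
            for j in JOINTS:
                if j in report.traces and report.traces[j].joint_decision:
                    counts[j][f] += 1
    return FalseAlarmTable(
        counts=counts,
        n_subjects=len(normal_subjects),
        fold_sizes=[len(f) for f in folds],
    )
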