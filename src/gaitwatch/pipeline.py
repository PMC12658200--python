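"""End-to-end orchestration: fit a reference model set, screen subjects.

``fit_reference`` runs QC → angle extraction → windowing → per-joint
autoencoder training → threshold calibration on a cohort of *normal*
subjects, producing an immutable :class:`ReferenceModelSet`.
``screen_subject`` applies the frozen normalisation, models and thresholds
to a new landmark stream — it never retrains or recalibrates, so screening
is reproducible bit for bit from the bundle alone.

Joint decisions default to the sequence level: a joint fires when the
subject's mean window reconstruction error exceeds a threshold calibrated
on the training subjects' per-subject mean errors (μ + 2σ).  This matches
flagging a whole gait sequence by its MSE, and keeps the any-joint OR rule
well behaved when a recording contributes many windows; window-level
flagging (any ``k_min`` windows over the window-error threshold) remains
available via ``decision_level="window"`` and always feeds the per-window
outlier traces used for plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect
from .detect import AnomalyTrace, SubjectReport
from .kinematics import JOINTS, AngleSeries, extract_angles
from .landmark_io import LandmarkSequence, read_landmarks
from .model import (
    JointModelConfig,
    TrainedJointModel,
    WindowSet,
    make_windows,
    reconstruction_errors,
    train_joint_model,
)
from .preprocess import run_qc

__all__ = [
    "PipelineConfig",
    "ReferenceModelSet",
    "fit_reference",
    "screen_subject",
    "screen_cohort",
    "cohort_summary",
]


@dataclass
class PipelineConfig:
    """One structured config for the whole screening pipeline."""

    visibility_min: float = 0.5
    lateral_tau: float = 0.35
    max_gap: int = 5
    window_length: int = 30
    window_stride: int = 15
    min_usable_frames: int | None = None  # default: 2 x window_length
    k_min: int = 1
    decision_level: str = "sequence"  # "sequence" | "window"
    model_overrides: dict = field(default_factory=dict)  # e.g. {"epochs": 50}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decision_level not in ("sequence", "window"):
            raise ValueError("decision_level must be 'sequence' or 'window'")
        if self.min_usable_frames is None:
            self.min_usable_frames = 2 * self.window_length


@dataclass
class ReferenceModelSet:
    """Five frozen joint models plus the config snapshot that produced them."""

    models: dict[str, TrainedJointModel]
    config: PipelineConfig
    n_training_subjects: int
    seed: int

    def __post_init__(self) -> None:
        missing = [j for j in JOINTS if j not in self.models]
        if missing:
            raise ValueError(f"reference set missing joint models: {missing}")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "gaitwatch-reference-set",
            "version": 1,
            "config": asdict(self.config),
            "n_training_subjects": self.n_training_subjects,
            "seed": self.seed,
            "joints": list(JOINTS),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for joint, model in self.models.items():
            model.save(directory / joint)

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceModelSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = PipelineConfig(**manifest["config"])
        models = {j: TrainedJointModel.load(directory / j) for j in manifest["joints"]}
        return cls(
            models=models,
            config=config,
            n_training_subjects=manifest["n_training_subjects"],
            seed=manifest["seed"],
        )


def _subject_angle_series(
    seq: LandmarkSequence, config: PipelineConfig, backend=None
) -> tuple[dict[str, AngleSeries] | None, int, int | None]:
    """QC a sequence and extract one (possibly gapped) series per joint."""
    segments, report = run_qc(
        seq,
        visibility_min=config.visibility_min,
        lateral_tau=config.lateral_tau,
        max_gap=config.max_gap,
        min_usable_frames=config.min_usable_frames,
        backend=backend,
    )
    if report.triage_class == 3 or not segments:
        return None, 0, report.triage_class
    per_joint: dict[str, list[AngleSeries]] = {j: [] for j in JOINTS}
    n_frames = 0
    for seg in segments:
        n_frames += len(seg)
        angles = extract_angles(seg)
        for j in JOINTS:
            per_joint[j].append(angles[j])
    merged = {}
    for j in JOINTS:
        parts = per_joint[j]
        merged[j] = AngleSeries(
            subject_id=seq.subject_id,
            joint=j,
            fps=seq.fps,
            frame_index=np.concatenate([p.frame_index for p in parts]),
            values=np.concatenate([p.values for p in parts]),
        )
    return merged, n_frames, report.triage_class


def _load_sequences(source) -> list[LandmarkSequence]:
    if isinstance(source, (str, Path)):
        paths = sorted(Path(source).glob("*.csv")) + sorted(Path(source).glob("*.json"))
        # angle tables produced alongside landmark files are not landmarks
        paths = [p for p in paths if not p.name.endswith(".angles.csv")]
        return [read_landmarks(p) for p in paths]
    return list(source)


def fit_reference(
    normal_subjects,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    backend=None,
) -> ReferenceModelSet:
    """Fit the five-joint reference model set on normal gait only.

    ``normal_subjects`` is a list of landmark sequences or a directory of
    canonical landmark files.  Normalisation statistics are pooled over all
    training subjects per joint; thresholds are μ + 2σ of the training
    reconstruction errors, at both the window level and the per-subject
    (sequence) level.  Raises if fewer than two subjects survive QC or any
    joint ends up with zero training windows.
    """
    if config is None:
        config = PipelineConfig()
    if seed is None:
        seed = config.seed
    sequences = _load_sequences(normal_subjects)
    L, S = config.window_length, config.window_stride

    usable: list[dict[str, AngleSeries]] = []
    for seq in sequences:
        series, _, triage = _subject_angle_series(seq, config, backend=backend)
        if series is not None:
            usable.append(series)
    if len(usable) < 2:
        raise ValueError(
            f"need at least 2 usable normal subjects after QC, got {len(usable)}"
        )

    models: dict[str, TrainedJointModel] = {}
    for j_idx, joint in enumerate(JOINTS):
        all_vals = np.concatenate([s[joint].values for s in usable])
        stats = (float(all_vals.mean()), float(all_vals.std(ddof=0)))
        window_sets = [make_windows(s[joint], L, S, stats=stats) for s in usable]
        train_ws = WindowSet.concat(window_sets)
        if len(train_ws) == 0:
            raise ValueError(f"zero training windows for joint {joint!r}")
        jm_config = JointModelConfig.for_joint(
            joint,
            window_length=L,
            window_stride=S,
            seed=seed + j_idx,
            **config.model_overrides,
        )
        model = train_joint_model(train_ws, jm_config)

        errs = reconstruction_errors(model, train_ws)
        model.train_error_mean = float(errs.mean())
        model.train_error_sd = float(errs.std(ddof=1))
        model.window_threshold = detect.calibrate_threshold(errs)
        # per-subject (sequence-level) mean errors, in concat order
        subj_errors = []
        offset = 0
        for ws in window_sets:
            if len(ws) == 0:
                continue
            subj_errors.append(float(errs[offset : offset + len(ws)].mean()))
            offset += len(ws)
        model.sequence_threshold = detect.calibrate_threshold(subj_errors)
        models[joint] = model

    return ReferenceModelSet(
        models=models,
        config=config,
        n_training_subjects=len(usable),
        seed=seed,
    )


def screen_subject(
    ref: ReferenceModelSet,
    seq: LandmarkSequence,
    backend=None,
) -> SubjectReport:
    """Score one subject against a frozen reference model set.

    QC-class-3 sequences yield a report whose ``subject_decision`` is
    ``None`` (undetermined) rather than a guess.  Otherwise every window of
    every joint is scored with the frozen normalisation; the joint decision
    follows the configured decision level and the subject decision is the OR
    over the five joints.  A joint whose usable series is shorter than one
    window gets an empty trace and a false decision.
    """
    config = ref.config
    series, n_frames, triage = _subject_angle_series(seq, config, backend=backend)
    if series is None:
        return SubjectReport(
            subject_id=seq.subject_id,
            traces={},
            subject_decision=None,
            n_usable_frames=0,
            qc_class=triage,
        )
    traces: dict[str, AnomalyTrace] = {}
    for joint in JOINTS:
        model = ref.models[joint]
        ws = make_windows(
            series[joint],
            config.window_length,
            config.window_stride,
            stats=(model.mean, model.sd),
        )
        if len(ws) == 0:
            traces[joint] = AnomalyTrace(
                joint=joint,
                errors=np.zeros(0),
                threshold=model.window_threshold,
                flags=np.zeros(0, dtype=bool),
                joint_decision=False,
            )
            continue
        errs = reconstruction_errors(model, ws)
        trace = detect.flag_anomalies(
            errs,
            model.window_threshold,
            k_min=config.k_min,
            window_starts=[p[1] for p in ws.provenance],
            window_length=config.window_length,
        )
        trace.joint = joint
        trace.sequence_error = float(errs.mean())
        trace.sequence_threshold = model.sequence_threshold
        if config.decision_level == "sequence":
            trace.joint_decision = bool(trace.sequence_error > model.sequence_threshold)
        traces[joint] = trace
    return SubjectReport(
        subject_id=seq.subject_id,
        traces=traces,
        subject_decision=detect.subject_decision(traces),
        n_usable_frames=n_frames,
        qc_class=triage,
    )


def screen_cohort(
    ref: ReferenceModelSet, sequences, backend=None
) -> list[SubjectReport]:
    return [screen_subject(ref, seq, backend=backend) for seq in _load_sequences(sequences)]


def cohort_summary(reports: list[SubjectReport]) -> dict:
    """Joint counts, co-detection matrix and the subject decision table."""
    determined = [r for r in reports if r.subject_decision is not None]
    M, counts = detect.co_detection_matrix(determined)
    table = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                **{j: r.traces[j].joint_decision for j in JOINTS if j in r.traces},
                "subject_decision": r.subject_decision,
            }
            for r in reports
        ]
    )
    return {
        "joint_counts": counts,
        "co_detection": pd.DataFrame(M, index=list(JOINTS), columns=list(JOINTS)),
        "decisions": table,
        "n_abnormal": int(sum(bool(r.subject_decision) for r in determined)),
        "n_determined": len(determined),
    }
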