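"""Per-joint sequence-autoencoder anomaly models.

Each of the five joint-angle channels gets its own univariate recurrent
autoencoder trained exclusively on normal gait.  An angle series is cut into
fixed-length sliding windows (default 30 frames ≈ one second at 30 fps,
stride 15), z-scored with training-set statistics, and reconstructed through
a two-layer LSTM encoder, a 16-dimensional bottleneck, and a mirrored
decoder; the mean squared reconstruction error of a window is the anomaly
score.  The right knee — the joint with the largest, most structured
excursions — uses a wider 64–32/32–64 encoder/decoder; all other joints use
32–16/16–32.  Dropout 0.2 in encoder and decoder, Adam at learning rate
1e-4, and per-joint epoch/batch settings are fixed in
:data:`JOINT_HYPERPARAMS`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

from ._lstm import SequenceAutoencoder
from .kinematics import JOINTS, AngleSeries

__all__ = [
    "JOINT_HYPERPARAMS",
    "JointModelConfig",
    "WindowSet",
    "TrainedJointModel",
    "make_windows",
    "train_joint_model",
    "reconstruction_errors",
]

#: Per-joint (encoder units, epochs, batch size).
JOINT_HYPERPARAMS: dict[str, dict] = {
    "right_hip": {"units": (32, 16), "epochs": 200, "batch_size": 16},
    "left_hip": {"units": (32, 16), "epochs": 150, "batch_size": 32},
    "right_knee": {"units": (64, 32), "epochs": 150, "batch_size": 32},
    "left_knee": {"units": (32, 16), "epochs": 200, "batch_size": 64},
    "nose_shoulder": {"units": (32, 16), "epochs": 150, "batch_size": 64},
}


@dataclass
class JointModelConfig:
    """Architecture and training hyperparameters for one joint's model."""

    joint: str
    units: tuple[int, int] = (32, 16)
    latent_dim: int = 16
    dropout: float = 0.2
    optimizer: str = "adam"
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-4
    window_length: int = 30
    window_stride: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 1 <= self.window_stride <= self.window_length:
            raise ValueError("window_stride must be in [1, window_length]")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    @classmethod
    def for_joint(cls, joint: str, **overrides) -> "JointModelConfig":
        """The standard configuration for a joint, with optional overrides."""
        hp = JOINT_HYPERPARAMS[joint]
        kwargs = dict(
            joint=joint,
            units=hp["units"],
            epochs=hp["epochs"],
            batch_size=hp["batch_size"],
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class WindowSet:
    """Fixed-length z-scored windows of one joint's angle series."""

    joint: str
    windows: np.ndarray  # (n_windows, L)
    mean: float  # normalization stats, degrees (training-set derived)
    sd: float
    provenance: list[tuple[str, int]] = field(default_factory=list)  # (subject, start frame)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        if self.windows.ndim != 2:
            raise ValueError("windows must be 2-D (n_windows, L)")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_length(self) -> int:
        return self.windows.shape[1]

    @classmethod
    def concat(cls, sets: list["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValueError("cannot concatenate zero WindowSets")
        joint = sets[0].joint
        mean, sd = sets[0].mean, sets[0].sd
        for s in sets:
            if s.joint != joint or s.mean != mean or s.sd != sd:
                raise ValueError("WindowSets must share joint and stats to concatenate")
        nonempty = [s.windows for s in sets if len(s)]
        windows = (
            np.concatenate(nonempty, axis=0)
            if nonempty
            else np.zeros((0, sets[0].window_length))
        )
        prov = [p for s in sets for p in s.provenance]
        return cls(joint, windows, mean, sd, prov)


_SD_GUARD = 1e-8


def make_windows(
    series: AngleSeries,
    L: int = 30,
    S: int = 15,
    stats: tuple[float, float] | None = None,
) -> WindowSet:
    """Cut an angle series into z-scored sliding windows.

    Windows start at 0, S, 2S, … within each contiguous run of frames (the
    series may carry gaps from QC); ``stats = (mean, sd)`` are applied when
    given (scoring against a trained model), otherwise computed from the
    series itself (fitting).  A near-zero standard deviation is guarded to 1
    so constant series z-score to all zeros.  A series shorter than ``L``
    yields an empty set.
    """
    if L < 2 or not 1 <= S <= L:
        raise ValueError("require L >= 2 and 1 <= S <= L")
    vals = series.values
    if stats is None:
        mean = float(vals.mean()) if len(vals) else 0.0
        sd = float(vals.std(ddof=0)) if len(vals) else 1.0
    else:
        mean, sd = float(stats[0]), float(stats[1])
    sd_eff = sd if sd >= _SD_GUARD else 1.0

    windows: list[np.ndarray] = []
    prov: list[tuple[str, int]] = []
    # contiguous runs of frame indices
    fidx = series.frame_index
    if len(fidx):
        breaks = np.flatnonzero(np.diff(fidx) != 1)
        bounds = np.concatenate([[0], breaks + 1, [len(fidx)]])
    else:
        bounds = np.array([0, 0])
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        seg = vals[b0:b1]
        for start in range(0, len(seg) - L + 1, S):
            windows.append(seg[start : start + L])
            prov.append((series.subject_id, int(fidx[b0 + start])))
    if not windows and len(vals):
        logger.warning(
            "series %s/%s shorter than one window (L=%d); empty WindowSet",
            series.subject_id, series.joint, L,
        )
    arr = np.asarray(windows) if windows else np.zeros((0, L))
    arr = (arr - mean) / sd_eff
    return WindowSet(series.joint, arr, mean, sd, prov)


@dataclass
class TrainedJointModel:
    """A fitted per-joint autoencoder with its stats and calibrated thresholds."""

    config: JointModelConfig
    net: SequenceAutoencoder
    mean: float
    sd: float
    window_threshold: float | None = None  # mu + 2 sigma of training window errors
    sequence_threshold: float | None = None  # mu + 2 sigma of training per-subject errors
    train_error_mean: float | None = None
    train_error_sd: float | None = None
    loss_history: list[float] = field(default_factory=list)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.net.reconstruct(X)

    # -- persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "gaitwatch-joint-model",
            "version": 1,
            "config": asdict(self.config),
            "mean": self.mean,
            "sd": self.sd,
            "window_threshold": self.window_threshold,
            "sequence_threshold": self.sequence_threshold,
            "train_error_mean": self.train_error_mean,
            "train_error_sd": self.train_error_sd,
            "loss_history": self.loss_history,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savez(directory / "weights.npz", **self.net.get_weights())

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedJointModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        cfg_dict = manifest["config"]
        cfg_dict["units"] = tuple(cfg_dict["units"])
        config = JointModelConfig(**cfg_dict)
        net = SequenceAutoencoder(
            n_channels=1,
            enc_units=config.units,
            latent_dim=config.latent_dim,
            dropout=config.dropout,
            seed=config.seed,
        )
        with np.load(directory / "weights.npz") as data:
            net.set_weights({k: data[k] for k in data.files})
        return cls(
            config=config,
            net=net,
            mean=manifest["mean"],
            sd=manifest["sd"],
            window_threshold=manifest["window_threshold"],
            sequence_threshold=manifest["sequence_threshold"],
            train_error_mean=manifest["train_error_mean"],
            train_error_sd=manifest["train_error_sd"],
            loss_history=list(manifest.get("loss_history", [])),
        )


def train_joint_model(train: WindowSet, config: JointModelConfig) -> TrainedJointModel:
    """Fit one joint's autoencoder on normal-gait windows.

    Fully seeded: weight initialisation, epoch shuffling and dropout masks
    all derive from ``config.seed``, so the same data and seed reproduce the
    same weights bit for bit.  Raises ``FloatingPointError`` (naming the
    epoch) if the loss goes non-finite.
    """
    if len(train) == 0:
        raise ValueError(f"no training windows for joint {config.joint!r}")
    if train.window_length != config.window_length:
        raise ValueError(
            f"window length {train.window_length} != configured {config.window_length}"
        )
    net = SequenceAutoencoder(
        n_channels=1,
        enc_units=config.units,
        latent_dim=config.latent_dim,
        dropout=config.dropout,
        seed=config.seed,
    )
    X = train.windows[:, :, None]
    history = net.fit(
        X,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
    )
    return TrainedJointModel(
        config=config,
        net=net,
        mean=train.mean,
        sd=train.sd,
        loss_history=history,
    )


def reconstruction_errors(model, windows: WindowSet, batch_size: int = 256) -> np.ndarray:
    """Per-window mean squared reconstruction error.

    ``error_w = (1/L) * sum_t (x_t - x_hat_t)^2`` in normalised units.
    ``model`` is anything exposing ``reconstruct(X)`` on (n, L, 1) arrays —
    a :class:`TrainedJointModel`, a raw network, or a stub in tests.
    """
    X = windows.windows[:, :, None]
    L = getattr(getattr(model, "config", None), "window_length", None)
    if L is not None and X.shape[1] != L:
        raise ValueError(f"window length {X.shape[1]} does not match model ({L})")
    errs = np.empty(X.shape[0])
    for start in range(0, X.shape[0], batch_size):
        chunk = X[start : start + batch_size]
        Xhat = model.reconstruct(chunk)
        if Xhat.shape != chunk.shape:
            raise ValueError("reconstruction shape mismatch")
        errs[start : start + batch_size] = np.mean((Xhat - chunk) ** 2, axis=(1, 2))
    return errs
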