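"""Reading and writing pose-landmark time series.

The canonical on-disk schema is deliberately plain: a CSV with one row per
(frame, landmark) and the columns ``subject_id, frame, landmark, x, y,
visibility``, preceded by ``#``-prefixed header lines recording fps, units and
frame size, or an equivalent JSON document with one object per frame.  A
``pose33`` dialect adapter maps the 33-point full-body convention used by
common markerless pose estimators onto the nine landmarks the gait pipeline
needs (nose, shoulders, hips, knees, ankles).

Coordinates follow the image convention throughout: origin at the top-left,
x to the right, y **downward**.  Normalised coordinates in [0, 1] are the
internal standard; pixel inputs are converted on load using the recorded
frame size.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_LANDMARKS",
    "POSE33_INDEX",
    "LandmarkFrame",
    "LandmarkSequence",
    "FormatError",
    "read_landmarks",
    "write_landmarks",
    "read_angles_csv",
    "write_angles_csv",
]

#: The nine landmarks required for the five gait joint angles.
REQUIRED_LANDMARKS: tuple[str, ...] = (
    "nose",
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: Index of each required landmark in the 33-point body convention.
POSE33_INDEX: dict[str, int] = {
    "nose": 0,
    "left_shoulder": 11,
    "right_shoulder": 12,
    "left_hip": 23,
    "right_hip": 24,
    "left_knee": 25,
    "right_knee": 26,
    "left_ankle": 27,
    "right_ankle": 28,
}


class FormatError(ValueError):
    """A landmark file does not conform to the requested dialect."""


@dataclass
class LandmarkFrame:
    """Named 2D landmarks with visibility for a single video frame."""

    frame_index: int
    landmarks: dict[str, tuple[float, float, float]]  # name -> (x, y, visibility)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        for name, (x, y, v) in self.landmarks.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for landmark {name!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"visibility out of [0, 1] for landmark {name!r}")


@dataclass
class LandmarkSequence:
    """An ordered landmark time series for one subject.

    Data are stored columnar for speed: ``xy`` has shape ``(n_frames,
    n_landmarks, 2)`` and ``visibility`` ``(n_frames, n_landmarks)``, with
    ``landmark_names`` fixing the landmark axis order.
    """

    subject_id: str
    fps: float
    landmark_names: tuple[str, ...]
    frame_index: np.ndarray  # (n,) int
    xy: np.ndarray  # (n, k, 2) float
    visibility: np.ndarray  # (n, k) float in [0, 1]
    units: str = "normalized"  # "normalized" | "pixels"
    frame_width: float | None = None
    frame_height: float | None = None

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        self.visibility = np.asarray(self.visibility, dtype=np.float64)
        n, k = len(self.frame_index), len(self.landmark_names)
        if self.xy.shape != (n, k, 2):
            raise ValueError(f"xy shape {self.xy.shape} != {(n, k, 2)}")
        if self.visibility.shape != (n, k):
            raise ValueError("visibility shape mismatch")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if n and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        if self.units not in ("normalized", "pixels"):
            raise ValueError(f"unknown units {self.units!r}")

    def __len__(self) -> int:
        return len(self.frame_index)

    def landmark_idx(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise KeyError(f"landmark {name!r} not present") from None

    def frame(self, i: int) -> LandmarkFrame:
        """The i-th retained frame as a :class:`LandmarkFrame`."""
        lms = {
            name: (self.xy[i, j, 0], self.xy[i, j, 1], self.visibility[i, j])
            for j, name in enumerate(self.landmark_names)
        }
        return LandmarkFrame(int(self.frame_index[i]), lms)

    def take(self, mask_or_idx: np.ndarray) -> "LandmarkSequence":
        """A new sequence restricted to the selected frames."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LandmarkSequence(
            subject_id=self.subject_id,
            fps=self.fps,
            landmark_names=self.landmark_names,
            frame_index=self.frame_index[idx],
            xy=self.xy[idx],
            visibility=self.visibility[idx],
            units=self.units,
            frame_width=self.frame_width,
            frame_height=self.frame_height,
        )

    @classmethod
    def from_frames(
        cls,
        subject_id: str,
        fps: float,
        frames: Sequence[LandmarkFrame],
        units: str = "normalized",
        frame_width: float | None = None,
        frame_height: float | None = None,
    ) -> "LandmarkSequence":
        if frames:
            names = tuple(frames[0].landmarks.keys())
        else:
            names = REQUIRED_LANDMARKS
        n, k = len(frames), len(names)
        xy = np.zeros((n, k, 2))
        vis = np.ones((n, k))
        fidx = np.zeros(n, dtype=np.int64)
        for i, fr in enumerate(frames):
            fidx[i] = fr.frame_index
            for j, name in enumerate(names):
                x, y, v = fr.landmarks[name]
                xy[i, j] = (x, y)
                vis[i, j] = v
        return cls(subject_id, fps, names, fidx, xy, vis, units, frame_width, frame_height)


def _to_normalized(seq: LandmarkSequence) -> LandmarkSequence:
    """Convert a pixel-unit sequence to normalised coordinates in place."""
    if seq.units == "normalized":
        return seq
    if not seq.frame_width or not seq.frame_height:
        raise FormatError("pixel-unit sequence requires frame_width and frame_height")
    xy = seq.xy.copy()
    xy[..., 0] /= seq.frame_width
    xy[..., 1] /= seq.frame_height
    return LandmarkSequence(
        seq.subject_id, seq.fps, seq.landmark_names, seq.frame_index,
        xy, seq.visibility, "normalized", seq.frame_width, seq.frame_height,
    )


# ---------------------------------------------------------------------------
# canonical serialization

_HEADER_KEYS = ("subject_id", "fps", "units", "frame_width", "frame_height")


def _header_lines(seq: LandmarkSequence) -> list[str]:
    lines = ["# gaitwatch-landmarks v1"]
    lines.append(f"# subject_id: {seq.subject_id}")
    lines.append(f"# fps: {seq.fps!r}")
    lines.append(f"# units: {seq.units}")
    if seq.frame_width is not None:
        lines.append(f"# frame_width: {seq.frame_width!r}")
    if seq.frame_height is not None:
        lines.append(f"# frame_height: {seq.frame_height!r}")
    return lines


def _parse_header(text_lines: Iterable[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in text_lines:
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            key = key.strip()
            if key in _HEADER_KEYS:
                meta[key] = val.strip()
    return meta


def write_landmarks(seq: LandmarkSequence, path: str | Path) -> None:
    """Serialize a sequence losslessly to canonical CSV (or JSON by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        _write_json(seq, path)
        return
    n, k = len(seq), len(seq.landmark_names)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(seq.subject_id, n * k),
            "frame": np.repeat(seq.frame_index, k),
            "landmark": np.tile(np.asarray(seq.landmark_names, dtype=object), n),
            "x": seq.xy[..., 0].ravel(),
            "y": seq.xy[..., 1].ravel(),
            "visibility": seq.visibility.ravel(),
        }
    )
    buf = io.StringIO()
    buf.write("\n".join(_header_lines(seq)) + "\n")
    df.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue())


def _write_json(seq: LandmarkSequence, path: Path) -> None:
    frames = []
    for i in range(len(seq)):
        frames.append(
            {
                "frame": int(seq.frame_index[i]),
                "landmarks": {
                    name: {
                        "x": float(seq.xy[i, j, 0]),
                        "y": float(seq.xy[i, j, 1]),
                        "visibility": float(seq.visibility[i, j]),
                    }
                    for j, name in enumerate(seq.landmark_names)
                },
            }
        )
    doc = {
        "format": "gaitwatch-landmarks",
        "version": 1,
        "subject_id": seq.subject_id,
        "fps": seq.fps,
        "units": seq.units,
        "frame_width": seq.frame_width,
        "frame_height": seq.frame_height,
        "frames": frames,
    }
    Path(path).write_text(json.dumps(doc))


def read_landmarks(path: str | Path, dialect: str = "canonical") -> LandmarkSequence:
    """Load a landmark sequence.

    Parameters
    ----------
    path
        CSV or JSON file (by suffix).
    dialect
        ``"canonical"`` loads verbatim; ``"pose33"`` maps the 33-point body
        convention (by landmark index or name) onto the canonical nine
        landmarks and discards the rest.
    """
    if dialect not in ("canonical", "pose33"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        seq = _read_json(path)
    else:
        seq = _read_csv(path)
    if dialect == "pose33":
        seq = _adapt_pose33(seq)
    missing = [n for n in REQUIRED_LANDMARKS if n not in seq.landmark_names]
    if missing:
        raise FormatError(f"missing required landmark: {missing[0]}")
    return _to_normalized(seq)


def _read_csv(path: Path) -> LandmarkSequence:
    with open(path) as fh:
        head = []
        for line in fh:
            if line.startswith("#"):
                head.append(line)
            else:
                break
    meta = _parse_header(head)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("frame", "landmark", "x", "y", "visibility"):
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    return _from_long_table(df, meta)


def _from_long_table(df: pd.DataFrame, meta: Mapping[str, str]) -> LandmarkSequence:
    subject_id = meta.get("subject_id") or (
        str(df["subject_id"].iloc[0]) if "subject_id" in df.columns and len(df) else "unknown"
    )
    fps = float(meta.get("fps", 30.0))
    units = meta.get("units", "normalized")
    fw = float(meta["frame_width"]) if "frame_width" in meta else None
    fh = float(meta["frame_height"]) if "frame_height" in meta else None
    if len(df) == 0:
        return LandmarkSequence(
            subject_id, fps, REQUIRED_LANDMARKS,
            np.zeros(0, dtype=np.int64), np.zeros((0, 9, 2)), np.zeros((0, 9)),
            units, fw, fh,
        )
    names = tuple(dict.fromkeys(df["landmark"].astype(str)))
    frames = np.asarray(sorted(df["frame"].unique()), dtype=np.int64)
    pos = {f: i for i, f in enumerate(frames)}
    col = {n: j for j, n in enumerate(names)}
    n, k = len(frames), len(names)
    xy = np.full((n, k, 2), np.nan)
    vis = np.zeros((n, k))
    fi = df["frame"].map(pos).to_numpy()
    li = df["landmark"].astype(str).map(col).to_numpy()
    xy[fi, li, 0] = df["x"].to_numpy(float)
    xy[fi, li, 1] = df["y"].to_numpy(float)
    vis[fi, li] = df["visibility"].to_numpy(float)
    if np.isnan(xy).any():
        bad = names[int(np.argwhere(np.isnan(xy[..., 0]))[0][1])]
        raise FormatError(f"missing coordinates for landmark: {bad}")
    return LandmarkSequence(subject_id, fps, names, frames, xy, vis, units, fw, fh)


def _read_json(path: Path) -> LandmarkSequence:
    doc = json.loads(Path(path).read_text())
    frames = doc.get("frames", [])
    lm_frames = []
    for fr in frames:
        lm_frames.append(
            LandmarkFrame(
                int(fr["frame"]),
                {
                    name: (rec["x"], rec["y"], rec.get("visibility", 1.0))
                    for name, rec in fr["landmarks"].items()
                },
            )
        )
    return LandmarkSequence.from_frames(
        subject_id=str(doc.get("subject_id", "unknown")),
        fps=float(doc.get("fps", 30.0)),
        frames=lm_frames,
        units=doc.get("units", "normalized"),
        frame_width=doc.get("frame_width"),
        frame_height=doc.get("frame_height"),
    )


_POSE33_BY_INDEX = {v: k for k, v in POSE33_INDEX.items()}


def _adapt_pose33(seq: LandmarkSequence) -> LandmarkSequence:
    """Subset/rename a 33-point sequence to the canonical nine landmarks."""
    canonical: dict[str, int] = {}
    for j, raw in enumerate(seq.landmark_names):
        name = str(raw)
        if name.isdigit():
            mapped = _POSE33_BY_INDEX.get(int(name))
        else:
            mapped = name if name in POSE33_INDEX else None
        if mapped is not None and mapped not in canonical:
            canonical[mapped] = j
    missing = [n for n in REQUIRED_LANDMARKS if n not in canonical]
    if missing:
        raise FormatError(f"missing required landmark: {missing[0]}")
    cols = [canonical[n] for n in REQUIRED_LANDMARKS]
    return LandmarkSequence(
        seq.subject_id, seq.fps, REQUIRED_LANDMARKS, seq.frame_index,
        seq.xy[:, cols], seq.visibility[:, cols],
        seq.units, seq.frame_width, seq.frame_height,
    )


# ---------------------------------------------------------------------------
# joint-angle tables

def write_angles_csv(series: Iterable, path: str | Path) -> None:
    """Write AngleSeries records to a long CSV (subject_id, frame, joint, degrees)."""
    rows = []
    for s in series:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "frame": s.frame_index,
                    "joint": s.joint,
                    "degrees": s.values,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["subject_id", "frame", "joint", "degrees"]
    )
    out.to_csv(path, index=False, float_format="%.17g")


def read_angles_csv(path: str | Path, fps: float = 30.0) -> list:
    """Read a long angle CSV back into AngleSeries objects (one per subject, joint)."""
    from .kinematics import AngleSeries

    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (sid, joint), grp in df.groupby(["subject_id", "joint"], sort=True):
        grp = grp.sort_values("frame")
        out.append(
            AngleSeries(
                subject_id=str(sid),
                joint=str(joint),
                fps=fps,
                frame_index=grp["frame"].to_numpy(np.int64),
                values=grp["degrees"].to_numpy(float),
            )
        )
    return out
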