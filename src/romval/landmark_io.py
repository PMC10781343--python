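"""Data model and I/O for 3D landmark trajectory streams.

Trajectories are wide tables: one row per frame, three columns per landmark
named ``<landmark>_x``, ``<landmark>_y``, ``<landmark>_z``.  Positions are in
meters; missing landmark-frame pairs are empty cells on disk and NaN triples
in memory (zero is a valid coordinate and is never used to mean "missing").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError, TrajectoryParseError, ValidationError

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class SkeletonDefinition:
    """A named, ordered landmark set plus a canonical-joint-name mapping."""

    name: str
    landmarks: tuple[str, ...]
    joint_map: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "landmarks", tuple(self.landmarks))
        object.__setattr__(self, "joint_map", dict(self.joint_map))
        if len(set(self.landmarks)) != len(self.landmarks):
            raise ValidationError(f"duplicate landmark names in skeleton {self.name!r}")
        unknown = {j: lm for j, lm in self.joint_map.items() if lm not in self.landmarks}
        if unknown:
            raise ValidationError(
                f"joint_map of {self.name!r} references unknown landmarks: {unknown}"
            )

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks)

    def landmark_index(self, landmark: str) -> int:
        try:
            return self.landmarks.index(landmark)
        except ValueError:
            raise ValidationError(f"unknown landmark {landmark!r} in skeleton {self.name!r}")

    def joint_landmark(self, joint: str) -> str:
        try:
            return self.joint_map[joint]
        except KeyError:
            raise ValidationError(f"joint {joint!r} not mapped in skeleton {self.name!r}")

    def joint_index(self, joint: str) -> int:
        return self.landmark_index(self.joint_landmark(joint))

    def has_joint(self, joint: str) -> bool:
        return joint in self.joint_map

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "landmarks": list(self.landmarks), "joint_map": dict(self.joint_map)},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SkeletonDefinition":
        d = json.loads(text)
        return cls(name=d["name"], landmarks=tuple(d["landmarks"]), joint_map=d["joint_map"])


#: 33-landmark monocular pose-estimation skeleton (BlazePose topology).
MEDIAPIPE_33 = SkeletonDefinition(
    name="mediapipe33",
    landmarks=(
        "nose",
        "left_eye_inner", "left_eye", "left_eye_outer",
        "right_eye_inner", "right_eye", "right_eye_outer",
        "left_ear", "right_ear",
        "mouth_left", "mouth_right",
        "left_shoulder", "right_shoulder",
        "left_elbow", "right_elbow",
        "left_wrist", "right_wrist",
        "left_pinky", "right_pinky",
        "left_index", "right_index",
        "left_thumb", "right_thumb",
        "left_hip", "right_hip",
        "left_knee", "right_knee",
        "left_ankle", "right_ankle",
        "left_heel", "right_heel",
        "left_foot_index", "right_foot_index",
    ),
    joint_map={
        "shoulder_l": "left_shoulder", "shoulder_r": "right_shoulder",
        "elbow_l": "left_elbow", "elbow_r": "right_elbow",
        "wrist_l": "left_wrist", "wrist_r": "right_wrist",
        "hip_l": "left_hip", "hip_r": "right_hip",
        "knee_l": "left_knee", "knee_r": "right_knee",
        "ankle_l": "left_ankle", "ankle_r": "right_ankle",
    },
)

#: 6-marker optical motion-capture set (right body side only).
MOCAP_6 = SkeletonDefinition(
    name="mocap6",
    landmarks=(
        "acromion",
        "humerus_lat_epicondyle",
        "radius_styloid",
        "greater_trochanter",
        "femur_lat_epicondyle",
        "lateral_malleolus",
    ),
    joint_map={
        "shoulder_r": "acromion",
        "elbow_r": "humerus_lat_epicondyle",
        "wrist_r": "radius_styloid",
        "hip_r": "greater_trochanter",
        "knee_r": "femur_lat_epicondyle",
        "ankle_r": "lateral_malleolus",
    },
)

SKELETONS = {"mediapipe33": MEDIAPIPE_33, "mocap6": MOCAP_6}


@dataclass
class LandmarkTrajectory:
    """Time-indexed 3D positions for a landmark set sampled at a fixed rate.

    ``positions`` has shape ``(n_frames, n_landmarks, 3)``.  A missing
    landmark-frame pair is an all-NaN triple; partially-NaN triples are
    normalized to all-NaN at construction.
    """

    skeleton: SkeletonDefinition
    fps: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.fps) or self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValidationError(f"positions must have shape (n_frames, n_landmarks, 3), got {pos.shape}")
        if pos.shape[1] != self.skeleton.n_landmarks:
            raise ValidationError(
                f"positions second axis ({pos.shape[1]}) does not match skeleton "
                f"{self.skeleton.name!r} ({self.skeleton.n_landmarks} landmarks)"
            )
        if pos.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        if np.isinf(pos).any():
            raise ValidationError("positions must be finite or NaN")
        partial = np.isnan(pos).any(axis=2)
        pos = pos.copy()
        pos[partial] = np.nan
        self.positions = pos

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame_index / fps)."""
        return np.arange(self.n_frames) / self.fps

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_frames, n_landmarks); True where the position is missing."""
        return np.isnan(self.positions[:, :, 0])

    def landmark(self, name: str) -> np.ndarray:
        return self.positions[:, self.skeleton.landmark_index(name), :]

    def joint(self, joint: str) -> np.ndarray:
        return self.positions[:, self.skeleton.joint_index(joint), :]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkTrajectory):
            return NotImplemented
        return (
            self.skeleton == other.skeleton
            and self.fps == other.fps
            and self.positions.shape == other.positions.shape
            and np.array_equal(self.positions, other.positions, equal_nan=True)
        )


@dataclass
class AcquisitionPair:
    """One acquisition: simultaneous ground-truth and predicted streams."""

    ground_truth: LandmarkTrajectory
    predicted: LandmarkTrajectory
    exercise: str
    subject_id: str = "unknown"
    meta: dict = field(default_factory=dict)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def expected_columns(skeleton: SkeletonDefinition) -> list[str]:
    return [f"{lm}_{ax}" for lm in skeleton.landmarks for ax in _AXES]


def read_trajectory(path: str | Path, skeleton: SkeletonDefinition, fps: float) -> LandmarkTrajectory:
    """Read a wide-format landmark table (.csv or .tsv) into a trajectory.

    Raises :class:`SchemaError` when required columns are absent,
    :class:`TrajectoryParseError` (with 1-based data row number) on
    non-numeric cells, and :class:`ValidationError` for fps <= 0.
    """
    if not np.isfinite(fps) or fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, skipinitialspace=True)
    required = expected_columns(skeleton)
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing_cols)}")
    if len(df) == 0:
        raise DataError(f"{path}: trajectory file contains no data rows")
    n = len(df)
    pos = np.empty((n, skeleton.n_landmarks, 3))
    for li, lm in enumerate(skeleton.landmarks):
        for ai, ax in enumerate(_AXES):
            col = df[f"{lm}_{ax}"]
            numeric = pd.to_numeric(col, errors="coerce")
            bad = numeric.isna() & col.notna() & (col.str.strip() != "")
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise TrajectoryParseError(
                    f"{path}: non-numeric value {col[bad.idxmax()]!r} in column "
                    f"'{lm}_{ax}', data row {row}"
                )
            # exact (correctly rounded) parse; pandas' fast path is lossy
            pos[:, li, ai] = [
                float(s) if isinstance(s, str) and s.strip() != "" else np.nan for s in col
            ]
    return LandmarkTrajectory(skeleton=skeleton, fps=float(fps), positions=pos)


def write_trajectory(traj: LandmarkTrajectory, path: str | Path) -> None:
    """Write a trajectory in the wide dialect accepted by :func:`read_trajectory`.

    Missing positions become empty cells.  Values are serialized with
    ``repr``-level precision so write -> read round trips bit-exactly.
    """
    path = Path(path)
    cols = expected_columns(traj.skeleton)
    flat = traj.positions.reshape(traj.n_frames, -1)
    df = pd.DataFrame(flat, columns=cols)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g", na_rep="")
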