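"""Joint amplitude (range-of-motion) time series per exercise.

The amplitude at a frame is the unsigned angle, in [0, 180] degrees, between
the moving body-segment vector projected onto the plane of movement and a
reference direction (constant "down" = +Y in the anatomical convention for
all exercises except the squat, whose reference is the per-frame foot->knee
vector, projected onto the same plane).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Union

import numpy as np
import yaml

from .errors import ConfigError, ValidationError
from .landmark_io import LandmarkTrajectory

#: Plane-of-movement normals in the anatomical convention.
PLANE_NORMALS = {
    "frontal": np.array([0.0, 0.0, 1.0]),   # Z-axis
    "sagittal": np.array([1.0, 0.0, 0.0]),  # X-axis
}

#: "Vertically downward" reference (shoulders -> hips direction).
DOWN = np.array([0.0, 1.0, 0.0])

Reference = Union[str, tuple]  # "down" or a (from_joint, to_joint) pair


@dataclass(frozen=True)
class ExerciseConfig:
    code: str
    plane: str
    segment_joints: tuple[str, str]
    reference: Reference
    evaluated_joint: str
    moving_limb: str

    def __post_init__(self) -> None:
        if self.plane not in PLANE_NORMALS:
            raise ConfigError(f"unknown plane {self.plane!r} for exercise {self.code!r}")
        object.__setattr__(self, "segment_joints", tuple(self.segment_joints))
        if len(self.segment_joints) != 2:
            raise ConfigError("segment_joints must be an ordered (joint1, joint2) pair")
        if isinstance(self.reference, (tuple, list)):
            object.__setattr__(self, "reference", tuple(self.reference))
            if len(self.reference) != 2:
                raise ConfigError("dynamic reference must be a (from_joint, to_joint) pair")
        elif self.reference != "down":
            raise ConfigError(f"reference must be 'down' or a joint pair, got {self.reference!r}")

    @property
    def plane_normal(self) -> np.ndarray:
        return PLANE_NORMALS[self.plane]

    @property
    def required_joints(self) -> tuple[str, ...]:
        joints = list(self.segment_joints)
        if isinstance(self.reference, tuple):
            joints += [j for j in self.reference if j not in joints]
        return tuple(joints)


# Built-in registry: 8 physiotherapy exercises.  Segment vector runs
# joint1 -> joint2; the squat's reference is the dynamic foot(ankle)->knee
# vector; the right body side is evaluated throughout.
EXERCISES: dict[str, ExerciseConfig] = {
    cfg.code: cfg
    for cfg in (
        ExerciseConfig("SF", "sagittal", ("shoulder_r", "elbow_r"), "down", "shoulder_r", "right arm"),
        ExerciseConfig("SA", "frontal", ("shoulder_r", "elbow_r"), "down", "shoulder_r", "right arm"),
        ExerciseConfig("EF", "sagittal", ("elbow_r", "wrist_r"), "down", "elbow_r", "arms (bilateral)"),
        ExerciseConfig("SP", "frontal", ("shoulder_r", "elbow_r"), "down", "shoulder_r", "arms (bilateral)"),
        ExerciseConfig("HA", "frontal", ("hip_r", "knee_r"), "down", "hip_r", "right leg"),
        ExerciseConfig("SQ", "sagittal", ("knee_r", "hip_r"), ("ankle_r", "knee_r"), "knee_r", "legs (bilateral)"),
        ExerciseConfig("MCH", "sagittal", ("hip_r", "knee_r"), "down", "hip_r", "legs (bilateral)"),
        ExerciseConfig("SKF", "sagittal", ("knee_r", "ankle_r"), "down", "knee_r", "right leg"),
    )
}


def get_exercise(code: str) -> ExerciseConfig:
    try:
        return EXERCISES[code.upper()]
    except KeyError:
        raise ConfigError(f"unknown exercise code {code!r}; known: {', '.join(sorted(EXERCISES))}")


def registry_to_yaml() -> str:
    entries = {}
    for code, cfg in EXERCISES.items():
        entries[code] = {
            "plane": cfg.plane,
            "segment_joints": list(cfg.segment_joints),
            "reference": "down" if cfg.reference == "down" else list(cfg.reference),
            "evaluated_joint": cfg.evaluated_joint,
            "moving_limb": cfg.moving_limb,
        }
    return yaml.safe_dump({"exercises": entries}, sort_keys=True)


def registry_from_yaml(text: str) -> dict[str, ExerciseConfig]:
    data = yaml.safe_load(io.StringIO(text))
    out = {}
    for code, e in data["exercises"].items():
        ref = e["reference"]
        out[code] = ExerciseConfig(
            code=code,
            plane=e["plane"],
            segment_joints=tuple(e["segment_joints"]),
            reference=ref if ref == "down" else tuple(ref),
            evaluated_joint=e["evaluated_joint"],
            moving_limb=e.get("moving_limb", ""),
        )
    return out


@dataclass
class AmplitudeSeries:
    """Per-frame joint amplitudes (degrees) at time points (seconds)."""

    times: np.ndarray
    values: np.ndarray
    source: str = "unknown"
    exercise: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValidationError("times and values must be 1-D and equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 180 + 1e-9):
            raise ValidationError("amplitudes must lie in [0, 180] degrees")
        self.times, self.values = t, v

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())


def project_onto_plane(v: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Component of v in the plane with unit normal n: v - (v.n) n."""
    v = np.asarray(v, dtype=float)
    n = np.asarray(n, dtype=float)
    if n.shape != (3,) or abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValidationError("plane normal must be a unit 3-vector")
    return v - np.tensordot(v, n, axes=([-1], [0]))[..., None] * n


def angle_to_reference(v_proj: np.ndarray, ref: np.ndarray) -> float:
    """Unsigned angle in degrees between v_proj and ref, in [0, 180].

    Zero-length inputs yield NaN (a missing sample, not an error); NaN
    inputs raise ValidationError.
    """
    v = np.asarray(v_proj, dtype=float)
    r = np.asarray(ref, dtype=float)
    if np.isnan(v).any() or np.isnan(r).any():
        raise ValidationError("NaN input to angle_to_reference")
    nv, nr = np.linalg.norm(v), np.linalg.norm(r)
    if nv < 1e-12 or nr < 1e-12:
        return float("nan")
    c = float(v @ r) / (nv * nr)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _angles_deg(v: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized unsigned angle (deg) between rows of v and r; NaN where degenerate."""
    nv = np.linalg.norm(v, axis=-1)
    nr = np.linalg.norm(r, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("...i,...i->...", v, r) / (nv * nr)
        c = np.where((nv < 1e-12) | (nr < 1e-12), np.nan, c)
        return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def compute_amplitude_series(
    traj: LandmarkTrajectory,
    cfg: ExerciseConfig,
    source: str = "unknown",
) -> AmplitudeSeries:
    """Amplitude time series for one exercise.

    ``traj`` must already be expressed in the anatomical convention
    (+X sagittal normal, +Y down, +Z anterior) — see
    :func:`romval.anatomical_frame.transform_to_frame`.  Frames with a
    missing required landmark yield NaN values.
    """
    for joint in cfg.required_joints:
        if not traj.skeleton.has_joint(joint):
            raise ConfigError(
                f"exercise {cfg.code}: joint {joint!r} not resolvable in skeleton {traj.skeleton.name!r}"
            )
    j1, j2 = cfg.segment_joints
    seg = traj.joint(j2) - traj.joint(j1)
    if cfg.reference == "down":
        ref = np.broadcast_to(DOWN, seg.shape)
    else:
        rf, rt = cfg.reference
        ref = traj.joint(rt) - traj.joint(rf)
    n = cfg.plane_normal
    seg_p = project_onto_plane(seg, n)
    ref_p = project_onto_plane(ref, n)
    values = _angles_deg(seg_p, ref_p)
    return AmplitudeSeries(times=traj.times, values=values, source=source, exercise=cfg.code)
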