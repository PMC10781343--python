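"""Synthetic paired acquisitions for end-to-end pipeline testing.

A seeded angle profile (raised-cosine repetition pulses with rest periods)
drives a forward-kinematic body template.  The ground-truth stream samples
the profile at the mocap rate in an anatomically aligned global frame
(6-marker skeleton); the predicted stream samples a linearly distorted,
optionally angle-noised profile at the camera rate, poses a 33-landmark
skeleton, rotates it by the camera yaw about the vertical axis, delays it by
an unknown start offset, and adds isotropic landmark position noise.
Amplitude distortion lives in angle space (so linear pred->gt relations are
exactly recoverable) while position noise lives in landmark space (so it
exercises the geometric pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError
from .landmark_io import MEDIAPIPE_33, MOCAP_6, AcquisitionPair, LandmarkTrajectory
from .rom_amplitude import ExerciseConfig

_CANONICAL_JOINTS = (
    "shoulder_l", "shoulder_r", "elbow_l", "elbow_r", "wrist_l", "wrist_r",
    "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r",
)


@dataclass(frozen=True)
class ProtocolSpec:
    """Exercise protocol: sets of repetitions separated by rest."""

    n_sets: int = 2
    reps_per_set: int = 7
    rest_s: float = 10.0
    rep_period_s: float = 3.0
    peak_amplitude_deg: float = 90.0
    per_rep_jitter_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sets < 1 or self.reps_per_set < 1:
            raise ValidationError("counts must be >= 1")
        if self.rest_s <= 0 or self.rep_period_s <= 0:
            raise ValidationError("durations must be positive")
        if not 0 < self.peak_amplitude_deg <= 180:
            raise ValidationError("peak_amplitude_deg must lie in (0, 180]")
        if self.per_rep_jitter_deg < 0:
            raise ValidationError("per_rep_jitter_deg must be >= 0")

    @property
    def n_reps(self) -> int:
        return self.n_sets * self.reps_per_set

    @property
    def duration_s(self) -> float:
        return (
            self.n_sets * self.reps_per_set * self.rep_period_s
            + (self.n_sets - 1) * self.rest_s
        )


@dataclass(frozen=True)
class CameraModel:
    """Predicted-stream acquisition model.

    ``amp_slope``/``amp_intercept_deg`` define the linear map from predicted
    to ground-truth amplitude (gt = slope * pred + intercept); the generator
    inverts it.  ``start_offset_s`` delays the predicted recording start
    relative to the ground-truth stream.
    """

    yaw_deg: float = 0.0
    noise_sigma_m: float = 0.0
    amp_slope: float = 1.0
    amp_intercept_deg: float = 0.0
    start_offset_s: float = 0.0
    fps: float = 30.0
    angle_noise_sigma_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.noise_sigma_m < 0 or self.angle_noise_sigma_deg < 0:
            raise ValidationError("noise levels must be >= 0")
        if self.amp_slope == 0:
            raise ValidationError("amp_slope must be nonzero")
        if self.start_offset_s < 0:
            raise ValidationError("start_offset_s must be >= 0")


@dataclass(frozen=True)
class BodyTemplate:
    """Segment lengths (m) and derived neutral pose; left/right symmetric."""

    torso_width_m: float = 0.35
    hip_width_m: float = 0.30
    torso_height_m: float = 0.50
    upper_arm_m: float = 0.30
    forearm_m: float = 0.27
    thigh_m: float = 0.42
    shank_m: float = 0.40

    def __post_init__(self) -> None:
        for f in (
            self.torso_width_m, self.hip_width_m, self.torso_height_m,
            self.upper_arm_m, self.forearm_m, self.thigh_m, self.shank_m,
        ):
            if f <= 0:
                raise ValidationError("all segment lengths must be positive")

    def scaled(self, factor: float) -> "BodyTemplate":
        return BodyTemplate(*(getattr(self, f) * factor for f in (
            "torso_width_m", "hip_width_m", "torso_height_m",
            "upper_arm_m", "forearm_m", "thigh_m", "shank_m",
        )))

    def neutral_joints(self) -> dict[str, np.ndarray]:
        """Neutral standing pose in the anatomical convention.

        Origin at the hips midpoint; +X subject-right, +Y down, +Z anterior.
        All torso points lie in the z = 0 frontal plane.
        """
        sw, hw = self.torso_width_m / 2, self.hip_width_m / 2
        th = self.torso_height_m
        j = {
            "hip_r": np.array([hw, 0.0, 0.0]),
            "hip_l": np.array([-hw, 0.0, 0.0]),
            "shoulder_r": np.array([sw, -th, 0.0]),
            "shoulder_l": np.array([-sw, -th, 0.0]),
        }
        for side in ("r", "l"):
            j[f"elbow_{side}"] = j[f"shoulder_{side}"] + np.array([0.0, self.upper_arm_m, 0.0])
            j[f"wrist_{side}"] = j[f"elbow_{side}"] + np.array([0.0, self.forearm_m, 0.0])
            j[f"knee_{side}"] = j[f"hip_{side}"] + np.array([0.0, self.thigh_m, 0.0])
            j[f"ankle_{side}"] = j[f"knee_{side}"] + np.array([0.0, self.shank_m, 0.0])
        return j


class AngleProfile:
    """Continuous-time repetition angle profile, evaluable at arbitrary times."""

    def __init__(self, protocol: ProtocolSpec, peak_values: np.ndarray):
        self.protocol = protocol
        self.peak_values = np.asarray(peak_values, dtype=float)
        if len(self.peak_values) != protocol.n_reps:
            raise ValidationError("one peak value per repetition is required")
        starts = []
        for s in range(protocol.n_sets):
            set_start = s * (protocol.reps_per_set * protocol.rep_period_s + protocol.rest_s)
            for r in range(protocol.reps_per_set):
                starts.append(set_start + r * protocol.rep_period_s)
        self.rep_starts = np.asarray(starts)

    @property
    def peak_times(self) -> np.ndarray:
        return self.rep_starts + self.protocol.rep_period_s / 2.0

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        T = self.protocol.rep_period_s
        k = np.searchsorted(self.rep_starts, t, side="right") - 1
        k = np.clip(k, 0, len(self.rep_starts) - 1)
        local = t - self.rep_starts[k]
        active = (local >= 0) & (local <= T)
        phase = np.where(active, local / T, 0.0)
        amp = self.peak_values[k] * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        return np.where(active, amp, 0.0)


def angle_profile(protocol: ProtocolSpec, seed: int) -> AngleProfile:
    """Seeded profile: raised-cosine pulses with per-repetition peak jitter."""
    rng = np.random.default_rng(seed)
    peaks = np.full(protocol.n_reps, protocol.peak_amplitude_deg)
    if protocol.per_rep_jitter_deg > 0:
        peaks = peaks + rng.normal(0.0, protocol.per_rep_jitter_deg, size=protocol.n_reps)
    peaks = np.clip(peaks, 1e-6, 180.0)
    return AngleProfile(protocol, peaks)


def _canonical_pose_sequence(
    template: BodyTemplate, cfg: ExerciseConfig, angles_deg: np.ndarray
) -> dict[str, np.ndarray]:
    """Canonical joint positions (n, 3) realizing each amplitude sample.

    The moving segment is rotated within the configured plane of movement so
    that the downstream amplitude measurement recovers the input angle
    exactly; all other joints stay neutral (the squat translates the torso
    rigidly with the hips).
    """
    th = np.radians(np.asarray(angles_deg, dtype=float))
    n = len(th)
    sin, cos = np.sin(th), np.cos(th)
    zeros = np.zeros(n)
    neutral = template.neutral_joints()
    joints = {name: np.tile(neutral[name], (n, 1)) for name in _CANONICAL_JOINTS}

    def vec(x, y, z):
        return np.stack([np.broadcast_to(x, (n,)), np.broadcast_to(y, (n,)), np.broadcast_to(z, (n,))], axis=1)

    ua, fa = template.upper_arm_m, template.forearm_m
    tl, sh = template.thigh_m, template.shank_m
    code = cfg.code

    if code == "SF":  # arm forward in the sagittal plane
        d = vec(zeros, cos, sin)
        joints["elbow_r"] = joints["shoulder_r"] + ua * d
        joints["wrist_r"] = joints["elbow_r"] + fa * d
    elif code == "SA":  # arm out to the side in the frontal plane
        d = vec(sin, cos, zeros)
        joints["elbow_r"] = joints["shoulder_r"] + ua * d
        joints["wrist_r"] = joints["elbow_r"] + fa * d
    elif code == "EF":  # forearms forward, bilateral
        d = vec(zeros, cos, sin)
        joints["wrist_r"] = joints["elbow_r"] + fa * d
        joints["wrist_l"] = joints["elbow_l"] + fa * d
    elif code == "SP":  # both arms out/up in the frontal plane
        dr = vec(sin, cos, zeros)
        dl = vec(-sin, cos, zeros)
        joints["elbow_r"] = joints["shoulder_r"] + ua * dr
        joints["wrist_r"] = joints["elbow_r"] + fa * dr
        joints["elbow_l"] = joints["shoulder_l"] + ua * dl
        joints["wrist_l"] = joints["elbow_l"] + fa * dl
    elif code == "HA":  # straight right leg abducted in the frontal plane
        d = vec(sin, cos, zeros)
        joints["knee_r"] = joints["hip_r"] + tl * d
        joints["ankle_r"] = joints["knee_r"] + sh * d
    elif code == "SQ":
        # Ankles fixed, shanks vertical; thighs rotate posteriorly about the
        # knees; the torso (and arms) translates rigidly with the hips.
        knee_r = joints["ankle_r"] + sh * vec(zeros, -1.0, zeros)
        hip_r = knee_r + tl * vec(zeros, -cos, -sin)
        delta = hip_r - joints["hip_r"]
        joints["knee_r"] = knee_r
        for name in ("hip_r", "hip_l", "shoulder_r", "shoulder_l",
                     "elbow_r", "elbow_l", "wrist_r", "wrist_l"):
            joints[name] = joints[name] + delta
        lateral = joints["hip_l"] - joints["hip_r"]
        joints["knee_l"] = joints["knee_r"] + lateral
        joints["ankle_l"] = joints["ankle_r"] + lateral
    elif code == "MCH":  # right knee raised forward
        d = vec(zeros, cos, sin)
        joints["knee_r"] = joints["hip_r"] + tl * d
        joints["ankle_r"] = joints["knee_r"] + sh * vec(zeros, 1.0, zeros)
    elif code == "SKF":  # seated: thighs horizontal, right shank swings
        for side in ("r", "l"):
            joints[f"knee_{side}"] = joints[f"hip_{side}"] + tl * vec(zeros, zeros, 1.0)
        joints["ankle_l"] = joints["knee_l"] + sh * vec(zeros, 1.0, zeros)
        joints["ankle_r"] = joints["knee_r"] + sh * vec(zeros, cos, sin)
    else:
        raise ConfigError(f"unknown exercise code {code!r}")
    return joints


def _mediapipe_positions(joints: dict[str, np.ndarray]) -> np.ndarray:
    """Map canonical joints to the full 33-landmark array (n, 33, 3).

    Non-joint landmarks (face, hands, feet) are placed at fixed offsets from
    the nearest canonical joint; they are plumbing only and never measured.
    """
    n = joints["hip_r"].shape[0]
    head = 0.5 * (joints["shoulder_l"] + joints["shoulder_r"]) + np.array([0.0, -0.25, 0.05])
    off = {
        "nose": (head, (0.0, 0.0, 0.05)),
        "left_eye_inner": (head, (-0.015, -0.03, 0.04)),
        "left_eye": (head, (-0.03, -0.03, 0.04)),
        "left_eye_outer": (head, (-0.045, -0.03, 0.04)),
        "right_eye_inner": (head, (0.015, -0.03, 0.04)),
        "right_eye": (head, (0.03, -0.03, 0.04)),
        "right_eye_outer": (head, (0.045, -0.03, 0.04)),
        "left_ear": (head, (-0.07, -0.02, 0.0)),
        "right_ear": (head, (0.07, -0.02, 0.0)),
        "mouth_left": (head, (-0.02, 0.03, 0.04)),
        "mouth_right": (head, (0.02, 0.03, 0.04)),
    }
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        s = side[0]
        wrist = joints[f"wrist_{'l' if s == 'l' else 'r'}"]
        ankle = joints[f"ankle_{'l' if s == 'l' else 'r'}"]
        off[f"{side}_pinky"] = (wrist, (sgn * 0.02, 0.08, 0.0))
        off[f"{side}_index"] = (wrist, (sgn * -0.01, 0.08, 0.02))
        off[f"{side}_thumb"] = (wrist, (sgn * -0.02, 0.05, 0.03))
        off[f"{side}_heel"] = (ankle, (0.0, 0.05, -0.04))
        off[f"{side}_foot_index"] = (ankle, (0.0, 0.07, 0.15))

    canon_map = {
        "left_shoulder": "shoulder_l", "right_shoulder": "shoulder_r",
        "left_elbow": "elbow_l", "right_elbow": "elbow_r",
        "left_wrist": "wrist_l", "right_wrist": "wrist_r",
        "left_hip": "hip_l", "right_hip": "hip_r",
        "left_knee": "knee_l", "right_knee": "knee_r",
        "left_ankle": "ankle_l", "right_ankle": "ankle_r",
    }
    out = np.empty((n, MEDIAPIPE_33.n_landmarks, 3))
    for i, lm in enumerate(MEDIAPIPE_33.landmarks):
        if lm in canon_map:
            out[:, i, :] = joints[canon_map[lm]]
        else:
            base, delta = off[lm]
            out[:, i, :] = base + np.asarray(delta)
    return out


def _mocap_positions(joints: dict[str, np.ndarray]) -> np.ndarray:
    canon = ("shoulder_r", "elbow_r", "wrist_r", "hip_r", "knee_r", "ankle_r")
    return np.stack([joints[c] for c in canon], axis=1)


def pose_sequence(
    template: BodyTemplate, cfg: ExerciseConfig, angles_deg
) -> tuple[np.ndarray, np.ndarray]:
    """(gt (n,6,3), pred (n,33,3)) landmark arrays realizing the amplitudes."""
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if np.any(angles < 0) or np.any(angles > 180):
        raise ValidationError("angles must lie in [0, 180] degrees")
    joints = _canonical_pose_sequence(template, cfg, angles)
    return _mocap_positions(joints), _mediapipe_positions(joints)


def pose_from_angle(
    template: BodyTemplate, cfg: ExerciseConfig, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single-frame pose: ((6,3) marker set, (33,3) predicted skeleton)."""
    gt, pred = pose_sequence(template, cfg, [angle_deg])
    return gt[0], pred[0]


def _yaw_matrix(yaw_deg: float) -> np.ndarray:
    """Rotation about the vertical (shoulders->hips, +Y) axis."""
    c, s = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def render_pair(
    template: BodyTemplate,
    cfg: ExerciseConfig,
    protocol: ProtocolSpec,
    camera: CameraModel,
    seed: int,
    gt_fps: float = 100.0,
    tail_s: float = 1.0,
    subject_id: str = "synthetic",
) -> AcquisitionPair:
    """Render one synthetic acquisition pair.

    The ground-truth stream is sampled at ``gt_fps`` in the anatomical
    convention.  The predicted stream samples the distorted profile
    (gt - intercept)/slope at times shifted by the start offset, clipped to
    [0, 180] (the measurement is unsigned, so a negative distorted angle
    cannot be realized), posed, yawed about the vertical axis, and noised.
    True generator parameters are recorded in ``AcquisitionPair.meta``.
    """
    ss = np.random.SeedSequence(seed)
    seed_profile, seed_angle_noise, seed_pos_noise = ss.spawn(3)
    profile = angle_profile(protocol, seed_profile)
    total = protocol.duration_s + tail_s

    gt_t = np.arange(0.0, total, 1.0 / gt_fps)
    gt_angles = profile(gt_t)
    gt_pos, _ = pose_sequence(template, cfg, gt_angles)
    gt_traj = LandmarkTrajectory(skeleton=MOCAP_6, fps=gt_fps, positions=gt_pos)

    pred_total = total - camera.start_offset_s
    if pred_total <= 0:
        raise ValidationError("start_offset_s exceeds the acquisition duration")
    pred_t = np.arange(0.0, pred_total, 1.0 / camera.fps)
    true_angles = profile(pred_t + camera.start_offset_s)
    pred_angles = (true_angles - camera.amp_intercept_deg) / camera.amp_slope
    if camera.angle_noise_sigma_deg > 0:
        rng = np.random.default_rng(seed_angle_noise)
        pred_angles = pred_angles + rng.normal(0.0, camera.angle_noise_sigma_deg, size=pred_angles.shape)
    pred_angles = np.clip(pred_angles, 0.0, 180.0)
    _, pred_pos = pose_sequence(template, cfg, pred_angles)
    pred_pos = pred_pos @ _yaw_matrix(camera.yaw_deg).T
    if camera.noise_sigma_m > 0:
        rng = np.random.default_rng(seed_pos_noise)
        pred_pos = pred_pos + rng.normal(0.0, camera.noise_sigma_m, size=pred_pos.shape)
    pred_traj = LandmarkTrajectory(skeleton=MEDIAPIPE_33, fps=camera.fps, positions=pred_pos)

    meta = {
        "seed": int(seed),
        "exercise": cfg.code,
        "gt_fps": float(gt_fps),
        "pred_fps": float(camera.fps),
        "start_offset_s": float(camera.start_offset_s),
        "yaw_deg": float(camera.yaw_deg),
        "amp_slope": float(camera.amp_slope),
        "amp_intercept_deg": float(camera.amp_intercept_deg),
        "noise_sigma_m": float(camera.noise_sigma_m),
        "angle_noise_sigma_deg": float(camera.angle_noise_sigma_deg),
        "peak_times_s": profile.peak_times.tolist(),
        "peak_values_deg": profile.peak_values.tolist(),
        "n_repetitions": protocol.n_reps,
    }
    return AcquisitionPair(
        ground_truth=gt_traj, predicted=pred_traj, exercise=cfg.code,
        subject_id=subject_id, meta=meta,
    )
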