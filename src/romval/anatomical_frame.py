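"""Camera-invariant anatomical coordinate frame from torso keypoints.

The frame is right-handed with X the sagittal-plane normal, Y the
transverse-plane normal oriented shoulders -> hips ("down" for an upright
subject), and Z the frontal-plane normal oriented anteriorly.  Z comes from a
consensus (RANSAC-style) plane fit through the four torso keypoints, Y from
the midpoint difference, and X from the right-hand rule (x = y cross z).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import DataError, GeometryError, ValidationError
from .landmark_io import LandmarkTrajectory

_TORSO_JOINTS = ("shoulder_l", "shoulder_r", "hip_l", "hip_r")
_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class PlaneFitParams:
    """Consensus plane-fit parameters (deterministic given random_seed)."""

    residual_threshold: float = 0.01  # meters
    min_samples: int = 3
    max_trials: int = 100
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_threshold <= 0:
            raise ValidationError("residual_threshold must be > 0")
        if self.min_samples < 3:
            raise ValidationError("min_samples must be >= 3")
        if self.max_trials < 1:
            raise ValidationError("max_trials must be >= 1")


@dataclass(frozen=True)
class AnatomicalFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.isfinite(v).all():
                raise ValidationError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        for name in ("x_axis", "y_axis", "z_axis"):
            if abs(np.linalg.norm(getattr(self, name)) - 1.0) > _ORTHO_TOL:
                raise GeometryError(f"{name} is not unit length")
        x, y, z = self.x_axis, self.y_axis, self.z_axis
        for a, b, pair in ((x, y, "x,y"), (x, z, "x,z"), (y, z, "y,z")):
            if abs(float(a @ b)) > _ORTHO_TOL:
                raise GeometryError(f"axes {pair} not orthogonal")
        if np.max(np.abs(np.cross(y, z) - x)) > _ORTHO_TOL:
            raise GeometryError("frame is not right-handed (x != y cross z)")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns (x_axis, y_axis, z_axis)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"cannot normalize near-zero {what}")
    return v / n


def _tls_plane_normal(points: np.ndarray) -> np.ndarray:
    """Total-least-squares plane normal via SVD of the centered points."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= max(s[0], 1e-300) * 1e-9:
        raise GeometryError("points are collinear or coincident; plane undefined")
    return vt[2]


def fit_plane_normal(points, params: PlaneFitParams = PlaneFitParams()) -> np.ndarray:
    """Unit normal of the consensus plane through ``points``.

    Minimal 3-point subsets are enumerated deterministically (seeded
    subsample when there are more than ``max_trials``); each candidate is
    refit by total least squares over its inliers (point-plane distance
    <= residual_threshold).  Candidates are ranked by inlier count of the
    refit plane, ties broken by the smaller mean absolute residual over
    *all* points, which keeps the choice deterministic when every minimal
    subset fits its own points exactly.  If no candidate reaches 3 inliers
    the TLS fit over all points is returned (fallback for near-degenerate
    inputs).  The sign of the returned normal is unresolved.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("points must be an (n, 3) array")
    if pts.shape[0] < 3:
        raise ValidationError("at least 3 points are required to fit a plane")
    if not np.isfinite(pts).all():
        raise ValidationError("points must be finite")
    if params.min_samples > pts.shape[0]:
        raise ValidationError("min_samples exceeds the number of points")

    _ = _tls_plane_normal(pts)  # raises GeometryError on global degeneracy

    n_pts = pts.shape[0]
    all_subsets = list(combinations(range(n_pts), params.min_samples))
    if len(all_subsets) > params.max_trials:
        rng = np.random.default_rng(params.random_seed)
        idx = rng.choice(len(all_subsets), size=params.max_trials, replace=False)
        subsets = [all_subsets[i] for i in sorted(idx)]
    else:
        subsets = all_subsets

    best_key = None
    best_normal = None
    for subset in subsets:
        sub = pts[list(subset)]
        try:
            normal = _tls_plane_normal(sub)
        except GeometryError:
            continue
        dist = np.abs((pts - sub.mean(axis=0)) @ normal)
        inliers = dist <= params.residual_threshold
        if int(inliers.sum()) < 3:
            continue
        try:
            refit = _tls_plane_normal(pts[inliers])
        except GeometryError:
            continue
        refit_dist = np.abs((pts - pts[inliers].mean(axis=0)) @ refit)
        count = int((refit_dist <= params.residual_threshold).sum())
        key = (count, -float(refit_dist.mean()))
        if best_key is None or key > best_key:
            best_key, best_normal = key, refit
    if best_normal is None:
        return _unit(_tls_plane_normal(pts), "plane normal")
    return _unit(np.asarray(best_normal), "plane normal")


def build_anatomical_frame(
    shoulder_l,
    shoulder_r,
    hip_l,
    hip_r,
    params: PlaneFitParams = PlaneFitParams(),
    anterior_hint=(0.0, 0.0, 1.0),
) -> AnatomicalFrame:
    """Construct the anatomical frame from the four torso keypoints.

    Y is the normalized shoulders-midpoint -> hips-midpoint vector and is
    taken as exact; the fitted plane normal is projected orthogonal to Y and
    renormalized to give Z, whose sign is chosen to point along
    ``anterior_hint``; X = Y cross Z.  Origin is the hips midpoint.
    """
    pts = np.asarray([shoulder_l, shoulder_r, hip_l, hip_r], dtype=float)
    if pts.shape != (4, 3) or not np.isfinite(pts).all():
        raise ValidationError("torso keypoints must be four finite 3-vectors")
    shoulder_mid = 0.5 * (pts[0] + pts[1])
    hip_mid = 0.5 * (pts[2] + pts[3])
    if np.linalg.norm(hip_mid - shoulder_mid) < 1e-9:
        raise GeometryError("shoulders midpoint coincides with hips midpoint")
    y = _unit(hip_mid - shoulder_mid, "shoulders->hips vector")

    normal = fit_plane_normal(pts, params)
    z = normal - (normal @ y) * y
    z = _unit(z, "frontal-plane normal after re-orthogonalization")
    hint = np.asarray(anterior_hint, dtype=float)
    if hint.shape != (3,) or not np.isfinite(hint).all():
        raise ValidationError("anterior_hint must be a finite 3-vector")
    if float(z @ hint) < 0:
        z = -z
    x = np.cross(y, z)
    return AnatomicalFrame(origin=hip_mid, x_axis=x, y_axis=y, z_axis=z)


def frame_from_axis_mapping(
    down_axis: str = "+y",
    anterior_axis: str = "+z",
    origin=(0.0, 0.0, 0.0),
) -> AnatomicalFrame:
    """Frame for streams whose global axes are already anatomical.

    ``down_axis``/``anterior_axis`` are signed axis names ("+y", "-z", ...)
    naming which global direction points caudally and anteriorly.  Used for
    mocap exports whose lab axes are assumed parallel to the anatomical
    plane normals, so no plane fit is needed.
    """
    y = _parse_axis(down_axis)
    z = _parse_axis(anterior_axis)
    if abs(float(y @ z)) > _ORTHO_TOL:
        raise ValidationError(f"down_axis {down_axis!r} and anterior_axis {anterior_axis!r} are not orthogonal")
    x = np.cross(y, z)
    return AnatomicalFrame(origin=np.asarray(origin, dtype=float), x_axis=x, y_axis=y, z_axis=z)


def _parse_axis(spec: str) -> np.ndarray:
    s = spec.strip().lower()
    sign = 1.0
    if s and s[0] in "+-":
        sign = -1.0 if s[0] == "-" else 1.0
        s = s[1:]
    try:
        i = "xyz".index(s)
    except ValueError:
        raise ValidationError(f"invalid axis spec {spec!r}; expected one of +x,-x,+y,-y,+z,-z")
    v = np.zeros(3)
    v[i] = sign
    return v


def transform_to_frame(traj: LandmarkTrajectory, frame: AnatomicalFrame) -> LandmarkTrajectory:
    """Express a trajectory in the frame's coordinates.

    Each position p maps to ((p - origin) . x, (p - origin) . y, (p - origin) . z);
    fps, landmark set and missingness are preserved.
    """
    new_pos = (traj.positions - frame.origin) @ frame.rotation
    return LandmarkTrajectory(skeleton=traj.skeleton, fps=traj.fps, positions=new_pos)


def frame_from_first_visible(
    traj: LandmarkTrajectory,
    params: PlaneFitParams = PlaneFitParams(),
    anterior_hint=(0.0, 0.0, 1.0),
) -> AnatomicalFrame:
    """Static anatomical frame from the first frame with a complete torso."""
    for joint in _TORSO_JOINTS:
        if not traj.skeleton.has_joint(joint):
            raise ValidationError(f"skeleton {traj.skeleton.name!r} lacks torso joint {joint!r}")
    torso = np.stack([traj.joint(j) for j in _TORSO_JOINTS], axis=1)  # (n, 4, 3)
    complete = np.isfinite(torso).all(axis=(1, 2))
    idx = np.flatnonzero(complete)
    if idx.size == 0:
        raise DataError("no frame with all four torso landmarks visible")
    f = int(idx[0])
    return build_anatomical_frame(
        torso[f, 0], torso[f, 1], torso[f, 2], torso[f, 3], params=params, anterior_hint=anterior_hint
    )
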