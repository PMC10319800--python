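"""Rigid-body head-pose estimation and posture/movement features.

Converts labeled 3D marker trajectories (four head markers forming a rigid
body plus neck, back and tail-root trunk markers, tracked at 120 Hz) into
the per-frame behavioral covariates used by every downstream stage: head
Euler angles in room (allocentric) and trunk (egocentric) reference frames,
back angles, neck elevation, planar position, body direction, running speed,
self-motion, and the first derivatives of the postural variables.

Conventions
-----------
* Room frame: x/y horizontal, z up; units cm, angles degrees.
* Head frame at neutral pose: x forward (nose), y left, z up.
* Named head angles (pitch, azimuth, roll) use the azimuth-first intrinsic
  Z-Y'-X'' (yaw-pitch-roll) decomposition, so that the allocentric azimuth
  minus the body direction equals the egocentric azimuth by construction.
* Angles are wrapped to (-180, 180]; derivatives are computed on unwrapped
  series and therefore free of +-180 wrap spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "TrackingSession",
    "HeadTemplate",
    "PoseSeries",
    "euler_xyz",
    "compose_euler_xyz",
    "head_angles",
    "compose_head_rotation",
    "fit_head_template",
    "fit_pose_series",
    "compute_features",
    "wrap_degrees",
    "POSTURAL_FEATURES",
    "FEATURE_COLUMNS",
]

#: The nine postural variables whose first derivatives are also covariates.
POSTURAL_FEATURES = (
    "allo_head_pitch", "allo_head_azimuth", "allo_head_roll",
    "ego_head_pitch", "ego_head_azimuth", "ego_head_roll",
    "back_pitch", "back_azimuth", "neck_elevation",
)

#: Full per-frame feature table produced by :func:`compute_features`.
FEATURE_COLUMNS = (
    POSTURAL_FEATURES
    + tuple("d_" + f for f in POSTURAL_FEATURES)
    + ("body_direction", "speed", "position_x", "position_y",
       "self_motion_x", "self_motion_y",
       "ego3_x", "ego3_y", "ego3_z")
)


@dataclass
class TrackingSession:
    """Timestamped 3D marker data for one recording session.

    head : (T, 4, 3) array, cm. trunk : (T, 3, 3) array, cm, ordered
    (neck, back, tail_root). Missing markers are NaN.
    """

    t: np.ndarray
    head: np.ndarray
    trunk: np.ndarray
    fps: float = 120.0
    condition: str = "light1"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.head = np.asarray(self.head, dtype=float)
        self.trunk = np.asarray(self.trunk, dtype=float)
        if self.head.shape != (self.t.size, 4, 3):
            raise ValueError("head must have shape (T, 4, 3)")
        if self.trunk.shape != (self.t.size, 3, 3):
            raise ValueError("trunk must have shape (T, 3, 3)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self):
        return self.t.size

    @property
    def duration(self):
        return self.n_frames / self.fps

    @property
    def neck(self):
        return self.trunk[:, 0]

    @property
    def back(self):
        return self.trunk[:, 1]

    @property
    def tail_root(self):
        return self.trunk[:, 2]


@dataclass
class HeadTemplate:
    points: np.ndarray          # (4, 3), centered at the centroid
    frame_index: int            # frame the template was taken from

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class PoseSeries:
    """Per-frame rigid transform of the (re-based, re-axed) head template."""

    rotations: np.ndarray       # (T, 3, 3)
    origins: np.ndarray         # (T, 3) head-origin position in the room, cm
    valid: np.ndarray           # (T,) bool
    gimbal_flags: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# angle utilities

def wrap_degrees(a):
    """Wrap angles (degrees) to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return w


def compose_euler_xyz(theta_x, theta_y, theta_z, degrees=True):
    """Rotation matrix from intrinsic X-Y-Z Euler angles."""
    return Rotation.from_euler(
        "XYZ", [theta_x, theta_y, theta_z], degrees=degrees
    ).as_matrix()


def euler_xyz(rotation, degrees=True):
    """Intrinsic X-Y-Z Euler decomposition of a proper rotation.

    Returns ``(theta_x, theta_y, theta_z, gimbal)``; near gimbal lock
    (|theta_y| within ~1e-6 deg of 90) the third angle is set to 0 and the
    flag is True. Composing the three angles reproduces the input to 1e-9.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
        raise ValueError("input must be a proper rotation matrix (det=+1)")
    # R = Rx(a) Ry(b) Rz(c):  R[0,2]=sin b ; R[0,0]=cos b cos c ; R[0,1]=-cos b sin c
    sb = np.clip(R[0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    if 1.0 - abs(sb) < 1e-12:
        # gimbal lock: only a+-c determined; convention c=0
        a = np.arctan2(R[1, 0], R[1, 1]) if sb > 0 else np.arctan2(-R[1, 0], R[1, 1])
        c = 0.0
        gimbal = True
    else:
        a = np.arctan2(-R[1, 2], R[2, 2])
        c = np.arctan2(-R[0, 1], R[0, 0])
        gimbal = False
    ang = np.array([a, b, c])
    if degrees:
        ang = np.degrees(ang)
    return ang[0], ang[1], ang[2], gimbal


def compose_head_rotation(pitch, azimuth, roll, degrees=True):
    """Head rotation from named angles: R = Rz(azimuth) Ry(pitch) Rx(roll).

    Positive pitch tips the nose down (right-hand rotation about +y = left);
    positive azimuth turns the nose left; positive roll tips the right ear
    down. The azimuth factor acts in the room frame, so a change of heading
    adds to azimuth and leaves pitch/roll untouched.
    """
    return Rotation.from_euler(
        "ZYX", [azimuth, pitch, roll], degrees=degrees
    ).as_matrix()


def head_angles(rotation, degrees=True):
    """Named head angles (pitch, azimuth, roll) of a rotation matrix.

    Inverse of :func:`compose_head_rotation` (intrinsic Z-Y'-X'').
    """
    az, pitch, roll = Rotation.from_matrix(rotation).as_euler(
        "ZYX", degrees=degrees
    )
    return pitch, az, roll


# ---------------------------------------------------------------------------
# template and pose fitting

def _pairwise_distances(points):
    d = points[..., :, None, :] - points[..., None, :, :]
    return np.linalg.norm(d, axis=-1)


def fit_head_template(head, min_frames=100):
    """Estimate the rigid-body template of the four head markers.

    The per-frame pairwise-distance matrices are averaged; the template is
    the frame whose distances are closest (least squares) to that average.
    The template is returned centered at the centroid of its four points.
    """
    head = np.asarray(head, dtype=float)
    valid = np.all(np.isfinite(head), axis=(1, 2))
    if valid.sum() < min_frames:
        raise ValueError(
            f"need >= {min_frames} frames with all 4 head markers visible"
        )
    idx = np.flatnonzero(valid)
    dists = _pairwise_distances(head[idx])
    iu = np.triu_indices(4, k=1)
    flat = dists[:, iu[0], iu[1]]
    mean_d = flat.mean(axis=0)
    err = np.sum((flat - mean_d) ** 2, axis=1)
    best = idx[int(np.argmin(err))]
    pts = head[best]
    return HeadTemplate(points=pts - pts.mean(axis=0), frame_index=int(best))


def _kabsch(template, target):
    """Least-squares rigid transform: target ~ R @ template + t."""
    ct = template.mean(axis=0)
    cg = target.mean(axis=0)
    H = (template - ct).T @ (target - cg)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cg - R @ ct
    return R, t


def _planar_speed(xy, fps, radius_s=0.25):
    """Running speed (cm/s) from a planar trajectory, window radius 250 ms."""
    w = max(1, int(round(radius_s * fps)))
    T = xy.shape[0]
    speed = np.full(T, np.nan)
    if T > 2 * w:
        disp = np.linalg.norm(xy[2 * w:] - xy[:-2 * w], axis=1)
        speed[w:T - w] = disp / (2 * w / fps)
    return speed


def fit_pose_series(session, template, *, origin_stencil=20,
                    run_stencil=50, run_speed_min=10.0):
    """Per-frame rigid transform of the head template, re-based and re-axed.

    Three steps, each a closed-form least-squares fit:

    1. Kabsch alignment of the template to the four markers at every frame.
    2. Origin re-basing: the point of the head coordinate system (in
       template coordinates) whose room trajectory minimizes the summed
       squared distance between its position ``origin_stencil`` frames
       before and after each frame — an estimate of the head's rotation
       axis (base of the head).
    3. Axis alignment: a fixed rotation of the template coordinate system
       chosen so the head z axis matches the room vertical and the head x
       axis matches the running direction (horizontal displacement of the
       origin over +-``run_stencil`` frames, on frames faster than
       ``run_speed_min`` cm/s), the two objectives combined as one
       orthogonal-Procrustes fit.
    """
    head = session.head
    T = session.n_frames
    tpl = template.points
    # degenerate (near-coplanar) templates still fit but warn via flag
    if np.linalg.svd(tpl, compute_uv=False)[-1] < 1e-8:
        import warnings
        warnings.warn("head template is near-coplanar; pose may be ill-conditioned")

    Rs = np.full((T, 3, 3), np.nan)
    Ts = np.full((T, 3), np.nan)
    valid = np.all(np.isfinite(head), axis=(1, 2))
    for i in np.flatnonzero(valid):
        Rs[i], Ts[i] = _kabsch(tpl, head[i])

    # --- origin re-basing -------------------------------------------------
    s = origin_stencil
    ok = valid[:-2 * s] & valid[2 * s:] if T > 2 * s else np.zeros(0, bool)
    if ok.sum() >= 10:
        A = Rs[:-2 * s][ok] - Rs[2 * s:][ok]            # (n, 3, 3)
        b = Ts[2 * s:][ok] - Ts[:-2 * s][ok]            # (n, 3)
        AtA = np.einsum("nij,nik->jk", A, A)
        Atb = np.einsum("nij,ni->j", A, b)
        d = np.linalg.lstsq(AtA + 1e-9 * np.eye(3), Atb, rcond=None)[0]
    else:
        d = np.zeros(3)
    origins = np.einsum("tij,j->ti", Rs, d) + Ts

    # --- axis alignment (anchored on frames faster than run_speed_min) ----
    ez = np.array([0.0, 0.0, 1.0])
    r = run_stencil
    run_sel = np.zeros(T, dtype=bool)
    disp = None
    if T > 2 * r:
        speed = _planar_speed(origins[:, :2], session.fps)
        disp = origins[2 * r:, :2] - origins[:-2 * r, :2]
        fast = np.isfinite(speed) & (speed > run_speed_min)
        # sustained locomotion only: erode the mask so regime-transition
        # frames (speed crossing the gate mid pose swing) drop out
        from scipy.ndimage import binary_erosion
        fast = binary_erosion(fast, np.ones(int(round(0.8 * session.fps))))
        mid_ok = valid[:-2 * r] & valid[2 * r:] & fast[r:T - r]
        run_sel[r:T - r] = mid_ok
    anchor = run_sel if run_sel.sum() >= 10 else valid
    vert = np.einsum("tji,j->ti", Rs[anchor], ez)
    # component-wise median: robust to the brief regime-transition frames
    # that pass the speed gate with the head still mid-swing
    targets = [np.median(vert, axis=0)]
    sources = [ez]
    if run_sel.sum() >= 10 and disp is not None:
        mid_ok = run_sel[r:T - r]
        run = np.zeros((mid_ok.sum(), 3))
        run[:, :2] = disp[mid_ok] / np.linalg.norm(disp[mid_ok], axis=1, keepdims=True)
        run_head = np.einsum("tji,tj->ti", Rs[r:T - r][mid_ok], run)
        targets.append(np.median(run_head, axis=0))
        sources.append(np.array([1.0, 0.0, 0.0]))
    Q, _ = Rotation.align_vectors(np.array(targets), np.array(sources))
    Qm = Q.as_matrix()     # align_vectors gives targets ~ Q @ sources
    Rs_aligned = np.einsum("tij,jk->tik", Rs, Qm)

    gimbal = np.zeros(T, dtype=bool)
    return PoseSeries(rotations=Rs_aligned, origins=origins, valid=valid,
                      gimbal_flags=gimbal)


# ---------------------------------------------------------------------------
# feature extraction

def _interpolate_short_gaps(x, max_gap=5):
    """Linearly fill NaN runs of length <= max_gap (per column)."""
    x = np.array(x, dtype=float)
    flat = x.reshape(x.shape[0], -1)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        isn = np.isnan(col)
        if not isn.any() or isn.all():
            continue
        runs = np.flatnonzero(np.diff(np.concatenate(([0], isn.view(np.int8), [0]))))
        for a, b in zip(runs[::2], runs[1::2]):
            if b - a <= max_gap and a > 0 and b < col.size:
                col[a:b] = np.interp(np.arange(a, b), [a - 1, b], [col[a - 1], col[b]])
        flat[:, j] = col
    return x


def _central_diff(series, offset, fps):
    """Central difference with +-offset frames; NaN at the edges."""
    out = np.full(series.shape, np.nan)
    if series.size > 2 * offset:
        out[offset:-offset] = (series[2 * offset:] - series[:-2 * offset]) * fps / (2 * offset)
    return out


def _unwrap_deg(a):
    out = np.array(a, dtype=float)
    fin = np.isfinite(out)
    out[fin] = np.degrees(np.unwrap(np.radians(out[fin])))
    return out


def _circular_mean_deg(a):
    a = a[np.isfinite(a)]
    if a.size == 0:
        return 0.0
    rad = np.radians(a)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def compute_features(session, poses, *, deriv_offset=10, selfmotion_offset=15,
                     center_back=True):
    """Build the per-frame posture/movement covariate table.

    Returns a DataFrame with :data:`FEATURE_COLUMNS`, one row per 120 Hz
    frame. Frames where a stencil leaves the session or a marker is missing
    are NaN (no extrapolation). With fps != 120 the derivative and
    self-motion stencils rescale proportionally.
    """
    fps = session.fps
    if fps != 120.0:
        import warnings
        scale = fps / 120.0
        deriv_offset = max(1, int(round(deriv_offset * scale)))
        selfmotion_offset = max(1, int(round(selfmotion_offset * scale)))
        warnings.warn("fps != 120; derivative stencils rescaled proportionally")
    T = session.n_frames
    if T < 4 * deriv_offset + 1:
        raise ValueError("session too short for the derivative stencils")

    trunk = _interpolate_short_gaps(session.trunk)
    neck, back, tail = trunk[:, 0], trunk[:, 1], trunk[:, 2]

    out = pd.DataFrame(index=np.arange(T), columns=list(FEATURE_COLUMNS),
                       dtype=float)

    # body direction: horizontal angle of the tail-root -> neck vector
    bvec = neck - tail
    body_dir = np.degrees(np.arctan2(bvec[:, 1], bvec[:, 0]))
    out["body_direction"] = wrap_degrees(body_dir)

    # allocentric and egocentric head angles
    pitch = np.full(T, np.nan)
    azim = np.full(T, np.nan)
    roll = np.full(T, np.nan)
    epitch = np.full(T, np.nan)
    eazim = np.full(T, np.nan)
    eroll = np.full(T, np.nan)
    ego3 = np.full((T, 3), np.nan)
    # egocentric frame: yaw from the horizontal body direction, pitch from
    # the elevation of the 3D tail-root -> neck vector (the trunk axis)
    body_elev = np.degrees(np.arctan2(bvec[:, 2], np.linalg.norm(bvec[:, :2], axis=1)))
    ok = poses.valid & np.isfinite(body_dir)
    Rb = Rotation.from_euler(
        "ZY", np.stack([body_dir[ok], -body_elev[ok]], axis=1), degrees=True
    ).as_matrix()
    R_ego = np.einsum("tji,tjk->tik", Rb, poses.rotations[ok])
    rot_allo = Rotation.from_matrix(poses.rotations[ok])
    rot_ego = Rotation.from_matrix(R_ego)
    az_a, pi_a, ro_a = rot_allo.as_euler("ZYX", degrees=True).T
    az_e, pi_e, ro_e = rot_ego.as_euler("ZYX", degrees=True).T
    pitch[ok], azim[ok], roll[ok] = pi_a, az_a, ro_a
    epitch[ok], eazim[ok], eroll[ok] = pi_e, az_e, ro_e
    ego3[ok] = rot_ego.as_rotvec(degrees=True)  # exponential-map alternative

    out["allo_head_pitch"] = pitch
    out["allo_head_azimuth"] = azim
    out["allo_head_roll"] = roll
    out["ego_head_pitch"] = epitch
    out["ego_head_azimuth"] = eazim
    out["ego_head_roll"] = eroll
    out[["ego3_x", "ego3_y", "ego3_z"]] = ego3

    # back angles from the back-marker -> neck segment, re-centered so the
    # session's average occupancy peak sits near zero
    seg = neck - back
    horiz = np.linalg.norm(seg[:, :2], axis=1)
    back_pitch = np.degrees(np.arctan2(seg[:, 2], horiz))
    back_azim = wrap_degrees(np.degrees(np.arctan2(seg[:, 1], seg[:, 0])) - body_dir)
    if center_back:
        back_pitch = back_pitch - _circular_mean_deg(back_pitch)
        back_azim = wrap_degrees(back_azim - _circular_mean_deg(back_azim))
    out["back_pitch"] = back_pitch
    out["back_azimuth"] = back_azim

    # neck elevation above the floor (5th percentile of neck z)
    floor = np.nanpercentile(neck[:, 2], 5)
    out["neck_elevation"] = neck[:, 2] - floor

    # planar position and speed from the neck point
    out["position_x"] = neck[:, 0]
    out["position_y"] = neck[:, 1]
    speed = _planar_speed(neck[:, :2], fps)
    out["speed"] = speed

    # self-motion: speed times the unit vector of the body-direction change
    phi = _unwrap_deg(body_dir)
    o = selfmotion_offset
    dphi = np.full(T, np.nan)
    dphi[o:T - o] = phi[2 * o:] - phi[:-2 * o]
    out["self_motion_x"] = speed * np.cos(np.radians(dphi))
    out["self_motion_y"] = speed * np.sin(np.radians(dphi))

    # first derivatives of the nine postural variables (unwrapped angles)
    for name in POSTURAL_FEATURES:
        series = out[name].to_numpy()
        if name != "neck_elevation":
            series = _unwrap_deg(series)
        out["d_" + name] = _central_diff(series, deriv_offset, fps)

    for name in POSTURAL_FEATURES[:-1]:
        out[name] = wrap_degrees(out[name].to_numpy())
    return out
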