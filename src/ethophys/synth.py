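"""Synthetic freely-moving-rodent sessions with known ground truth.

Generates the three input streams the analysis stack consumes — 3D marker
tracking (a four-marker rigid head body plus three trunk markers at 120 Hz),
spike trains driven by a Bernoulli GLM on the extracted posture covariates,
and white-noise stimulus event trains — together with the ground truth
(scripted behavioral regimes, generating tuning parameters, injected
synaptic couplings) that the downstream recovery tests score against.

Behavior is built from a small mechanistic repertoire rather than recorded
data: the trunk follows a smooth confined planar random walk, the head sits
on a rigid marker frame whose Euler angles relax toward piecewise-constant
regime targets through a critically damped second-order filter with
Ornstein-Uhlenbeck jitter on top. That produces smooth pose time series
with watershed-separable behavioral regimes without hand tuning.

All randomness flows from a single integer seed; per-unit substreams are
derived deterministically so outputs are bit-identical across runs and
stable under unit reordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import TrackingSession, compose_head_rotation, wrap_degrees

__all__ = [
    "TuningSpec",
    "CouplingSpec",
    "SynthConfig",
    "GroundTruth",
    "SpikeData",
    "EventTrain",
    "gen_tracking",
    "gen_spikes_from_glm",
    "gen_coupled_pair",
    "gen_stimulus_session",
    "two_regime_script",
    "default_regime_script",
    "make_session",
]

#: local head-marker geometry (cm): x forward, y left, z up; non-coplanar
HEAD_MARKER_LOCAL = np.array([
    [2.5, 0.0, 1.0],
    [-1.5, 1.8, 0.5],
    [-1.5, -1.8, 0.5],
    [0.0, 0.0, 2.8],
])

BODY_LENGTH_CM = 20.0


@dataclass
class TuningSpec:
    """Ground-truth tuning of one unit to one behavioral covariate.

    The unit's Bernoulli log-odds get a Gaussian bump
    ``gain * exp(-d(x, center)^2 / (2 width^2))`` in covariate ``name``;
    angular covariates use wrapped distance.
    """

    unit: int
    covariate: str
    center: float
    width: float
    gain: float
    circular: bool = False


@dataclass
class CouplingSpec:
    pre: int
    post: int
    lag_ms: float
    transmission_prob: float
    sign: str = "exc"   # "exc" or "inh"

    def __post_init__(self):
        if not 0 < self.lag_ms <= 4:
            raise ValueError("lag_ms must lie in (0, 4] ms")
        if not 0 <= self.transmission_prob <= 1:
            raise ValueError("transmission_prob must lie in [0, 1]")
        if self.sign not in ("exc", "inh"):
            raise ValueError("sign must be 'exc' or 'inh'")


@dataclass
class SynthConfig:
    duration_s: float = 1200.0
    fps: float = 120.0
    n_units: int = 20
    seed: int = 0
    arena_cm: float = 100.0          # square half-width
    base_rate_hz: float = 5.0
    marker_jitter_cm: float = 0.05
    fs_fraction: float = 0.2
    tuning_specs: list = field(default_factory=list)
    coupling_specs: list = field(default_factory=list)
    event_duration_s: float = 5.0
    event_min_isi_s: float = 10.0
    condition: str = "light1"

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery scoring."""

    regime: np.ndarray = None            # per-frame regime index
    regime_names: list = None
    scripted: dict = field(default_factory=dict)   # per-frame scripted series
    tuning_specs: list = field(default_factory=list)
    connections: list = field(default_factory=list)
    rs_fs: np.ndarray = None


@dataclass
class SpikeData:
    """Per-unit spike-time lists plus the unit metadata table."""

    spike_times: list                    # list of float arrays (seconds)
    metadata: pd.DataFrame
    duration_s: float

    @property
    def n_units(self):
        return len(self.spike_times)


@dataclass
class EventTrain:
    onsets: np.ndarray                   # seconds
    duration_s: float                    # per-event duration
    session_duration_s: float


def _unit_rng(seed, unit):
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(unit)]))


# ---------------------------------------------------------------------------
# regime scripts

def default_regime_script():
    """Foraging-like repertoire: level running (which anchors the room/running
    axis alignment downstream) interleaved with slower head-down search,
    rearing and lateral scanning bouts, for broad covariate coverage."""
    return {
        "regimes": [
            ("run_level", dict(speed=20.0, pitch=0.0, neck=8.0, roll=0.0)),
            ("search_head_down", dict(speed=6.0, pitch=-40.0, neck=5.0, roll=0.0)),
            ("rear", dict(speed=1.0, pitch=35.0, neck=14.0, roll=0.0)),
            ("scan_left", dict(speed=3.0, pitch=-10.0, neck=7.0, roll=25.0)),
            ("scan_right", dict(speed=3.0, pitch=-10.0, neck=7.0, roll=-25.0)),
        ],
        "mean_bout_s": 4.0,
    }


def two_regime_script(mean_bout_s=20.0, bout_range_s=(10.0, 40.0)):
    """Two well-separated scripted regimes for ethogram recovery tests.

    Bouts are long relative to the ~1 s regime-transition blur of the
    2 s-knot spline detrending, so per-frame ground truth is clean."""
    return {
        "regimes": [
            ("still_head_down", dict(speed=0.0, pitch=-45.0, neck=4.0, roll=0.0)),
            ("run_head_level", dict(speed=25.0, pitch=0.0, neck=9.0, roll=0.0)),
        ],
        "mean_bout_s": mean_bout_s,
        "bout_range_s": bout_range_s,
    }


def _sample_regime_sequence(rng, n_frames, fps, n_regimes, mean_bout_s,
                            bout_range_s=(2.0, 10.0)):
    """Alternating regime bouts with clipped exponential durations."""
    labels = np.zeros(n_frames, dtype=int)
    if n_regimes == 1:
        return labels
    t = 0
    current = int(rng.integers(n_regimes))
    while t < n_frames:
        dur = float(np.clip(rng.exponential(mean_bout_s), *bout_range_s))
        n = max(1, int(round(dur * fps)))
        labels[t:t + n] = current
        t += n
        nxt = int(rng.integers(n_regimes - 1))
        current = nxt if nxt < current else nxt + 1
    return labels


def _critically_damped(target, fps, omega=4.0, x0=None):
    """Second-order critically damped tracking of a target series."""
    dt = 1.0 / fps
    x = np.empty_like(target)
    v = 0.0
    x[0] = target[0] if x0 is None else x0
    for i in range(1, target.size):
        a = omega * omega * (target[i] - x[i - 1]) - 2.0 * omega * v
        v = v + a * dt
        x[i] = x[i - 1] + v * dt
    return x


def _ou(rng, n, fps, tau_s, sigma):
    """Ornstein-Uhlenbeck noise around zero."""
    dt = 1.0 / fps
    a = np.exp(-dt / tau_s)
    b = sigma * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = sigma * eps[0]
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * eps[i]
    return x


# ---------------------------------------------------------------------------
# tracking

def gen_tracking(config, script=None):
    """Generate a marker-tracking session; returns (TrackingSession, GroundTruth).

    Head markers move as a rigid body about a base point above the neck;
    trunk markers follow a smooth planar random walk confined to the arena.
    With a multi-regime ``script`` the pose targets switch between bouts and
    the per-frame regime index is recorded in the ground truth.
    """
    if config.duration_s <= 0 or config.fps <= 0:
        raise ValueError("invalid config: non-positive duration or fps")
    fps = config.fps
    n = int(round(config.duration_s * fps))
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 977]))
    script = script or default_regime_script()
    regimes = script["regimes"]
    labels = _sample_regime_sequence(rng, n, fps, len(regimes),
                                     script["mean_bout_s"],
                                     script.get("bout_range_s", (2.0, 10.0)))

    def target(key):
        vals = np.array([r[1][key] for r in regimes])
        return vals[labels]

    dt = 1.0 / fps
    # --- trunk ------------------------------------------------------------
    speed = np.clip(_critically_damped(target("speed"), fps, omega=1.5)
                    + _ou(rng, n, fps, 1.0, 1.5), 0.0, None)
    heading = np.empty(n)
    heading[0] = rng.uniform(-np.pi, np.pi)
    pos = np.empty((n, 2))
    pos[0] = rng.uniform(-0.3, 0.3, 2) * config.arena_cm
    turn_noise = rng.standard_normal(n) * 0.5 * np.sqrt(dt)
    half = config.arena_cm
    for i in range(1, n):
        # steer back toward the center when close to the wall
        r = np.linalg.norm(pos[i - 1])
        steer = 0.0
        if r > 0.75 * half:
            to_center = np.arctan2(-pos[i - 1, 1], -pos[i - 1, 0])
            dh = np.angle(np.exp(1j * (to_center - heading[i - 1])))
            steer = 4.0 * (r / half - 0.75) * dh
        heading[i] = heading[i - 1] + turn_noise[i] + steer * dt * 10.0
        step = speed[i] * dt
        pos[i] = pos[i - 1] + step * np.array([np.cos(heading[i]),
                                               np.sin(heading[i])])
        pos[i] = np.clip(pos[i], -half, half)

    body_dir = np.degrees(heading)
    neck_z = np.clip(_critically_damped(target("neck"), fps, omega=3.0)
                     + _ou(rng, n, fps, 0.8, 0.3), 2.0, None)
    dirv = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    neck = np.concatenate([pos + 0.5 * BODY_LENGTH_CM * dirv,
                           neck_z[:, None]], axis=1)
    tail = np.concatenate([pos - 0.5 * BODY_LENGTH_CM * dirv,
                           np.full((n, 1), 3.0)], axis=1)
    # spine flexion: the upper-back marker swings laterally (bend) and
    # arches vertically relative to the trunk axis
    bend = np.radians(_ou(rng, n, fps, 0.8, 8.0))
    arch = 1.5 + _ou(rng, n, fps, 1.0, 0.8)
    seg_dir = np.stack([np.cos(heading + bend), np.sin(heading + bend)], axis=1)
    back_xy = neck[:, :2] - 0.4 * BODY_LENGTH_CM * seg_dir
    back_z = 0.5 * (neck_z + 3.0) + arch
    back = np.concatenate([back_xy, back_z[:, None]], axis=1)
    trunk = np.stack([neck, back, tail], axis=1)
    trunk = trunk + rng.normal(0.0, config.marker_jitter_cm, trunk.shape)

    # --- head -------------------------------------------------------------
    pitch = (_critically_damped(target("pitch"), fps, omega=8.0)
             + _ou(rng, n, fps, 0.7, 3.0))
    roll = _critically_damped(target("roll"), fps, omega=8.0) + _ou(rng, n, fps, 0.7, 3.0)
    ego_azim = _ou(rng, n, fps, 1.2, 12.0)
    azim = wrap_degrees(body_dir + ego_azim)

    base = neck + np.concatenate([1.5 * dirv, np.full((n, 1), 2.0)], axis=1)
    from scipy.spatial.transform import Rotation
    R = Rotation.from_euler(
        "ZYX", np.stack([azim, pitch, roll], axis=1), degrees=True
    ).as_matrix()
    head = base[:, None, :] + np.einsum("tij,mj->tmi", R, HEAD_MARKER_LOCAL)
    head += rng.normal(0.0, config.marker_jitter_cm, head.shape)

    t = np.arange(n) / fps
    session = TrackingSession(t=t, head=head, trunk=trunk, fps=fps,
                              condition=config.condition)
    truth = GroundTruth(
        regime=labels,
        regime_names=[r[0] for r in regimes],
        scripted={
            "allo_head_pitch": pitch,
            "allo_head_azimuth": azim,
            "allo_head_roll": roll,
            "ego_head_azimuth": wrap_degrees(ego_azim),
            "body_direction": wrap_degrees(body_dir),
            "speed": speed,
            "neck_elevation": neck_z,
            "back_bend_deg": np.degrees(bend),
        },
        tuning_specs=list(config.tuning_specs),
    )
    return session, truth


# ---------------------------------------------------------------------------
# spikes

def _logit(p):
    return np.log(p / (1.0 - p))


def tuning_logodds(features, spec):
    """Gaussian log-odds bump of one TuningSpec over a feature table."""
    if spec.covariate not in features.columns:
        raise KeyError(f"unknown covariate {spec.covariate!r} in tuning spec")
    x = features[spec.covariate].to_numpy(dtype=float)
    d = x - spec.center
    if spec.circular:
        d = wrap_degrees(d)
    return spec.gain * np.exp(-0.5 * (d / spec.width) ** 2)


def gen_spikes_from_glm(features, config, *, fps=None):
    """Bernoulli-GLM-driven spike trains over a posture-feature table.

    Each unit spikes per frame with probability ``sigmoid(b0 + sum of its
    tuning bumps)``; b0 is set so an untuned unit fires at
    ``config.base_rate_hz``. Spike times land uniformly within the frame.
    Unit metadata includes waveform features drawn from two separated
    clusters (RS-like broad and FS-like narrow) and 3D anatomical positions.
    """
    fps = fps or config.fps
    n = len(features)
    b0 = _logit(np.clip(config.base_rate_hz / fps, 1e-6, 0.5))
    specs_by_unit = {}
    for spec in config.tuning_specs:
        specs_by_unit.setdefault(spec.unit, []).append(spec)

    valid = ~features[[c for c in features.columns]].isna().any(axis=1).to_numpy()
    spike_times = []
    for u in range(config.n_units):
        rng = _unit_rng(config.seed, u)
        eta = np.full(n, b0)
        for spec in specs_by_unit.get(u, ()):
            bump = tuning_logodds(features, spec)
            eta = eta + np.where(np.isfinite(bump), bump, 0.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        p[~valid] = np.clip(config.base_rate_hz / fps, 1e-6, 0.5)
        fires = rng.random(n) < p
        idx = np.flatnonzero(fires)
        times = (idx + rng.random(idx.size)) / fps
        spike_times.append(np.sort(times))

    meta = _unit_metadata(config)
    return SpikeData(spike_times=spike_times, metadata=meta,
                     duration_s=n / fps)


def _unit_metadata(config):
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4242]))
    n = config.n_units
    is_fs = rng.random(n) < config.fs_fraction
    # two separated waveform clusters (ms / ratio / ms / a.u.)
    width = np.where(is_fs, rng.normal(0.20, 0.02, n), rng.normal(0.45, 0.03, n))
    ptr = np.where(is_fs, rng.normal(1.4, 0.15, n), rng.normal(2.6, 0.3, n))
    fwhm = np.where(is_fs, rng.normal(0.12, 0.015, n), rng.normal(0.30, 0.03, n))
    slope = np.where(is_fs, rng.normal(-0.55, 0.08, n), rng.normal(-0.20, 0.05, n))
    meta = pd.DataFrame({
        "unit_id": np.arange(n),
        "channel": rng.integers(0, 384, n),
        "ap_mm": rng.uniform(-6.5, -3.5, n),
        "ml_mm": rng.uniform(1.9, 2.7, n),
        "dv_mm": rng.uniform(0.3, 2.0, n),
        "region": rng.choice(["V1", "V2L", "A1", "A2D"], n),
        "spike_width_ms": width,
        "peak_to_trough_ratio": ptr,
        "fwhm_ms": fwhm,
        "end_slope": slope,
        "true_type": np.where(is_fs, "FS", "RS"),
    })
    return meta


# ---------------------------------------------------------------------------
# coupled pairs and stimulus trains

def gen_coupled_pair(base_rate_hz, lag_ms, p_trans, sign, duration_s, seed,
                     *, post_rate_hz=None, jitter_ms=0.2):
    """Poisson pre train plus a synaptically coupled post train.

    exc: each pre spike adds a post spike at ``lag_ms`` (Gaussian-jittered,
    sd ``jitter_ms``) with probability ``p_trans``, on top of an independent
    Poisson floor. inh: post spikes within +-0.8 ms of pre+lag are deleted
    with probability ``p_trans``.
    """
    if base_rate_hz < 0 or (post_rate_hz is not None and post_rate_hz < 0):
        raise ValueError("rates must be non-negative")
    if not 0 < lag_ms <= 4:
        raise ValueError("lag_ms must lie in (0, 4] ms")
    if not 0 <= p_trans <= 1:
        raise ValueError("p_trans must lie in [0, 1]")
    if sign not in ("exc", "inh"):
        raise ValueError("sign must be 'exc' or 'inh'")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31337]))
    post_rate_hz = base_rate_hz if post_rate_hz is None else post_rate_hz

    def poisson_train(rate):
        n = rng.poisson(rate * duration_s)
        return np.sort(rng.uniform(0.0, duration_s, n))

    pre = poisson_train(base_rate_hz)
    post = poisson_train(post_rate_hz)
    lag = lag_ms * 1e-3
    if sign == "exc":
        transmit = rng.random(pre.size) < p_trans
        extra = pre[transmit] + lag + rng.normal(0.0, jitter_ms * 1e-3,
                                                 transmit.sum())
        post = np.sort(np.concatenate([post, extra]))
        post = post[(post >= 0) & (post < duration_s)]
    else:
        keep = np.ones(post.size, dtype=bool)
        window = 0.8e-3
        lo = np.searchsorted(post, pre + lag - window)
        hi = np.searchsorted(post, pre + lag + window)
        for a, b in zip(lo, hi):
            if b > a:
                keep[a:b] &= rng.random(b - a) >= p_trans
        post = post[keep]
    return pre, post


def gen_stimulus_session(config=None, *, duration_s=None, seed=0,
                         event_duration_s=5.0, min_isi_s=10.0):
    """Stimulus onsets with >``min_isi_s`` gaps between events.

    Gap between consecutive onsets is event duration + min ISI + an
    exponential excess (mean 5 s), so events never overlap and all
    inter-stimulus intervals exceed the floor.
    """
    if config is not None:
        duration_s = config.duration_s
        seed = config.seed
        event_duration_s = config.event_duration_s
        min_isi_s = config.event_min_isi_s
    if duration_s < event_duration_s + min_isi_s:
        warnings.warn("session too short for any stimulus event")
        return EventTrain(onsets=np.empty(0), duration_s=event_duration_s,
                          session_duration_s=duration_s)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 808]))
    onsets = []
    t = rng.uniform(2.0, 2.0 + min_isi_s)
    while t + event_duration_s <= duration_s:
        onsets.append(t)
        t += event_duration_s + min_isi_s + rng.exponential(5.0)
    return EventTrain(onsets=np.asarray(onsets), duration_s=event_duration_s,
                      session_duration_s=duration_s)


def gen_action_tuned_ensemble(n_units, n_actions, duration_s, seed, *,
                              fps=120.0, base_rate_hz=5.0, gain=3.0,
                              mean_bout_s=4.0, tuned_fraction=1.0):
    """Frame labels plus spike trains of action-tuned units.

    Labels follow alternating scripted bouts over ``n_actions`` actions;
    each tuned unit fires at ``gain`` times its base rate inside its
    preferred action (units are assigned preferred actions round-robin).
    Returns (labels, spike_trains, preferred_action).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    n = int(round(duration_s * fps))
    labels = _sample_regime_sequence(rng, n, fps, n_actions, mean_bout_s)
    p_base = np.clip(base_rate_hz / fps, 1e-6, 0.5)
    trains = []
    preferred = np.full(n_units, -1)
    for u in range(n_units):
        urng = _unit_rng(seed, u)
        p = np.full(n, p_base)
        if u < tuned_fraction * n_units:
            preferred[u] = u % n_actions
            p[labels == preferred[u]] = np.clip(p_base * gain, 0, 0.9)
        fires = urng.random(n) < p
        idx = np.flatnonzero(fires)
        trains.append(np.sort((idx + urng.random(idx.size)) / fps))
    return labels, trains, preferred


# ---------------------------------------------------------------------------
# one-call session builder

def make_session(config, script=None):
    """Generate tracking, features, spikes and events for one session.

    Returns ``(session, features, spikes, events, truth)`` where features
    is the kinematics-extracted covariate table (so generated spikes are
    tuned to the same covariate values the analysis will see).
    """
    from .kinematics import compute_features, fit_head_template, fit_pose_series

    session, truth = gen_tracking(config, script=script)
    template = fit_head_template(session.head)
    poses = fit_pose_series(session, template)
    features = compute_features(session, poses)
    spikes = gen_spikes_from_glm(features, config)
    truth.rs_fs = spikes.metadata["true_type"].to_numpy()
    events = gen_stimulus_session(config)
    return session, features, spikes, events, truth
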