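import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ethophys import kinematics as kin
from ethophys import synth


class TestEulerXYZ:
    def test_identity(self):
        a, b, c, flag = kin.euler_xyz(np.eye(3))
        assert (a, b, c) == (0.0, 0.0, 0.0)
        assert not flag

    def test_single_axis_rotation(self):
        R = kin.compose_euler_xyz(30.0, 0.0, 0.0)
        a, b, c, _ = kin.euler_xyz(R)
        assert a == pytest.approx(30.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_random_rotations(self, rng):
        for _ in range(200):
            R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            a, b, c, flag = kin.euler_xyz(R)
            if flag:
                continue
            back = kin.compose_euler_xyz(a, b, c)
            assert np.abs(back - R).max() < 1e-9

    def test_gimbal_lock_convention(self):
        R = kin.compose_euler_xyz(25.0, 90.0, 40.0)
        a, b, c, flag = kin.euler_xyz(R)
        assert flag
        assert c == 0.0
        assert b == pytest.approx(90.0, abs=1e-6)

    def test_rejects_improper_matrix(self):
        with pytest.raises(ValueError):
            kin.euler_xyz(np.diag([1.0, 1.0, -1.0]))


class TestHeadAngles:
    def test_round_trip(self, rng):
        for _ in range(50):
            p, a, r = rng.uniform([-80, -179, -80], [80, 179, 80])
            R = kin.compose_head_rotation(p, a, r)
            p2, a2, r2 = kin.head_angles(R)
            assert np.allclose([p2, a2, r2], [p, a, r], atol=1e-9)

    def test_heading_adds_to_azimuth_only(self, rng):
        """Rotating the room frame about z shifts azimuth and nothing else."""
        p, a, r = 25.0, 40.0, -10.0
        R = kin.compose_head_rotation(p, a, r)
        phi = 73.0
        Rz = Rotation.from_euler("z", phi, degrees=True).as_matrix()
        p2, a2, r2 = kin.head_angles(Rz @ R)
        assert p2 == pytest.approx(p, abs=1e-9)
        assert a2 == pytest.approx(a + phi, abs=1e-9)
        assert r2 == pytest.approx(r, abs=1e-9)


class TestHeadTemplate:
    def test_identical_frames_recover_geometry(self):
        pts = synth.HEAD_MARKER_LOCAL
        head = np.repeat(pts[None], 150, axis=0)
        tpl = kin.fit_head_template(head)
        d_t = np.linalg.norm(tpl.points[:, None] - tpl.points[None], axis=-1)
        d_0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        assert np.allclose(d_t, d_0, atol=1e-12)

    def test_outlier_frame_not_chosen(self):
        pts = synth.HEAD_MARKER_LOCAL
        head = np.repeat(pts[None], 200, axis=0)
        head[57] = pts * 1.8          # stretched geometry
        tpl = kin.fit_head_template(head)
        assert tpl.frame_index != 57

    def test_noisy_template_within_tolerance(self, rng):
        sigma = 0.1
        pts = synth.HEAD_MARKER_LOCAL
        head = pts[None] + rng.normal(0, sigma, (300, 4, 3))
        tpl = kin.fit_head_template(head)
        iu = np.triu_indices(4, 1)
        d_t = np.linalg.norm(tpl.points[:, None] - tpl.points[None], axis=-1)[iu]
        d_0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)[iu]
        assert np.abs(d_t - d_0).max() < 3 * sigma

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            kin.fit_head_template(np.zeros((10, 4, 3)))


class TestPoseFit:
    def test_known_rotation_recovered(self, rng):
        from ethophys.kinematics import _kabsch
        tpl = synth.HEAD_MARKER_LOCAL - synth.HEAD_MARKER_LOCAL.mean(0)
        R0 = Rotation.random(random_state=5).as_matrix()
        t0 = np.array([3.0, -2.0, 7.0])
        R, t = _kabsch(tpl, tpl @ R0.T + t0)
        assert np.abs(R - R0).max() < 1e-9
        assert np.abs(t - t0).max() < 1e-9

    def test_template_frame_gives_identity(self):
        from ethophys.kinematics import _kabsch
        tpl = synth.HEAD_MARKER_LOCAL - synth.HEAD_MARKER_LOCAL.mean(0)
        R, t = _kabsch(tpl, tpl)
        assert np.abs(R - np.eye(3)).max() < 1e-12
        assert np.abs(t).max() < 1e-12


def _static_trunk(n, neck=(10.0, 0.0, 8.0), tail=(-10.0, 0.0, 8.0),
                  back=None):
    trunk = np.empty((n, 3, 3))
    trunk[:, 0] = neck
    trunk[:, 2] = tail
    trunk[:, 1] = back if back is not None else (0.0, 0.0, 9.0)
    return trunk


def _static_head(n, pitch=0.0, azimuth=0.0, roll=0.0, base=(12.0, 0.0, 10.0)):
    R = kin.compose_head_rotation(pitch, azimuth, roll)
    pts = np.asarray(base) + synth.HEAD_MARKER_LOCAL @ R.T
    return np.repeat(pts[None], n, axis=0)


class TestComputeFeatures:
    def test_stationary_animal_zero_speed(self):
        n = 1200
        session = kin.TrackingSession(t=np.arange(n) / 120.0,
                                      head=_static_head(n),
                                      trunk=_static_trunk(n))
        tpl = kin.fit_head_template(session.head)
        poses = kin.fit_pose_series(session, tpl)
        feats = kin.compute_features(session, poses)
        speed = feats["speed"].dropna()
        assert np.allclose(speed, 0.0, atol=1e-9)
        sm = feats[["self_motion_x", "self_motion_y"]].dropna().to_numpy()
        assert np.allclose(sm, 0.0, atol=1e-9)

    def test_derivative_of_constant_is_zero(self):
        n = 1200
        session = kin.TrackingSession(t=np.arange(n) / 120.0,
                                      head=_static_head(n, pitch=20.0),
                                      trunk=_static_trunk(n))
        poses = kin.fit_pose_series(session, kin.fit_head_template(session.head))
        feats = kin.compute_features(session, poses)
        for col in feats.columns:
            if col.startswith("d_"):
                assert np.allclose(feats[col].dropna(), 0.0, atol=1e-6)

    def test_back_azimuth_ramp_rate(self):
        """Upper-back marker swinging at 90 deg/s around a fixed trunk axis."""
        n = 1200
        fps = 120.0
        t = np.arange(n) / fps
        phi = np.radians(90.0 * t)      # swing angle of the back segment
        neck = np.array([10.0, 0.0, 8.0])
        trunk = np.empty((n, 3, 3))
        trunk[:, 0] = neck
        trunk[:, 2] = (-10.0, 0.0, 8.0)
        trunk[:, 1, 0] = neck[0] - 8.0 * np.cos(phi)
        trunk[:, 1, 1] = neck[1] - 8.0 * np.sin(phi)
        trunk[:, 1, 2] = 8.0
        session = kin.TrackingSession(t=t, head=_static_head(n), trunk=trunk)
        poses = kin.fit_pose_series(session, kin.fit_head_template(session.head))
        feats = kin.compute_features(session, poses, center_back=False)
        d = feats["d_back_azimuth"].dropna().to_numpy()
        assert np.median(np.abs(d - 90.0)) < 0.9

    def test_ego_equals_allo_minus_body_direction_for_level_trunk(self):
        """With a horizontal trunk the azimuths decompose additively."""
        n = 600
        feats_list = []
        for az in (0.0, 35.0, -120.0):
            trunk = _static_trunk(n)
            session = kin.TrackingSession(t=np.arange(n) / 120.0,
                                          head=_static_head(n, azimuth=az),
                                          trunk=trunk)
            poses = kin.fit_pose_series(session,
                                        kin.fit_head_template(session.head))
            feats = kin.compute_features(session, poses)
            resid = kin.wrap_degrees(
                (feats["allo_head_azimuth"] - feats["body_direction"]
                 - feats["ego_head_azimuth"]).to_numpy())
            resid = resid[np.isfinite(resid)]
            assert np.abs(resid).max() < 1e-6

    def test_angles_wrapped(self, small_session):
        feats = small_session["features"]
        for col in kin.POSTURAL_FEATURES[:-1] + ("body_direction",):
            v = feats[col].dropna()
            assert (v > -180.0).all() and (v <= 180.0).all()


class TestScriptedRecovery:
    def test_scripted_pitch_recovered(self):
        """+45 deg scripted pitch bouts recovered within a degree."""
        script = {
            "regimes": [
                ("run_level", dict(speed=22.0, pitch=0.0, neck=8.0, roll=0.0)),
                ("pitch_up", dict(speed=3.0, pitch=45.0, neck=8.0, roll=0.0)),
            ],
            "mean_bout_s": 6.0,
        }
        cfg = synth.SynthConfig(duration_s=240.0, seed=21, n_units=1,
                                marker_jitter_cm=0.02)
        session, truth = synth.gen_tracking(cfg, script=script)
        poses = kin.fit_pose_series(session,
                                    kin.fit_head_template(session.head))
        feats = kin.compute_features(session, poses)
        est = feats["allo_head_pitch"].to_numpy()
        scripted = truth.scripted["allo_head_pitch"]
        # score the settled +45 deg bouts (regime 1, target reached)
        m = np.isfinite(est) & (truth.regime == 1) & (np.abs(scripted - 45) < 5)
        assert m.sum() > 500
        assert np.median(est[m]) == pytest.approx(45.0, abs=1.0)

    def test_angle_recovery_across_sessions(self):
        """Median per-session angle error stays below 2 degrees."""
        meds = {k: [] for k in ("allo_head_pitch", "allo_head_azimuth",
                                "allo_head_roll")}
        for seed in range(5):
            cfg = synth.SynthConfig(duration_s=240.0, seed=seed, n_units=1)
            session, truth = synth.gen_tracking(cfg)
            poses = kin.fit_pose_series(
                session, kin.fit_head_template(session.head))
            feats = kin.compute_features(session, poses)
            for k in meds:
                est = feats[k].to_numpy()
                m = np.isfinite(est)
                err = kin.wrap_degrees(est[m] - truth.scripted[k][m])
                meds[k].append(np.median(np.abs(err)))
        for k, v in meds.items():
            assert np.median(v) < 2.0, (k, v)
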