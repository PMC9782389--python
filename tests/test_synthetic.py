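"""Synthetic generator: kinematic consistency, error injection, determinism."""

import numpy as np
import pytest

from imusep.errors import InvalidConfigError
from imusep.orientation import GRAVITY
from imusep.quat import (
    IDENTITY,
    QuaternionSeries,
    enforce_continuity,
    qangle,
    qfrom_axis_angle,
    qinv,
    qmul,
    qrel,
    qrotate,
)
from imusep.synthetic import (
    CALIBRATION_SIGNS,
    SEGMENTS,
    Q_NEUTRAL,
    SyntheticConfig,
    default_geometry,
    generate_dataset,
    generate_segment_motion,
    generate_trial,
    inject_sta,
    synthesize_imu_signals,
    synthesize_marker_set,
)
from imusep.frames import cluster_frame
from tests.conftest import clean_config


def _integrate_gyro(rec, q0):
    """Reference first-order quaternion integration of the gyro channel
    (raw Hamilton product: the rate quaternion is not unit-norm)."""
    q = np.empty((len(rec), 4))
    q[0] = q0
    dt = rec.dt
    for i in range(1, len(rec)):
        w, x, y, z = q[i - 1]
        gx, gy, gz = 0.5 * (rec.gyro[i] + rec.gyro[i - 1])
        qd = 0.5 * np.array(
            [
                -x * gx - y * gy - z * gz,
                w * gx + y * gz - z * gy,
                w * gy - x * gz + z * gx,
                w * gz + x * gy - y * gx,
            ]
        )
        qn = q[i - 1] + qd * dt
        q[i] = qn / np.linalg.norm(qn)
    return q


class TestSegmentMotion:
    def test_intensity_zero_is_static(self):
        cfg = clean_config(movement="squat", intensity=0.0, duration=8.0)
        motion = generate_segment_motion(cfg)
        for seg in SEGMENTS:
            assert qangle(qrel(motion.bone[seg].q, np.tile(Q_NEUTRAL, (len(motion.timestamps), 1)))).max() < 1e-9
            assert np.abs(np.diff(motion.origins[seg], axis=0)).max() < 1e-9

    def test_squat_periodicity(self):
        cfg = clean_config(movement="squat", intensity=1.0, duration=16.0)
        motion = generate_segment_motion(cfg)
        knee = motion.angles["knee_r"]
        t = motion.timestamps
        period = int(round(2.5 * cfg.imu_rate))  # 0.4 Hz cadence
        mid = (t > 8.0) & (t < 12.0)
        idx = np.where(mid)[0]
        assert np.abs(knee[idx] - knee[idx + period]).max() < 1e-6

    def test_unknown_movement_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(movement="cartwheel")

    def test_chain_consistency_thigh_shank_share_knee(self):
        cfg = clean_config(movement="run", intensity=0.8)
        geo = default_geometry()
        motion = generate_segment_motion(cfg, geo)
        knee_from_thigh = motion.origins["thigh_r"] + qrotate(
            motion.bone["thigh_r"].q, np.array([0.0, -geo.thigh_length, 0.0])
        )
        assert np.abs(knee_from_thigh - motion.origins["shank_r"]).max() < 1e-9

    def test_orientation_angular_velocity_consistency(self):
        """Integrating the angular velocity implied by the orientation
        series reproduces the series (physical self-consistency)."""
        cfg = clean_config(movement="kick", intensity=1.0, duration=11.0)
        motion = generate_segment_motion(cfg)
        s = motion.bone["thigh_r"]
        mount = (np.zeros(3), IDENTITY)
        rec = synthesize_imu_signals(s, motion.origins["thigh_r"], mount, cfg)
        q = _integrate_gyro(rec, s.q[0])
        err = qangle(qrel(q, s.q))
        assert err.max() < 0.1


class TestInjectSta:
    def _bone(self, n=2500):
        ts = np.arange(n) / 250.0
        return QuaternionSeries(ts, np.tile(Q_NEUTRAL, (n, 1)), "GRF", "thigh_r"), ts

    def test_zero_gain_is_identity(self):
        bone, ts = self._bone()
        skin, sta = inject_sta(bone, np.zeros(len(ts)), 0.0, [0, 0, 1])
        assert np.allclose(skin.q, bone.q)
        assert np.all(sta == 0)

    def test_sinusoidal_flexion_closed_form_rms(self):
        """STA RMS equals gain * F / sqrt(2) for sinusoidal flexion F."""
        bone, ts = self._bone(5000)
        F, g = 90.0, 0.08
        flex = F * np.sin(2 * np.pi * 0.8 * ts)
        skin, sta = inject_sta(bone, flex, g, [0.2, 0.9, 0.4])
        assert np.sqrt(np.mean(sta**2)) == pytest.approx(g * F / np.sqrt(2), rel=0.01)

    def test_sta_series_equals_relative_angle(self):
        bone, ts = self._bone(1000)
        flex = 60.0 * np.sin(2 * np.pi * 1.1 * ts)
        skin, sta = inject_sta(bone, flex, 0.1, [1, 1, 0])
        assert np.abs(qangle(qrel(bone.q, skin.q)) - sta).max() < 1e-9

    def test_impact_transient_decays_with_configured_tau(self):
        bone, ts = self._bone(2500)
        skin, sta = inject_sta(
            bone, np.zeros(len(ts)), 0.0, [0, 0, 1],
            impacts=[(4.0, 1.0)], impact_amplitude_deg=5.0,
            impact_freq_hz=15.0, impact_tau_s=0.05,
        )
        after = ts >= 4.0
        env = 5.0 * np.exp(-(ts[after] - 4.0) / 0.05)
        assert np.all(sta[after] <= env + 1e-9)
        assert sta[after].max() > 2.0  # transient actually present
        assert np.all(sta[ts < 4.0] == 0)


class TestMarkerSynthesis:
    def test_rigid_roundtrip_without_sta(self):
        """cluster_frame on synthesized RMC markers recovers the sensor
        pose exactly when STA and noise are absent."""
        cfg = clean_config(movement="walk", intensity=0.6)
        geo = default_geometry()
        motion = generate_segment_motion(cfg, geo)
        skin = {s: motion.bone[s] for s in SEGMENTS}
        mounts = geo.mounts
        ms = synthesize_marker_set(motion, skin, geo, mounts)
        seg = "shank_l"
        s = cluster_frame(ms, tuple(f"{seg}_RMC{i}" for i in (1, 2, 3, 4)), geo.rmc_local)
        q_expected = qmul(skin[seg].q[::2], np.broadcast_to(mounts[seg][1], (len(s), 4)))
        assert qangle(qrel(s.q, q_expected)).max() < 1e-6

    def test_marker_noise_spreads_distances(self):
        cfg = clean_config(movement="squat", intensity=0.0, duration=6.0)
        geo = default_geometry()
        motion = generate_segment_motion(cfg, geo)
        skin = {s: motion.bone[s] for s in SEGMENTS}
        rng = np.random.default_rng(2)
        ms = synthesize_marker_set(motion, skin, geo, geo.mounts, noise_mm=0.5, rng=rng)
        d = np.linalg.norm(ms["LASIS"] - ms["RASIS"], axis=1)
        # distance of two markers with iid sigma=0.5 noise: std ~ 0.5*sqrt(2)
        assert d.std() == pytest.approx(0.5 * np.sqrt(2), rel=0.25)


class TestImuSynthesis:
    def test_static_pose_signals(self):
        cfg = clean_config(movement="squat", intensity=0.0, duration=6.0)
        geo = default_geometry()
        motion = generate_segment_motion(cfg, geo)
        rec = synthesize_imu_signals(
            motion.bone["pelvis"], motion.origins["pelvis"], geo.mounts["pelvis"], cfg
        )
        assert np.abs(rec.gyro).max() < 1e-9
        assert np.abs(np.linalg.norm(rec.accel, axis=1) - GRAVITY).max() < 1e-6
        assert np.abs(rec.mag - rec.mag[0]).max() < 1e-12

    def test_constant_rotation_integrates_back(self):
        """Gyro of a constant-rate vertical rotation integrates to the pose
        within 0.05 deg."""
        cfg = clean_config()
        n = 2501
        ts = np.arange(n) / cfg.imu_rate
        q = qmul(
            qfrom_axis_angle(np.array([0.0, 0, 1]), 1.2 * ts),
            np.broadcast_to(Q_NEUTRAL, (n, 4)),
        )
        s = QuaternionSeries(ts, q, "GRF", "pelvis")
        origins = np.tile([0.0, 0, 1000.0], (n, 1))
        rec = synthesize_imu_signals(s, origins, (np.zeros(3), IDENTITY), cfg)
        qi = _integrate_gyro(rec, q[0])
        assert qangle(qrel(qi, enforce_continuity(s).q)).max() < 0.05

    def test_free_fall_during_flight(self):
        cfg = clean_config(movement="squat_jump", intensity=1.0, duration=12.0)
        geo = default_geometry()
        motion = generate_segment_motion(cfg, geo)
        rec = synthesize_imu_signals(
            motion.bone["pelvis"], motion.origins["pelvis"], geo.mounts["pelvis"], cfg
        )
        assert np.linalg.norm(rec.accel, axis=1).min() < 0.2

    def test_gyro_bias_added(self):
        cfg = clean_config(movement="squat", intensity=0.0, duration=6.0)
        geo = default_geometry()
        motion = generate_segment_motion(cfg, geo)
        rec = synthesize_imu_signals(
            motion.bone["pelvis"], motion.origins["pelvis"], geo.mounts["pelvis"], cfg,
            gyro_bias=np.array([0.01, 0.0, -0.02]),
        )
        assert np.allclose(rec.gyro.mean(axis=0), [0.01, 0.0, -0.02], atol=1e-9)

    def test_mag_dipole_disturbance_is_position_dependent(self):
        cfg = clean_config(
            movement="walk", intensity=1.0,
            mag_disturbance={"position_mm": [500.0, 0.0, 1000.0], "moment": [0, 0, 1.0], "amplitude": 0.5},
        )
        geo = default_geometry()
        motion = generate_segment_motion(cfg, geo)
        rec_d = synthesize_imu_signals(
            motion.bone["pelvis"], motion.origins["pelvis"], geo.mounts["pelvis"], cfg
        )
        cfg0 = clean_config(movement="walk", intensity=1.0)
        rec_0 = synthesize_imu_signals(
            motion.bone["pelvis"], motion.origins["pelvis"], geo.mounts["pelvis"], cfg0
        )
        dev = np.linalg.norm(rec_d.mag - rec_0.mag, axis=1)
        assert dev.max() > 0.01
        assert dev.std() > 0  # varies as the sensor moves


class TestCalibrationTrials:
    def test_calibration_signs_match_generated_kinematics(self):
        """The protocol sign table matches the initial rotation direction
        of every segment in every generated calibration movement."""
        cfg = clean_config()
        geo = default_geometry()
        from imusep import synthetic as syn

        truth = syn._subject_randomization(cfg, np.random.default_rng(0), geo)
        for method in ("A", "B", "C"):
            trial = generate_trial(cfg, f"calib{method}", truth, geo, None)
            for seg in SEGMENTS:
                w0, w1 = trial.movement_windows[seg]
                bone = trial.bone[seg].window(w0, w1)
                rel = qrel(np.broadcast_to(bone.q[0], bone.q.shape), bone.q)
                # initial body-frame rotation direction about +Z
                ang = 2.0 * np.arcsin(np.clip(rel[:, 3], -1, 1))
                lead = ang[np.abs(ang) > np.radians(2.0)]
                assert len(lead) > 0, (method, seg)
                assert np.sign(lead[0]) == CALIBRATION_SIGNS[method][seg], (method, seg)

    def test_frame_error_only_in_calibration_trials(self):
        cfg = clean_config(mounting_error_deg=12.0)
        geo = default_geometry()
        from imusep import synthetic as syn

        truth = syn._subject_randomization(cfg, np.random.default_rng(1), geo)
        mov = generate_trial(cfg, "movement", truth, geo, None)
        cal = generate_trial(cfg, "calibB", truth, geo, None)
        # during their static lead-ins, the movement trial stands in the
        # neutral pose while the calibration trial is offset by the frame
        # error (a rotation about the longitudinal axis leaves gravity
        # unchanged, so the stance is physically plausible)
        seg = "thigh_l"
        assert qangle(qrel(mov.bone[seg].q[0], Q_NEUTRAL)) < 1e-9
        expected = qmul(Q_NEUTRAL, qinv(truth.q_frame_error[seg]))
        assert qangle(qrel(cal.bone[seg].q[0], expected)) < 1e-9
        assert abs(qangle(truth.q_frame_error[seg]) - 12.0) < 1e-9


class TestDataset:
    def test_same_seed_reproduces_exactly(self):
        a = generate_dataset(SyntheticConfig(seed=9), 1, 1, trials={"walk": ("walk", 1.0)})
        b = generate_dataset(SyntheticConfig(seed=9), 1, 1, trials={"walk": ("walk", 1.0)})
        ta = a.subjects[0].trial("walk_rep1")
        tb = b.subjects[0].trial("walk_rep1")
        assert np.array_equal(ta.imu["pelvis"].gyro, tb.imu["pelvis"].gyro)
        assert np.array_equal(ta.markers["LASIS"], tb.markers["LASIS"])

    def test_different_seeds_differ(self):
        a = generate_dataset(SyntheticConfig(seed=9), 1, 1, trials={"walk": ("walk", 1.0)})
        b = generate_dataset(SyntheticConfig(seed=10), 1, 1, trials={"walk": ("walk", 1.0)})
        assert not np.array_equal(
            a.subjects[0].trial("walk_rep1").imu["pelvis"].gyro,
            b.subjects[0].trial("walk_rep1").imu["pelvis"].gyro,
        )

    def test_layout_roles_present(self):
        ds = generate_dataset(SyntheticConfig(seed=3), 2, 2, trials={"squat": ("squat", 1.0)})
        assert len(ds.subjects) == 2
        roles = [t.role for t in ds.subjects[0].trials]
        for role in ("neutral", "calibA", "calibB", "calibC", "compass", "static"):
            assert roles.count(role) == 1
        assert roles.count("movement") == 2
        # per-subject randomization differs
        assert not np.allclose(
            ds.subjects[0].truth.q_mount["pelvis"], ds.subjects[1].truth.q_mount["pelvis"]
        )

    def test_ground_truth_sta_matches_bone_skin_relation(self):
        ds = generate_dataset(SyntheticConfig(seed=4), 1, 1, trials={"shot": ("kick", 1.0)})
        tr = ds.subjects[0].trial("shot_rep1")
        for seg in ("thigh_r", "shank_r"):
            rel = qangle(qrel(tr.bone[seg].q, tr.skin[seg].q))
            # float rounding through the quaternion products leaves ~1e-7 deg
            assert np.abs(rel - tr.sta_deg[seg]).max() < 1e-5
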