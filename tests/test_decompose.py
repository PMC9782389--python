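"""Frame composition, the nine comparisons, RMSD aggregation."""

import numpy as np
import pandas as pd
import pytest

from imusep.calibrate import BodyCal
from imusep.decompose import (
    TABLE1_PAIRS,
    ComparisonResult,
    aggregate,
    apply_mcbf,
    compare_frames,
    compose_scbf,
    express_in_grf,
    independence_check,
    results_frame,
    run_table1,
)
from imusep.errors import EmptyInputError, FrameMismatchError, MissingFrameError
from imusep.quat import (
    IDENTITY,
    QuaternionSeries,
    qangle,
    qfrom_axis_angle,
    qmul,
    qnorm,
    qrel,
    qto_matrix,
)

N = 500
TS = np.arange(N) / 250.0


def series(q, source="GRF", target="x"):
    q = np.tile(q, (N, 1)) if np.ndim(q) == 1 else q
    return QuaternionSeries(TS, q, source, target)


def random_series(seed, source="IRF", target="IMU-sf"):
    q = qnorm(np.random.default_rng(seed).normal(size=(N, 4)))
    return QuaternionSeries(TS, q, source, target)


class TestComposition:
    def test_identity_cal_unchanged(self):
        s = random_series(0)
        cal = BodyCal(IDENTITY, "A")
        out = compose_scbf(s, cal)
        assert np.allclose(out.q, s.q)
        assert out.target_frame == "IMU-scbfA"

    def test_constant_rotation_cal(self):
        s = series(IDENTITY, source="IRF")
        cal = BodyCal(qfrom_axis_angle([0, 1, 0], np.pi / 2), "B")
        out = compose_scbf(s, cal)
        assert np.abs(qangle(qrel(s.q, out.q)) - 90.0).max() < 1e-9

    def test_matrix_chain_oracle(self):
        s = random_series(1)
        cal = BodyCal(qnorm(np.array([0.6, 0.2, -0.5, 0.4])), "C")
        out = compose_scbf(s, cal)
        expected = np.einsum(
            "nij,jk->nik", qto_matrix(s.q), qto_matrix(cal.q_sensor_to_body)
        )
        assert np.abs(qto_matrix(out.q) - expected).max() < 1e-10

    def test_mcbf_cal_required_for_scbf_rejected(self):
        s = random_series(2)
        with pytest.raises(FrameMismatchError):
            compose_scbf(s, BodyCal(IDENTITY, "mcbf"))

    def test_hand_eye_identity_and_yaw(self):
        s = series(IDENTITY, source="IRF")
        assert np.allclose(express_in_grf(IDENTITY, s).q, s.q)
        yaw = qfrom_axis_angle([0, 0, 1], np.radians(35))
        out = express_in_grf(yaw, s)
        assert np.abs(qangle(out.q) - 35.0).max() < 1e-9
        assert out.source_frame == "GRF"

    def test_left_and_right_multiplication_commute(self):
        s = random_series(3)
        he = qnorm(np.array([0.8, 0.1, 0.3, -0.2]))
        cal = BodyCal(qnorm(np.array([0.5, 0.5, 0.5, 0.5])), "A")
        a = compose_scbf(express_in_grf(he, s), cal)
        b = express_in_grf(he, compose_scbf(s, cal))
        assert qangle(qrel(a.q, b.q)).max() < 1e-10

    def test_wrong_source_frame_rejected(self):
        s = random_series(4, source="GRF")
        with pytest.raises(FrameMismatchError):
            express_in_grf(IDENTITY, s)

    def test_apply_mcbf_cancels_at_static(self):
        body = series(qnorm(np.array([0.9, 0.1, 0.2, -0.3])), target="AL-mcbf")
        off = qfrom_axis_angle([0.3, 0.8, 0.5], np.radians(14))
        sensor = series(qmul(body.q[0], off), target="RMC-sf")
        cal = BodyCal(off, "mcbf")
        out = apply_mcbf(sensor, cal, "RMC-mcbf")
        assert qangle(qrel(out.q, body.q)).max() < 1e-9


class TestCompareFrames:
    def test_equal_series_zero(self):
        s = random_series(5, source="GRF")
        r = compare_frames(s, s, 5)
        assert r.rmsd == 0.0 and r.max_error == 0.0

    def test_constant_offset(self):
        a = random_series(6, source="GRF")
        off = qfrom_axis_angle([0.2, 0.3, 0.9], np.radians(10))
        b = QuaternionSeries(TS, qmul(a.q, off), "GRF", "y")
        r = compare_frames(a, b, 4)
        assert r.rmsd == pytest.approx(10.0, abs=1e-9)
        assert r.max_error == pytest.approx(10.0, abs=1e-9)

    def test_sinusoidal_offset_rms_closed_form(self):
        """An 8 deg sinusoidal axis-angle difference has RMSD A/sqrt(2)."""
        n = 2500  # 10 s at 250 Hz
        ts = np.arange(n) / 250.0
        a = QuaternionSeries(ts, np.tile(IDENTITY, (n, 1)), "GRF", "a")
        ang = np.radians(8.0) * np.sin(2 * np.pi * 1.7 * ts)
        b = QuaternionSeries(ts, qfrom_axis_angle(np.array([0.0, 0, 1]), ang), "GRF", "b")
        r = compare_frames(a, b, 6)
        assert r.rmsd == pytest.approx(8.0 / np.sqrt(2), rel=0.01)

    def test_rmsd_invariants(self):
        a, b = random_series(7, "GRF"), random_series(8, "GRF")
        r = compare_frames(a, b, 6)
        assert 0 <= r.rmsd <= r.max_error
        assert r.rmsd == pytest.approx(float(np.sqrt(np.mean(r.angle_series**2))))

    def test_mismatches_rejected(self):
        a = random_series(9, "GRF")
        b = QuaternionSeries(TS[:-1], a.q[:-1], "GRF", "b")
        with pytest.raises(FrameMismatchError):
            compare_frames(a, b, 1)
        c = random_series(10, "IRF")
        with pytest.raises(FrameMismatchError):
            compare_frames(a, c, 1)


class TestTable1:
    FRAMES = ("IMU-scbfA", "IMU-scbfB", "IMU-scbfC", "IMU-mcbf", "RMC-mcbf", "AL-mcbf")

    def test_identical_frames_give_nine_zeros(self):
        s = random_series(11, "GRF")
        frames = {f: s for f in self.FRAMES}
        results = run_table1(frames, segment="pelvis", trial="squat")
        assert len(results) == 9
        assert {r.comparison_id for r in results} == set(range(1, 10))
        assert all(r.rmsd == 0.0 for r in results)

    def test_pairings_match_table(self):
        base = random_series(12, "GRF")
        rng = np.random.default_rng(13)
        frames = {
            f: QuaternionSeries(TS, qmul(base.q, qnorm(rng.normal(size=4))), "GRF", f)
            for f in self.FRAMES
        }
        results = {r.comparison_id: r for r in run_table1(frames)}
        for cid, (f1, f2, _) in TABLE1_PAIRS.items():
            direct = compare_frames(frames[f1], frames[f2], cid)
            assert results[cid].rmsd == pytest.approx(direct.rmsd)

    def test_pure_frame_error_isolated(self):
        """A 15 deg body-frame error shows in #1 only; #4 and #5 stay 0."""
        sensor = random_series(14, "GRF")
        err = qfrom_axis_angle([0, 1, 0], np.radians(15))
        frames = {
            "IMU-mcbf": sensor,
            "RMC-mcbf": sensor,
            "AL-mcbf": sensor,
            "IMU-scbfA": QuaternionSeries(TS, qmul(sensor.q, err), "GRF", "IMU-scbfA"),
            "IMU-scbfB": sensor,
            "IMU-scbfC": sensor,
        }
        res = {r.comparison_id: r for r in run_table1(frames)}
        assert res[1].rmsd == pytest.approx(15.0, abs=1e-9)
        assert res[4].rmsd == 0.0 and res[5].rmsd == 0.0

    def test_root_sum_square_of_independent_errors(self):
        """Independent 6 deg STA and 4 deg filter perturbations compose to
        ~sqrt(52) in the combined comparison #6."""
        n = 5000
        ts = np.arange(n) / 250.0
        bone = QuaternionSeries(ts, np.tile(IDENTITY, (n, 1)), "GRF", "AL-mcbf")
        sta = qfrom_axis_angle(
            np.array([0.0, 0, 1]), np.radians(6 * np.sqrt(2)) * np.sin(2 * np.pi * 1.1 * ts)
        )
        filt = qfrom_axis_angle(
            np.array([1.0, 0, 0]), np.radians(4 * np.sqrt(2)) * np.sin(2 * np.pi * 2.7 * ts)
        )
        rmc = QuaternionSeries(ts, qmul(bone.q, sta), "GRF", "RMC-mcbf")
        imu = QuaternionSeries(ts, qmul(rmc.q, filt), "GRF", "IMU-mcbf")
        frames = {
            "AL-mcbf": bone, "RMC-mcbf": rmc, "IMU-mcbf": imu,
            "IMU-scbfA": imu, "IMU-scbfB": imu, "IMU-scbfC": imu,
        }
        res = {r.comparison_id: r for r in run_table1(frames)}
        assert res[4].rmsd == pytest.approx(6.0, rel=0.02)
        assert res[5].rmsd == pytest.approx(4.0, rel=0.02)
        expected = np.sqrt(6.0**2 + 4.0**2)
        assert res[6].rmsd == pytest.approx(expected, rel=0.15)

    def test_missing_frame_names_skipped_comparisons(self):
        s = random_series(15, "GRF")
        frames = {f: s for f in self.FRAMES if f != "RMC-mcbf"}
        with pytest.raises(MissingFrameError, match="RMC-mcbf"):
            run_table1(frames)


class TestAggregate:
    @staticmethod
    def _result(subject, trial, rep, segment, cid, rmsd):
        return ComparisonResult(
            comparison_id=cid, segment=segment, trial=trial, subject=subject,
            repetition=rep, angle_series=np.array([rmsd]), rmsd=rmsd, max_error=rmsd,
        )

    def test_single_subject_five_reps(self):
        res = [self._result("s1", "squat", r, "pelvis", 4, 7.0) for r in range(1, 6)]
        summary = aggregate(res)
        assert summary.single_subject
        row = summary.group.iloc[0]
        assert row.mean_rmsd_deg == pytest.approx(7.0)
        assert row.std_rmsd_deg == 0.0

    def test_two_subject_hand_arithmetic(self):
        res = [
            self._result("s1", "walk", 1, "pelvis", 5, 4.0),
            self._result("s2", "walk", 1, "pelvis", 5, 6.0),
        ]
        summary = aggregate(res)
        row = summary.group.iloc[0]
        assert row.mean_rmsd_deg == pytest.approx(5.0)
        assert row.std_rmsd_deg == pytest.approx(np.sqrt(2.0))
        assert not summary.single_subject

    def test_repetition_mean_before_subject_std(self):
        res = [
            self._result("s1", "walk", 1, "pelvis", 5, 3.0),
            self._result("s1", "walk", 2, "pelvis", 5, 5.0),
            self._result("s2", "walk", 1, "pelvis", 5, 6.0),
        ]
        summary = aggregate(res)
        per = summary.per_subject
        assert per[per.subject == "s1"].rmsd_deg.iloc[0] == pytest.approx(4.0)
        assert summary.group.iloc[0].mean_rmsd_deg == pytest.approx(5.0)

    def test_group_mean_within_subject_range(self):
        rng = np.random.default_rng(16)
        res = [
            self._result(f"s{i}", "run", r, "shank_l", 6, float(rng.uniform(2, 9)))
            for i in range(10)
            for r in range(1, 6)
        ]
        summary = aggregate(res)
        per = summary.per_subject
        g = summary.group.iloc[0]
        assert per.rmsd_deg.min() <= g.mean_rmsd_deg <= per.rmsd_deg.max()

    def test_sampling_recovery_of_cohort_mean(self):
        """Group mean over 10 subjects recovers the population mean within
        two standard errors."""
        rng = np.random.default_rng(17)
        mu, sd = 6.0, 1.0
        vals = rng.normal(mu, sd, 10)
        res = [self._result(f"s{i}", "sprint", 1, "pelvis", 6, float(v)) for i, v in enumerate(vals)]
        g = aggregate(res).group.iloc[0]
        assert abs(g.mean_rmsd_deg - mu) < 2 * sd / np.sqrt(10)

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            aggregate(pd.DataFrame(columns=["subject", "trial", "segment", "comparison", "rmsd_deg", "max_deg", "repetition"]))


class TestIndependenceCheck:
    def test_three_four_five(self):
        assert independence_check(3.0, 4.0, 5.0) == pytest.approx(1.0)

    def test_single_source(self):
        assert independence_check(0.0, 2.5, 2.5) == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        assert np.isnan(independence_check(0.0, 0.0, 1.0))
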