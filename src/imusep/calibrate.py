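"""Constant alignments: sensor-body calibration, hand-eye, static-trial
marker alignment, and IMU/marker time alignment.

A sensor-body calibration defines a body-segment frame in IMU sensor
coordinates from (i) a neutral standing pose, in which the segment's
longitudinal axis is assumed parallel to gravity, and (ii) a sagittal-plane
calibration movement, whose dominant rotation axis defines the mediolateral
(flexion) axis.  Three movement protocols are supported: A (bow + thigh
rises), B (squat) and C (inclined plank); they differ only in which time
windows feed which segment, which the trial manifest declares.

The hand-eye calibration relates the camera global frame (GRF) to the
filter's inertial reference frame (IRF).  Both share the gravity vertical,
so the unknown is a single heading angle, measured with a marker-
instrumented compass aligned with magnetic north.

The static-trial alignment (the marker-calibrated body frame) is the time
average of the rotation between an anatomical body-frame series and a
sensor-frame series over a static standing trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sp_signal

from .errors import (
    DegenerateFrameError,
    FrameMismatchError,
    InsufficientExcitationError,
    InvalidInputError,
    NotStaticError,
)
from .orientation import ImuRecord
from .quat import (
    QuaternionSeries,
    enforce_continuity,
    qfrom_axes,
    qinv,
    qmean,
    qrel,
)

__all__ = [
    "BodyCal",
    "SyncResult",
    "longitudinal_axis_static",
    "flexion_axis_functional",
    "build_sensor_body_cal",
    "hand_eye_from_compass",
    "static_frame_alignment",
    "estimate_sync_offset",
    "downsample_series",
    "series_angular_rate",
]

#: Residual phase error after nearest-sample alignment of the down-sampled
#: IMU stream to the 250 Hz marker clock: half the marker sample period.
SYNC_RESIDUAL_BOUND_S = 1.0 / (2.0 * 250.0)


@dataclass
class BodyCal:
    """A constant sensor-frame -> body-frame rotation.

    ``method`` is "A", "B" or "C" for the sensor-body calibrations
    (q_IMU-sf^IMU-scbf) or "mcbf" for a static-trial marker alignment
    (q_AL-mcbf^sensor, see static_frame_alignment).
    """

    q_sensor_to_body: np.ndarray
    method: str
    segment: str = ""

    def __post_init__(self):
        self.q_sensor_to_body = np.asarray(self.q_sensor_to_body, dtype=float)
        if self.q_sensor_to_body.shape != (4,):
            raise InvalidInputError("BodyCal quaternion must have shape (4,)")
        if abs(np.linalg.norm(self.q_sensor_to_body) - 1.0) > 1e-6:
            raise InvalidInputError("BodyCal quaternion must be unit-norm")


@dataclass
class SyncResult:
    """Integer-sample lag (at 250 Hz) of the IMU stream relative to the
    markers, plus the residual phase-error bound of the alignment."""

    lag: int
    residual_bound: float = SYNC_RESIDUAL_BOUND_S


def longitudinal_axis_static(
    rec: ImuRecord, window: tuple[float, float] | None = None, gyro_rms_max: float = 0.05
) -> np.ndarray:
    """Segment longitudinal (Y) axis in sensor coordinates, from gravity.

    Unit mean accelerometer direction over a static neutral-pose window,
    pointing up (toward the proximal end of the segment).
    """
    w = rec if window is None else rec.window(*window)
    if len(w) == 0:
        raise InvalidInputError("empty static window")
    rms = float(np.sqrt(np.mean(np.sum(w.gyro**2, axis=1))))
    if rms > gyro_rms_max:
        raise NotStaticError(f"gyro RMS {rms:.3f} rad/s in declared static window")
    mean = w.accel.mean(axis=0)
    n = np.linalg.norm(mean)
    if n < 1e-9:
        raise NotStaticError("zero mean accelerometer in static window")
    return mean / n


def flexion_axis_functional(
    rec: ImuRecord,
    window: tuple[float, float] | None,
    long_axis: np.ndarray,
    omega_min: float = 0.5,
    expected_sign: float = 1.0,
) -> np.ndarray:
    """Mediolateral (flexion) axis from a sagittal-plane calibration movement.

    Gyroscope samples with ``|w| >= omega_min`` rad/s are kept, their unit
    directions sign-aligned to the dominant direction, and averaged with
    magnitude weights.  The component along ``long_axis`` is projected out.
    ``expected_sign`` (+1/-1) encodes the protocol knowledge of the segment's
    initial rotation direction about its own +Z (to the subject's right)
    during the movement window; the sign of the returned axis is fixed from
    the first above-threshold movement stroke.
    """
    w = rec if window is None else rec.window(*window)
    omega = w.gyro
    mag = np.linalg.norm(omega, axis=1)
    keep = mag >= omega_min
    if keep.sum() < 5 or mag.max(initial=0.0) < 1.0:
        raise InsufficientExcitationError(
            "calibration window lacks rotation (need peak |w| > 1 rad/s)"
        )
    # first contiguous above-threshold run = the first movement stroke,
    # used below to fix the axis sign from the initial rotation direction
    first = int(np.argmax(keep))
    run_end = first + int(np.argmin(keep[first:])) if not keep[first:].all() else len(keep)
    stroke = omega[first:run_end]
    omega, mag = omega[keep], mag[keep]
    units = omega / mag[:, np.newaxis]
    ref = units[np.argmax(mag)]
    signs = np.where(units @ ref >= 0.0, 1.0, -1.0)
    axis = (signs * mag) @ units
    long_axis = np.asarray(long_axis, dtype=float)
    long_axis = long_axis / np.linalg.norm(long_axis)
    axis = axis - np.dot(axis, long_axis) * long_axis
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise InsufficientExcitationError("rotation axis collinear with the long axis")
    axis = axis / n
    proj = float((np.linalg.norm(stroke, axis=1) * (stroke @ axis)).sum())
    if proj * expected_sign < 0:
        axis = -axis
    return axis


def build_sensor_body_cal(
    long_axis: np.ndarray, flexion_axis: np.ndarray, method: str, segment: str = ""
) -> BodyCal:
    """Assemble the sensor-body calibration quaternion q_IMU-sf^IMU-scbf.

    Y is the longitudinal axis, Z the flexion axis orthogonalized against Y,
    X = Y x Z completes the right-handed triad.
    """
    if method not in ("A", "B", "C"):
        raise InvalidInputError("method must be 'A', 'B' or 'C'")
    y = np.asarray(long_axis, dtype=float)
    z = np.asarray(flexion_axis, dtype=float)
    y = y / np.linalg.norm(y)
    z = z - np.dot(z, y) * y
    n = np.linalg.norm(z)
    if n < np.sin(np.radians(10.0)):
        raise DegenerateFrameError(
            "flexion axis within 10 deg of the longitudinal axis"
        )
    z = z / n
    x = np.cross(y, z)
    return BodyCal(qfrom_axes(x, y, z), method=method, segment=segment)


def hand_eye_from_compass(
    tail: np.ndarray,
    tip: np.ndarray,
    max_tilt_deg: float = 10.0,
) -> np.ndarray:
    """Hand-eye quaternion ``q_GRF^IRF`` from a static marker compass.

    ``tail`` and ``tip`` are (n, 3) trajectories (mm, GRF) of the compass
    end markers, the tip pointing magnetic north.  GRF and IRF share the
    gravity vertical (+Z), so the hand-eye is the pure yaw that maps the IRF
    magnetic-north axis (+X by convention) onto the measured compass heading.
    """
    axis = (np.asarray(tip, float) - np.asarray(tail, float)).mean(axis=0)
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise DegenerateFrameError("compass markers coincide")
    axis = axis / n
    horiz = np.hypot(axis[0], axis[1])
    if np.degrees(np.arctan2(abs(axis[2]), horiz)) > max_tilt_deg:
        raise DegenerateFrameError(
            f"compass axis tilted more than {max_tilt_deg} deg from horizontal"
        )
    heading = np.arctan2(axis[1], axis[0])
    return np.array([np.cos(heading / 2.0), 0.0, 0.0, np.sin(heading / 2.0)])


def static_frame_alignment(
    body_series: QuaternionSeries, sensor_series: QuaternionSeries, segment: str = ""
) -> BodyCal:
    """Static-trial marker alignment: the mean of ``qrel(body_t, sensor_t)``.

    Returns ``q_AL-mcbf^sensor`` as a BodyCal with method "mcbf".  Down
    stream, the sensor series is right-multiplied by the *inverse* of this
    quaternion, so that the marker-calibrated sensor body frame coincides
    with the anatomical frame during the static trial.
    """
    if len(body_series) != len(sensor_series):
        raise FrameMismatchError(
            f"series lengths differ: {len(body_series)} vs {len(sensor_series)}"
        )
    rel = qrel(body_series.q, sensor_series.q)
    mean = qmean(QuaternionSeries(body_series.timestamps, rel))
    return BodyCal(mean, method="mcbf", segment=segment)


def series_angular_rate(s: QuaternionSeries) -> np.ndarray:
    """Angular-rate magnitude (rad/s) of a quaternion series, by central
    differences of the sign-continuous components."""
    s = enforce_continuity(s)
    qd = np.gradient(s.q, s.timestamps, axis=0)
    # body-frame rate: (0, w) = 2 * q^-1 (x) qdot; only the magnitude is used
    qi = qinv(s.q)
    a, b = qi, qd
    aw, ax, ay, az = a[:, 0], a[:, 1], a[:, 2], a[:, 3]
    bw, bx, by, bz = b[:, 0], b[:, 1], b[:, 2], b[:, 3]
    vx = aw * bx + ax * bw + ay * bz - az * by
    vy = aw * by - ax * bz + ay * bw + az * bx
    vz = aw * bz + ax * by - ay * bx + az * bw
    return 2.0 * np.sqrt(vx * vx + vy * vy + vz * vz)


def estimate_sync_offset(
    imu: ImuRecord, rmc_series: QuaternionSeries, max_lag: int = 250
) -> SyncResult:
    """Integer-sample lag (250 Hz) between the IMU and marker streams.

    Cross-correlates the down-sampled gyroscope magnitude with the angular-
    rate magnitude differentiated from the cluster-frame series over a
    shared dynamic event.  Positive lag means the IMU stream starts
    ``lag`` marker samples later than the markers.
    """
    factor = max(1, int(round(imu.rate / rmc_series.rate)))
    g = np.linalg.norm(imu.gyro, axis=1)[::factor]
    m = series_angular_rate(rmc_series)
    g = g - g.mean()
    m = m - m.mean()
    if np.max(np.abs(g), initial=0.0) < 0.05 or np.max(np.abs(m), initial=0.0) < 0.05:
        raise InsufficientExcitationError("no shared dynamic event to synchronize on")
    n = min(len(g), len(m))
    corr = sp_signal.correlate(g[:n], m[:n], mode="full")
    lags = sp_signal.correlation_lags(n, n, mode="full")
    ok = np.abs(lags) <= max_lag
    lag = int(lags[ok][np.argmax(corr[ok])])
    return SyncResult(lag=lag)


def downsample_series(
    s: QuaternionSeries, factor: int = 2, offset: int = 0, timestamps: np.ndarray | None = None
) -> QuaternionSeries:
    """Keep every ``factor``-th sample, starting at ``offset``.

    ``timestamps``, when given, rewrites the clock to the marker timeline
    (truncated/padded checks are the caller's responsibility).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise InvalidInputError("downsampling factor must be a positive integer")
    if offset < 0:
        raise InvalidInputError("offset must be non-negative")
    q = s.q[offset::factor]
    ts = s.timestamps[offset::factor]
    if timestamps is not None:
        timestamps = np.asarray(timestamps, dtype=float)
        n = min(len(q), len(timestamps))
        q, ts = q[:n], timestamps[:n]
    return replace(s, timestamps=ts, q=q)
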