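"""Raw IMU streams to sensor orientation via the gradient-descent filter.

The filter estimates ``q_t(IRF -> IMU-sf)``: the orientation of the sensor
frame relative to the inertial reference frame (IRF) whose Z axis points up
(opposite gravity) and whose X axis points along the horizontal component of
the magnetic field.  The update combines gyroscope integration with a
gradient-descent correction toward the accelerometer (gravity) and
magnetometer (earth-field) observations, weighted by the gain ``beta``
(default 0.043).  With ``beta = 0`` the filter reduces to pure gyroscope
integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptyInputError,
    InvalidCalibrationError,
    InvalidInputError,
    NotStaticError,
)
from .quat import QuaternionSeries, enforce_continuity, qfrom_matrix, qnorm

GRAVITY = 9.81  # m/s^2

__all__ = [
    "ImuRecord",
    "ImuCalParams",
    "FilterConfig",
    "apply_imu_calibration",
    "estimate_static_cal",
    "madgwick_step",
    "run_orientation_filter",
    "triad_init",
]


@dataclass
class ImuRecord:
    """Synchronized tri-axial gyro/accel/mag streams for one sensor.

    gyro in rad/s, accel in m/s^2 (specific force, reads +g when static),
    mag in arbitrary units.  Timestamps must be uniform.
    """

    timestamps: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    sensor_id: str = ""

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        n = len(self.timestamps)
        for name, ch in (("gyro", self.gyro), ("accel", self.accel), ("mag", self.mag)):
            if ch.shape != (n, 3):
                raise InvalidInputError(f"{name} shape {ch.shape} != ({n}, 3)")
        if n >= 2:
            dts = np.diff(self.timestamps)
            dt = dts[0]
            if dt <= 0 or np.any(np.abs(dts - dt) > max(1e-6 * dt, 1e-9)):
                raise InvalidInputError("timestamps are not uniformly spaced")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def window(self, t0: float, t1: float) -> "ImuRecord":
        m = (self.timestamps >= t0 - 1e-9) & (self.timestamps <= t1 + 1e-9)
        return replace(
            self,
            timestamps=self.timestamps[m],
            gyro=self.gyro[m],
            accel=self.accel[m],
            mag=self.mag[m],
        )


@dataclass
class ImuCalParams:
    """Per-sensor offset/scale/misalignment compensation parameters."""

    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    misalignment: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float)
        self.accel_bias = np.asarray(self.accel_bias, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.misalignment = np.asarray(self.misalignment, dtype=float)
        if np.any(self.scale <= 0.5) or np.any(self.scale >= 2.0):
            raise InvalidCalibrationError("scale factors outside (0.5, 2.0)")
        if abs(np.linalg.det(self.misalignment)) < 1e-6:
            raise InvalidCalibrationError("singular misalignment matrix")


@dataclass
class FilterConfig:
    """Orientation filter settings.

    beta: gradient-descent gain (dimensionless, default 0.043).
    q0: initial quaternion, or "auto" for a TRIAD solution on the first
        static second of the record.
    warmup: seconds of convergence window excluded from downstream RMSD.
    use_mag: include the magnetometer correction (IRF heading is magnetic);
        disable for IMU-only sensitivity studies.
    """

    beta: float = 0.043
    q0: np.ndarray | str = "auto"
    warmup: float = 5.0
    use_mag: bool = True

    def __post_init__(self):
        if self.beta < 0:
            raise InvalidInputError("beta must be >= 0")


def apply_imu_calibration(raw: ImuRecord, cal: ImuCalParams) -> ImuRecord:
    """Compensate offsets, scale factors and triad misalignment.

    Per channel: ``corrected = M @ (diag(scale) @ (raw - bias))``; the
    magnetometer is additionally normalized per sample (its gain is
    irrelevant to the filter).
    """
    M = cal.misalignment
    gyro = (M @ (cal.scale[:, None] * (raw.gyro - cal.gyro_bias).T)).T
    accel = (M @ (cal.scale[:, None] * (raw.accel - cal.accel_bias).T)).T
    mag = raw.mag.copy()
    n = np.linalg.norm(mag, axis=1, keepdims=True)
    np.divide(mag, n, out=mag, where=n > 0)
    return replace(raw, gyro=gyro, accel=accel, mag=mag)


def estimate_static_cal(static: ImuRecord, gyro_rms_max: float = 0.02) -> ImuCalParams:
    """Estimate offsets from a static recording.

    Gyro bias is the channel mean; a single accelerometer scale factor makes
    the mean static specific force equal one g.  Misalignment stays identity
    (externally supplied parameters can be loaded instead when a full
    multi-position calibration is available).
    """
    if len(static) == 0:
        raise EmptyInputError("empty static record")
    rms = float(np.sqrt(np.mean(np.sum(static.gyro**2, axis=1))))
    if rms > gyro_rms_max:
        raise NotStaticError(f"gyro RMS {rms:.3f} rad/s exceeds static guard {gyro_rms_max}")
    gyro_bias = static.gyro.mean(axis=0)
    acc_mag = float(np.linalg.norm(static.accel.mean(axis=0)))
    if acc_mag < 1e-6:
        raise NotStaticError("static accelerometer mean is zero; cannot scale to gravity")
    return ImuCalParams(gyro_bias=gyro_bias, scale=np.full(3, GRAVITY / acc_mag))


def madgwick_step(q, gyro, accel, mag, dt: float, beta: float, use_mag: bool = True):
    """One filter update.

    Integrates the gyroscope rate and descends the gradient of the combined
    gravity + magnetic-field objective, the earth-field reference being
    flattened to ``(b_x, 0, b_z)`` each step.  A zero-norm accelerometer or
    magnetometer sample skips the corresponding correction term for this
    step (gyro-only).
    """
    q1, q2, q3, q4 = float(q[0]), float(q[1]), float(q[2]), float(q[3])
    gx, gy, gz = float(gyro[0]), float(gyro[1]), float(gyro[2])
    if not all(map(math.isfinite, (q1, q2, q3, q4, gx, gy, gz, dt, beta))):
        raise InvalidInputError("non-finite filter input")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")

    # Rate of change from gyroscope: 0.5 * q (x) (0, w)
    qd1 = 0.5 * (-q2 * gx - q3 * gy - q4 * gz)
    qd2 = 0.5 * (q1 * gx + q3 * gz - q4 * gy)
    qd3 = 0.5 * (q1 * gy - q2 * gz + q4 * gx)
    qd4 = 0.5 * (q1 * gz + q2 * gy - q3 * gx)

    ax, ay, az = float(accel[0]), float(accel[1]), float(accel[2])
    an = math.sqrt(ax * ax + ay * ay + az * az)
    s1 = s2 = s3 = s4 = 0.0
    have_grad = False
    if beta > 0.0 and an > 0.0:
        ax, ay, az = ax / an, ay / an, az / an
        # Gravity objective f_g = R(q)^T e_z - a and its Jacobian transpose.
        f1 = 2.0 * (q2 * q4 - q1 * q3) - ax
        f2 = 2.0 * (q1 * q2 + q3 * q4) - ay
        f3 = 2.0 * (0.5 - q2 * q2 - q3 * q3) - az
        s1 += -2.0 * q3 * f1 + 2.0 * q2 * f2
        s2 += 2.0 * q4 * f1 + 2.0 * q1 * f2 - 4.0 * q2 * f3
        s3 += -2.0 * q1 * f1 + 2.0 * q4 * f2 - 4.0 * q3 * f3
        s4 += 2.0 * q2 * f1 + 2.0 * q3 * f2
        have_grad = True

    if beta > 0.0 and use_mag:
        mx, my, mz = float(mag[0]), float(mag[1]), float(mag[2])
        mn = math.sqrt(mx * mx + my * my + mz * mz)
        if mn > 0.0:
            mx, my, mz = mx / mn, my / mn, mz / mn
            # Field measured in IRF coordinates, flattened to (bx, 0, bz).
            hx = mx * (1 - 2 * (q3 * q3 + q4 * q4)) + 2 * my * (q2 * q3 - q1 * q4) + 2 * mz * (
                q2 * q4 + q1 * q3
            )
            hy = 2 * mx * (q2 * q3 + q1 * q4) + my * (1 - 2 * (q2 * q2 + q4 * q4)) + 2 * mz * (
                q3 * q4 - q1 * q2
            )
            hz = 2 * mx * (q2 * q4 - q1 * q3) + 2 * my * (q3 * q4 + q1 * q2) + mz * (
                1 - 2 * (q2 * q2 + q3 * q3)
            )
            bx = math.sqrt(hx * hx + hy * hy)
            bz = hz
            f4 = 2 * bx * (0.5 - q3 * q3 - q4 * q4) + 2 * bz * (q2 * q4 - q1 * q3) - mx
            f5 = 2 * bx * (q2 * q3 - q1 * q4) + 2 * bz * (q1 * q2 + q3 * q4) - my
            f6 = 2 * bx * (q1 * q3 + q2 * q4) + 2 * bz * (0.5 - q2 * q2 - q3 * q3) - mz
            s1 += (
                -2 * bz * q3 * f4
                + (-2 * bx * q4 + 2 * bz * q2) * f5
                + 2 * bx * q3 * f6
            )
            s2 += (
                2 * bz * q4 * f4
                + (2 * bx * q3 + 2 * bz * q1) * f5
                + (2 * bx * q4 - 4 * bz * q2) * f6
            )
            s3 += (
                (-4 * bx * q3 - 2 * bz * q1) * f4
                + (2 * bx * q2 + 2 * bz * q4) * f5
                + (2 * bx * q1 - 4 * bz * q3) * f6
            )
            s4 += (
                (-4 * bx * q4 + 2 * bz * q2) * f4
                + (-2 * bx * q1 + 2 * bz * q3) * f5
                + 2 * bx * q2 * f6
            )
            have_grad = True

    if have_grad:
        sn = math.sqrt(s1 * s1 + s2 * s2 + s3 * s3 + s4 * s4)
        if sn > 0.0:
            qd1 -= beta * s1 / sn
            qd2 -= beta * s2 / sn
            qd3 -= beta * s3 / sn
            qd4 -= beta * s4 / sn

    q1 += qd1 * dt
    q2 += qd2 * dt
    q3 += qd3 * dt
    q4 += qd4 * dt
    n = math.sqrt(q1 * q1 + q2 * q2 + q3 * q3 + q4 * q4)
    return np.array([q1 / n, q2 / n, q3 / n, q4 / n])


def triad_init(accel_mean, mag_mean, use_mag: bool = True) -> np.ndarray:
    """Deterministic orientation from static accel/mag means (TRIAD).

    Builds the IRF axes in sensor coordinates: Z up from gravity, X along
    the horizontal field component.  Without a usable magnetometer the
    heading is fixed arbitrarily (tilt only).
    """
    g = np.asarray(accel_mean, dtype=float)
    gn = np.linalg.norm(g)
    if gn < 1e-9:
        raise InvalidInputError("zero accelerometer mean in TRIAD init")
    z_s = g / gn  # IRF up, in sensor coords
    m = np.asarray(mag_mean, dtype=float)
    mh = m - np.dot(m, z_s) * z_s
    if use_mag and np.linalg.norm(mh) > 1e-9:
        x_s = mh / np.linalg.norm(mh)
    else:
        # arbitrary horizontal axis
        seed = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(seed, z_s)) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        x_s = seed - np.dot(seed, z_s) * z_s
        x_s /= np.linalg.norm(x_s)
    y_s = np.cross(z_s, x_s)
    # Rows of R(q_IRF^sf) are the IRF axes expressed in sensor coordinates.
    return qfrom_matrix(np.vstack([x_s, y_s, z_s]))


def run_orientation_filter(rec: ImuRecord, cfg: FilterConfig | None = None) -> QuaternionSeries:
    """Run the filter over a calibrated record.

    Returns the sign-continuous series ``q_t(IRF -> IMU-sf)`` at the
    record's sample rate.  With ``q0="auto"`` the initial orientation is a
    TRIAD solution on the first second of data (the protocol starts every
    recording with a static standing phase).
    """
    cfg = cfg or FilterConfig()
    if len(rec) < 2:
        raise EmptyInputError("record too short to filter")
    if rec.timestamps[-1] - rec.timestamps[0] < cfg.warmup:
        raise EmptyInputError(
            f"record shorter than the {cfg.warmup} s warm-up window"
        )
    dt = rec.dt
    if isinstance(cfg.q0, str):
        if cfg.q0 != "auto":
            raise InvalidInputError(f"unknown q0 mode {cfg.q0!r}")
        n0 = max(1, min(len(rec), int(round(1.0 / dt))))
        q = triad_init(
            rec.accel[:n0].mean(axis=0), rec.mag[:n0].mean(axis=0), use_mag=cfg.use_mag
        )
    else:
        q = qnorm(np.asarray(cfg.q0, dtype=float))

    out = np.empty((len(rec), 4))
    out[0] = q
    for i in range(1, len(rec)):
        q = madgwick_step(
            q, rec.gyro[i], rec.accel[i], rec.mag[i], dt, cfg.beta, use_mag=cfg.use_mag
        )
        out[i] = q
    series = QuaternionSeries(
        timestamps=rec.timestamps.copy(),
        q=out,
        source_frame="IRF",
        target_frame="IMU-sf",
    )
    return enforce_continuity(series)
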