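"""Ground-truthed synthetic datasets: bone and skin kinematics, marker
trajectories and raw IMU signals for the nine-trial protocol.

The generator emulates a lower-body capture session: five instrumented
segments (pelvis, both thighs, both shanks), sixteen anatomical-landmark
markers, a four-marker rigid cluster (RMC) per segment carrying the IMU,
plus the calibration recordings (neutral pose, calibration movements A-C,
marker compass, static trial).  Every quantity the pipeline later estimates
is known exactly and returned as ground truth.

World conventions
-----------------
The camera global frame (GRF) has Z up and X along the subject's neutral
anterior direction.  Body-segment frames follow ISB: X anterior, Y
proximal/up, Z to the subject's right; in the neutral pose every body frame
has the constant orientation ``Q_NEUTRAL`` relative to GRF.  The earth
magnetic field has a configurable declination (the heading the hand-eye
calibration must recover) and dip angle.

Error injection
---------------
* Soft tissue artefact: the skin (RMC/IMU) frame is the bone frame
  right-composed with a rotation about a fixed per-segment axis whose angle
  is a dimensionless gain times the flexion of the joint nearest the
  sensor, plus an exponentially damped 15 Hz oscillation triggered at
  impact events (footstrike, landing, ball contact).
* Body-frame definition error: calibration-trial kinematics are performed
  with the movement plane rotated about the segment's longitudinal axis by
  a known angle, so the sensor-body calibration recovers a body frame
  rotated by exactly that angle — a constant, per-subject frame error.
* IMU imperfections: gyroscope bias, white noise on all channels and an
  optional local magnetic dipole disturbance.

Landmark markers ride on the bone poses and RMC markers on the skin poses,
so the relative artefact between the two marker groups equals the injected
STA exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .errors import InvalidConfigError, InvalidInputError
from .frames import MarkerSet
from .orientation import GRAVITY, ImuRecord
from .quat import (
    QuaternionSeries,
    enforce_continuity,
    qfrom_axes,
    qfrom_axis_angle,
    qinv,
    qmul,
    qrotate,
)

__all__ = [
    "SEGMENTS",
    "MOVEMENTS",
    "TRIAL_CATALOGUE",
    "Q_NEUTRAL",
    "SyntheticConfig",
    "SkeletonGeometry",
    "MotionTruth",
    "TrialData",
    "SubjectTruth",
    "SubjectData",
    "SyntheticDataset",
    "default_geometry",
    "generate_segment_motion",
    "inject_sta",
    "synthesize_marker_set",
    "synthesize_imu_signals",
    "generate_trial",
    "generate_dataset",
]

SEGMENTS = ("pelvis", "thigh_l", "thigh_r", "shank_l", "shank_r")
MOVEMENTS = ("squat", "squat_jump", "walk", "run", "sprint", "kick")

#: The nine movement trials of the protocol: name -> (family, intensity).
TRIAL_CATALOGUE = {
    "squat": ("squat", 1.0),
    "squat_jump_50": ("squat_jump", 0.5),
    "squat_jump_100": ("squat_jump", 1.0),
    "walk": ("walk", 1.0),
    "run_50": ("run", 0.5),
    "sprint_100": ("sprint", 1.0),
    "pass": ("kick", 0.4),
    "cross": ("kick", 0.7),
    "shot": ("kick", 1.0),
}

#: Orientation of every body frame relative to GRF in the neutral pose:
#: body X (anterior) -> GRF X, body Y (up) -> GRF Z, body Z (right) -> GRF -Y.
Q_NEUTRAL = qfrom_axes((1.0, 0.0, 0.0), (0.0, 0.0, 1.0), (0.0, -1.0, 0.0))

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])


@dataclass
class SyntheticConfig:
    """Study conditions for one trial (or a whole dataset).

    All defaults are the generator's standing conditions; the seed fixes
    every random draw.
    """

    movement: str = "squat"
    intensity: float = 1.0
    duration: float = 14.0  # s, including the static lead-in
    lead_in: float = 6.0  # s of static standing before the movement
    seed: int = 0
    segments: tuple[str, ...] = SEGMENTS
    # soft tissue artefact
    sta_gain: float = 0.08  # deg STA per deg joint flexion
    impact_amplitude_deg: float = 4.0  # high-frequency STA at impacts
    impact_freq_hz: float = 15.0
    impact_tau_s: float = 0.05
    # IMU imperfections
    gyro_noise: float = 0.002  # rad/s, white, per axis
    accel_noise: float = 0.03  # m/s^2
    mag_noise: float = 0.005  # a.u. (field normalized to 1)
    gyro_bias_sigma: float = 0.005  # rad/s, per-subject constant bias draw
    # body-frame definition error (axial misexecution of the calibrations)
    mounting_error_deg: float = 15.0
    # marker measurement noise
    marker_noise_mm: float = 0.0
    # earth magnetic field in GRF
    mag_declination_deg: float = 20.0
    mag_dip_deg: float = 60.0
    mag_disturbance: dict | None = None  # {"position_mm", "moment", "amplitude"}
    # sample rates
    imu_rate: float = 500.0
    marker_rate: float = 250.0

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise InvalidConfigError("intensity must be in [0, 1]")
        if self.movement not in MOVEMENTS:
            raise InvalidConfigError(
                f"unknown movement {self.movement!r}; expected one of {MOVEMENTS}"
            )

    @property
    def mag_field(self) -> np.ndarray:
        """Unit earth-field vector in GRF (declination from +X, dip down)."""
        dec = np.radians(self.mag_declination_deg)
        dip = np.radians(self.mag_dip_deg)
        return np.array(
            [np.cos(dip) * np.cos(dec), np.cos(dip) * np.sin(dec), -np.sin(dip)]
        )

    @property
    def hand_eye_true(self) -> np.ndarray:
        """True q_GRF^IRF: a yaw by the magnetic declination."""
        half = np.radians(self.mag_declination_deg) / 2.0
        return np.array([np.cos(half), 0.0, 0.0, np.sin(half)])


@dataclass
class SkeletonGeometry:
    """Local marker coordinates (mm) and sensor mounts per segment.

    ``landmarks`` maps segment -> {marker name: position in the segment
    frame, origin at the proximal joint}.  ``rmc_local`` holds the four
    cluster-marker coordinates in the cluster (= IMU sensor) frame.
    ``mounts`` maps segment -> (position in segment frame, q_body^sensor).
    """

    landmarks: dict[str, dict[str, np.ndarray]]
    rmc_local: np.ndarray
    mounts: dict[str, tuple[np.ndarray, np.ndarray]]
    inter_asis: float
    thigh_length: float
    shank_length: float
    hjc_local: dict[str, np.ndarray]

    @property
    def leg_length(self) -> float:
        return self.thigh_length + self.shank_length + 90.0


def default_geometry() -> SkeletonGeometry:
    """An adult-male lower-body geometry consistent with the marker set.

    The hips sit exactly at the Bell-regression offsets from the ASIS
    midpoint so the marker-derived hip joint centre is exact by
    construction.
    """
    iad, lth, lsh = 240.0, 420.0, 430.0
    hjc = {
        "R": iad * np.array([-0.19, -0.30, 0.36]),
        "L": iad * np.array([-0.19, -0.30, -0.36]),
    }
    pelvis = {
        "LASIS": np.array([0.0, 0.0, -iad / 2]),
        "RASIS": np.array([0.0, 0.0, iad / 2]),
        "LPSIS": np.array([-130.0, 0.0, -60.0]),
        "RPSIS": np.array([-130.0, 0.0, 60.0]),
    }
    landmarks = {"pelvis": pelvis}
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        landmarks[f"thigh_{side.lower()}"] = {
            f"{side}THIGH": np.array([-35.0, -lth / 2, 0.0]),
            f"{side}MEP": np.array([0.0, -lth, -sgn * 55.0]),
            f"{side}LEP": np.array([0.0, -lth, sgn * 55.0]),
        }
        landmarks[f"shank_{side.lower()}"] = {
            f"{side}SHANK": np.array([30.0, -lsh / 2, 0.0]),
            f"{side}MMAL": np.array([0.0, -lsh, -sgn * 40.0]),
            f"{side}LMAL": np.array([0.0, -lsh, sgn * 40.0]),
        }
    rmc_local = np.array(
        [
            [45.0, 30.0, 0.0],
            [-45.0, 32.0, 6.0],
            [-45.0, -30.0, 0.0],
            [45.0, -32.0, 8.0],
        ]
    )
    mounts = {
        "pelvis": (
            np.array([-150.0, 15.0, 0.0]),
            qmul(qfrom_axis_angle(_EY, np.radians(180.0)), qfrom_axis_angle(_EX, np.radians(12.0))),
        ),
        "thigh_l": (
            np.array([20.0, -170.0, -70.0]),
            qmul(qfrom_axis_angle(_EY, np.radians(-75.0)), qfrom_axis_angle(_EZ, np.radians(8.0))),
        ),
        "thigh_r": (
            np.array([20.0, -170.0, 70.0]),
            qmul(qfrom_axis_angle(_EY, np.radians(75.0)), qfrom_axis_angle(_EZ, np.radians(-8.0))),
        ),
        "shank_l": (
            np.array([25.0, -140.0, -50.0]),
            qmul(qfrom_axis_angle(_EY, np.radians(-60.0)), qfrom_axis_angle(_EX, np.radians(10.0))),
        ),
        "shank_r": (
            np.array([25.0, -140.0, 50.0]),
            qmul(qfrom_axis_angle(_EY, np.radians(60.0)), qfrom_axis_angle(_EX, np.radians(-10.0))),
        ),
    }
    return SkeletonGeometry(
        landmarks=landmarks,
        rmc_local=rmc_local,
        mounts=mounts,
        inter_asis=iad,
        thigh_length=lth,
        shank_length=lsh,
        hjc_local=hjc,
    )


# ---------------------------------------------------------------------------
# movement profiles
# ---------------------------------------------------------------------------


def _ramp(t, t0, dur):
    """Smooth 0 -> 1 transition (C1) over [t0, t0 + dur]."""
    u = np.clip((t - t0) / max(dur, 1e-9), 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * u)


def _bump(t, t0, dur, amp):
    """C1 bump: 0 -> amp -> 0 over [t0, t0 + dur]."""
    u = np.clip((t - t0) / max(dur, 1e-9), 0.0, 1.0)
    return amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


@dataclass
class MotionTruth:
    """Ground-truth kinematics of one trial at the internal (IMU) rate."""

    timestamps: np.ndarray
    bone: dict[str, QuaternionSeries]  # q_t(GRF -> segment), per segment
    origins: dict[str, np.ndarray]  # proximal-joint position (mm, GRF)
    flexion_deg: dict[str, np.ndarray]  # STA driver per segment
    impacts: list[tuple[float, dict[str, float]]]  # (time, per-segment factor)
    angles: dict[str, np.ndarray] = field(default_factory=dict)  # raw joint angles


def _joint_angles(cfg: SyntheticConfig, t: np.ndarray) -> dict:
    """Joint-angle profiles (degrees) and pelvis height offset (mm)."""
    s = cfg.intensity
    lead = cfg.lead_in
    n = len(t)
    zeros = np.zeros(n)
    ang = {
        "pelvis_tilt": zeros.copy(),
        "pelvis_list": zeros.copy(),
        "pelvis_rot": zeros.copy(),
        "hip_l": zeros.copy(),
        "hip_r": zeros.copy(),
        "knee_l": zeros.copy(),
        "knee_r": zeros.copy(),
        "dz_mm": zeros.copy(),
        "dx_mm": zeros.copy(),
    }
    impacts: list[tuple[float, dict[str, float]]] = []
    t_end = t[-1] - 0.5
    env = _ramp(t, lead, 1.0) * (1.0 - _ramp(t, t_end, 0.5))
    ta = t - lead

    fam = cfg.movement
    if fam == "squat":
        f = 0.4
        a_knee = 100.0 * s
        c = env * 0.5 * (1.0 - np.cos(2.0 * np.pi * f * np.clip(ta, 0.0, None)))
        ang["knee_l"] = ang["knee_r"] = a_knee * c
        ang["hip_l"] = ang["hip_r"] = 0.85 * a_knee * c
        ang["pelvis_tilt"] = -0.25 * a_knee * c
        ang["anchor_feet"] = True
    elif fam == "squat_jump":
        a_knee = 90.0 * s
        h_mm = 350.0 * s  # jump height
        v0 = np.sqrt(2.0 * GRAVITY * h_mm / 1000.0)  # m/s at takeoff
        tf = 2.0 * v0 / GRAVITY  # flight time
        t_desc, d_desc = lead, 0.9
        t_push = t_desc + d_desc + 0.1
        d_push = 0.30
        t_to = t_push + d_push  # takeoff
        t_land = t_to + tf
        d_abs = 0.7
        # knee/hip: descend, extend for push-off, absorb the landing
        desc = _ramp(t, t_desc, d_desc) - _ramp(t, t_push, d_push)
        absorb = _bump(t, t_land, d_abs, 0.65 * a_knee)
        ang["knee_l"] = ang["knee_r"] = a_knee * desc + absorb
        ang["hip_l"] = ang["hip_r"] = 0.85 * (a_knee * desc + absorb)
        ang["pelvis_tilt"] = -0.22 * (a_knee * desc + absorb)
        # pelvis height: crouch, Hermite push to takeoff velocity, free
        # flight parabola, Hermite absorption back to standing
        drop = 3.0 * a_knee
        dz = -drop * _ramp(t, t_desc, d_desc)
        push = CubicHermiteSpline([t_push, t_to], [-drop, -30.0], [0.0, v0 * 1000.0])
        m_push = (t >= t_push) & (t < t_to)
        dz[m_push] = push(t[m_push])
        m_fly = (t >= t_to) & (t < t_land)
        tau = t[m_fly] - t_to
        dz[m_fly] = -30.0 + (v0 * tau - 0.5 * GRAVITY * tau**2) * 1000.0
        land = CubicHermiteSpline([t_land, t_land + d_abs], [-30.0, 0.0], [-v0 * 1000.0, 0.0])
        m_land = t >= t_land
        dz[m_land] = land(np.minimum(t[m_land], t_land + d_abs))
        ang["dz_mm"] = dz
        impacts.append(
            (t_land, {"shank_l": 1.0, "shank_r": 1.0, "thigh_l": 0.8, "thigh_r": 0.8, "pelvis": 0.5})
        )
    elif fam in ("walk", "run", "sprint"):
        if fam == "walk":
            f, a_hip, a_knee, bob = 0.9, 25.0 * s, 40.0 * s, 15.0 * s
            imp_scale = 0.3
        elif fam == "run":
            f = 1.2 + 0.6 * s
            a_hip, a_knee, bob = 45.0 * s, 80.0 * s, 40.0 * s
            imp_scale = 0.7
        else:  # sprint
            f = 1.6 + 0.6 * s
            a_hip, a_knee, bob = 55.0 * s, 100.0 * s, 50.0 * s
            imp_scale = 1.0
        ph = 2.0 * np.pi * f * np.clip(ta, 0.0, None)
        ang["hip_r"] = env * a_hip * np.sin(ph)
        ang["hip_l"] = env * a_hip * np.sin(ph + np.pi)
        ang["knee_r"] = env * a_knee * 0.5 * (1.0 - np.cos(ph + 0.4))
        ang["knee_l"] = env * a_knee * 0.5 * (1.0 - np.cos(ph + np.pi + 0.4))
        ang["pelvis_rot"] = env * 8.0 * s * np.sin(ph)
        ang["pelvis_list"] = env * 3.0 * s * np.sin(ph + 0.5)
        ang["pelvis_tilt"] = -env * 6.0 * s * (0.5 + 0.5 * np.sin(2.0 * ph))
        ang["dz_mm"] = -env * bob * (0.5 + 0.5 * np.sin(2.0 * ph + 1.0))
        # footstrikes: one per leg per cycle
        cycle = 1.0 / f
        k = 1
        while lead + k * cycle < t_end:
            tr = lead + (k - 0.75) * cycle  # right footstrike
            tl = lead + (k - 0.25) * cycle
            fac = imp_scale
            if tr > lead + 1.0:
                impacts.append((tr, {"shank_r": fac, "thigh_r": 0.7 * fac, "pelvis": 0.3 * fac}))
            if tl > lead + 1.0:
                impacts.append((tl, {"shank_l": fac, "thigh_l": 0.7 * fac, "pelvis": 0.3 * fac}))
            k += 1
    elif fam == "kick":
        a_back = 50.0 * s  # hip extension in the backswing
        a_fwd = 80.0 * s  # hip flexion at follow-through
        a_kneeb = 110.0 * s  # knee flexion during the swing
        t_plant = lead + 0.8  # stance (left) foot plant
        t_swing = t_plant + 0.35  # forward swing onset
        d_swing = 0.35 - 0.15 * s  # faster swing at higher intensity
        t_ball = t_swing + d_swing  # ball contact
        ang["hip_r"] = (
            -a_back * _ramp(t, t_plant - 0.3, 0.6)
            + (a_back + a_fwd) * _ramp(t, t_swing, d_swing + 0.15)
            - a_fwd * _ramp(t, t_ball + 0.5, 0.8)
        )
        ang["knee_r"] = _bump(t, t_plant - 0.2, (t_ball - t_plant) + 1.0, a_kneeb)
        ang["hip_l"] = 12.0 * s * _bump(t, t_plant - 0.4, 2.5, 1.0)
        ang["knee_l"] = 18.0 * s * _bump(t, t_plant - 0.4, 2.5, 1.0)
        ang["pelvis_rot"] = s * (
            -10.0 * _ramp(t, t_plant, 0.5)
            + 18.0 * _ramp(t, t_swing, d_swing + 0.3)
            - 8.0 * _ramp(t, t_ball + 0.5, 0.8)
        )
        ang["pelvis_tilt"] = -6.0 * s * _bump(t, t_plant - 0.3, 2.0, 1.0)
        ang["dz_mm"] = -40.0 * s * _bump(t, t_plant - 0.3, 2.0, 1.0)
        impacts.append((t_plant, {"shank_l": 1.0, "thigh_l": 0.7, "pelvis": 0.4}))
        impacts.append(
            (t_ball, {"shank_r": 1.2 * s + 0.3, "thigh_r": 1.0 * s + 0.2, "pelvis": 0.3})
        )
    else:  # pragma: no cover - guarded by the config validator
        raise InvalidConfigError(f"unknown movement {fam!r}")
    return {"angles": ang, "impacts": impacts}


def _chain_orientations(ang: dict, n: int) -> dict[str, np.ndarray]:
    """Bone orientation stacks (n, 4) from the joint-angle profiles."""
    rad = np.radians
    q_p = qmul(
        qmul(
            np.broadcast_to(Q_NEUTRAL, (n, 4)),
            qfrom_axis_angle(_EY, rad(ang["pelvis_rot"])),
        ),
        qmul(
            qfrom_axis_angle(_EX, rad(ang["pelvis_list"])),
            qfrom_axis_angle(_EZ, rad(ang["pelvis_tilt"])),
        ),
    )
    out = {"pelvis": q_p}
    for side in ("l", "r"):
        q_t = qmul(q_p, qfrom_axis_angle(_EZ, rad(ang[f"hip_{side}"])))
        q_s = qmul(q_t, qfrom_axis_angle(_EZ, -rad(ang[f"knee_{side}"])))
        out[f"thigh_{side}"] = q_t
        out[f"shank_{side}"] = q_s
    return out


def _motion_from_angles(
    cfg: SyntheticConfig,
    t: np.ndarray,
    ang: dict,
    impacts: list,
    geometry: SkeletonGeometry,
    frame_error: dict[str, np.ndarray] | None = None,
) -> MotionTruth:
    n = len(t)
    q = _chain_orientations(ang, n)
    if frame_error:
        for seg, qe in frame_error.items():
            if seg in q:
                q[seg] = qmul(q[seg], np.broadcast_to(qinv(qe), q[seg].shape))

    pelvis_origin = np.column_stack(
        [ang["dx_mm"], np.zeros(n), np.full(n, 1000.0) + ang["dz_mm"]]
    )

    def _chain(p0):
        origins = {"pelvis": p0}
        ankles = []
        for side in ("l", "r"):
            hip = p0 + qrotate(q["pelvis"], geometry.hjc_local[side.upper()])
            knee = hip + qrotate(
                q[f"thigh_{side}"], np.array([0.0, -geometry.thigh_length, 0.0])
            )
            origins[f"thigh_{side}"] = hip
            origins[f"shank_{side}"] = knee
            ankles.append(
                knee + qrotate(q[f"shank_{side}"], np.array([0.0, -geometry.shank_length, 0.0]))
            )
        return origins, 0.5 * (ankles[0] + ankles[1])

    origins, ankle_mid = _chain(pelvis_origin)
    if ang.get("anchor_feet"):
        # feet planted: translate the pelvis so the mean ankle stays put
        origins, _ = _chain(pelvis_origin - (ankle_mid - ankle_mid[0]))

    flexion = {
        "pelvis": 2.0 * np.abs(ang["pelvis_tilt"] - ang["pelvis_tilt"][0]),
        "thigh_l": np.abs(ang["knee_l"]),
        "thigh_r": np.abs(ang["knee_r"]),
        "shank_l": np.abs(ang["knee_l"]),
        "shank_r": np.abs(ang["knee_r"]),
    }
    bone = {
        seg: QuaternionSeries(t, q[seg], source_frame="GRF", target_frame=seg)
        for seg in cfg.segments
    }
    return MotionTruth(
        timestamps=t,
        bone=bone,
        origins={seg: origins[seg] for seg in cfg.segments},
        flexion_deg={seg: flexion[seg] for seg in cfg.segments},
        impacts=impacts,
        angles=ang,
    )


def generate_segment_motion(
    cfg: SyntheticConfig,
    geometry: SkeletonGeometry | None = None,
    frame_error: dict[str, np.ndarray] | None = None,
) -> MotionTruth:
    """Smooth bone kinematics for one trial of the configured movement.

    ``frame_error``, when given, right-composes each bone orientation with
    the inverse of the per-segment frame-error quaternion — the mechanism
    for misexecuted calibration movements (see the module docstring).
    """
    geometry = geometry or default_geometry()
    n = int(round(cfg.duration * cfg.imu_rate)) + 1
    t = np.arange(n) / cfg.imu_rate
    prof = _joint_angles(cfg, t)
    return _motion_from_angles(cfg, t, prof["angles"], prof["impacts"], geometry, frame_error)


# ---------------------------------------------------------------------------
# error injection and signal synthesis
# ---------------------------------------------------------------------------


def inject_sta(
    bone: QuaternionSeries,
    joint_flexion_deg: np.ndarray,
    gain: float,
    axis: np.ndarray,
    impacts: list[tuple[float, float]] | None = None,
    impact_amplitude_deg: float = 0.0,
    impact_freq_hz: float = 15.0,
    impact_tau_s: float = 0.05,
) -> tuple[QuaternionSeries, np.ndarray]:
    """Compose a bone series with a soft-tissue rotation.

    ``skin_t = bone_t (x) delta_t`` where ``delta_t`` rotates about the
    fixed unit ``axis`` (segment frame) by ``gain * flexion(t)`` degrees
    plus a damped oscillation of ``impact_amplitude_deg * factor`` for each
    impact ``(time, factor)``.  Returns the skin series and the injected
    STA angle series ``|angle(delta_t)|`` in degrees.
    """
    t = bone.timestamps
    angle_deg = gain * np.asarray(joint_flexion_deg, dtype=float)
    if len(angle_deg) != len(t):
        raise InvalidInputError("flexion series length mismatch")
    for t_i, factor in impacts or []:
        tau = t - t_i
        m = tau >= 0
        angle_deg = angle_deg + np.where(
            m,
            impact_amplitude_deg
            * factor
            * np.exp(-np.clip(tau, 0.0, None) / impact_tau_s)
            * np.sin(2.0 * np.pi * impact_freq_hz * tau),
            0.0,
        )
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    delta = qfrom_axis_angle(axis, np.radians(angle_deg))
    skin = QuaternionSeries(
        t, qmul(bone.q, delta), source_frame=bone.source_frame, target_frame="skin"
    )
    return skin, np.abs(angle_deg)


def synthesize_marker_set(
    motion: MotionTruth,
    skin: dict[str, QuaternionSeries],
    geometry: SkeletonGeometry,
    mounts: dict[str, tuple[np.ndarray, np.ndarray]],
    marker_rate: float = 250.0,
    noise_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    extra_markers: dict[str, np.ndarray] | None = None,
) -> MarkerSet:
    """Landmark and cluster marker trajectories at the camera rate.

    Landmark markers follow the bone poses; the four RMC markers per
    segment follow the skin poses through the sensor mount, so the relative
    artefact between the marker groups is exactly the injected STA.
    """
    dt = float(motion.timestamps[1] - motion.timestamps[0])
    step = max(1, int(round(1.0 / (dt * marker_rate))))
    sl = slice(None, None, step)
    ts = motion.timestamps[sl]
    positions: dict[str, np.ndarray] = {}
    for seg in motion.bone:
        origin = motion.origins[seg][sl]
        qb = motion.bone[seg].q[sl]
        for name, local in geometry.landmarks[seg].items():
            positions[name] = origin + qrotate(qb, local)
        qs = skin[seg].q[sl]
        pos_mount, q_b2s = mounts[seg]
        q_rmc = qmul(qs, np.broadcast_to(q_b2s, qs.shape))
        base = origin + qrotate(qs, pos_mount)
        for i, c in enumerate(geometry.rmc_local, start=1):
            positions[f"{seg}_RMC{i}"] = base + qrotate(q_rmc, c)
    for name, traj in (extra_markers or {}).items():
        positions[name] = traj[sl]
    if noise_mm > 0.0:
        rng = rng or np.random.default_rng(0)
        for name in positions:
            positions[name] = positions[name] + rng.normal(0.0, noise_mm, positions[name].shape)
    return MarkerSet(ts - ts[0], positions)


def _deriv(x: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """Five-point central finite differences along axis 0."""
    out = x
    for _ in range(order):
        d = np.empty_like(out)
        d[2:-2] = (out[:-4] - 8 * out[1:-3] + 8 * out[3:-1] - out[4:]) / (12.0 * dt)
        d[:2] = (out[1:3] - out[0:2]) / dt
        d[-2:] = (out[-2:] - out[-3:-1]) / dt
        out = d
    return out


def synthesize_imu_signals(
    skin: QuaternionSeries,
    origin_mm: np.ndarray,
    mount: tuple[np.ndarray, np.ndarray],
    cfg: SyntheticConfig,
    gyro_bias: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sensor_id: str = "",
) -> ImuRecord:
    """Raw IMU streams for one sensor riding the skin pose.

    gyro: body-rate of the sensor frame plus bias and noise; accel: the
    specific force (linear acceleration minus gravity) at the sensor
    position, expressed in the sensor frame; mag: the (optionally
    disturbed) earth field in the sensor frame.
    """
    pos_mount, q_b2s = mount
    t = skin.timestamps
    dt = float(t[1] - t[0])
    q_sf = qmul(enforce_continuity(skin).q, np.broadcast_to(q_b2s, skin.q.shape))
    # angular rate in the sensor frame: (0, w) = 2 q^-1 (x) qdot
    qd = _deriv(q_sf, dt)
    qi = qinv(q_sf)
    aw, ax_, ay_, az_ = qi[:, 0], qi[:, 1], qi[:, 2], qi[:, 3]
    bw, bx_, by_, bz_ = qd[:, 0], qd[:, 1], qd[:, 2], qd[:, 3]
    omega = 2.0 * np.column_stack(
        [
            aw * bx_ + ax_ * bw + ay_ * bz_ - az_ * by_,
            aw * by_ - ax_ * bz_ + ay_ * bw + az_ * bx_,
            aw * bz_ + ax_ * by_ - ay_ * bx_ + az_ * bw,
        ]
    )
    # sensor position (m) and its second derivative
    p = (origin_mm + qrotate(skin.q, pos_mount)) / 1000.0
    acc = _deriv(p, dt, order=2)
    g_vec = np.array([0.0, 0.0, -GRAVITY])
    f_world = acc - g_vec  # specific force in GRF
    R_cols = qinv(q_sf)
    f_sensor = qrotate(R_cols, f_world)
    field = np.broadcast_to(cfg.mag_field, p.shape).copy()
    if cfg.mag_disturbance:
        d = cfg.mag_disturbance
        r = p - np.asarray(d["position_mm"], dtype=float) / 1000.0
        rn = np.linalg.norm(r, axis=1, keepdims=True)
        rn = np.maximum(rn, 0.05)
        rhat = r / rn
        mhat = np.asarray(d["moment"], dtype=float)
        mhat = mhat / np.linalg.norm(mhat)
        amp = float(d.get("amplitude", 0.5))
        field = field + amp * (3.0 * rhat * (rhat @ mhat)[:, None] - mhat) / (rn / 0.3) ** 3
    mag_sensor = qrotate(R_cols, field)
    if rng is not None:
        omega = omega + rng.normal(0.0, cfg.gyro_noise, omega.shape)
        f_sensor = f_sensor + rng.normal(0.0, cfg.accel_noise, f_sensor.shape)
        mag_sensor = mag_sensor + rng.normal(0.0, cfg.mag_noise, mag_sensor.shape)
    if gyro_bias is not None:
        omega = omega + np.asarray(gyro_bias, dtype=float)
    return ImuRecord(
        timestamps=t.copy(), gyro=omega, accel=f_sensor, mag=mag_sensor, sensor_id=sensor_id
    )


# ---------------------------------------------------------------------------
# trials and datasets
# ---------------------------------------------------------------------------

#: Protocol knowledge: initial rotation direction of each segment about its
#: own +Z (subject's right) during the calibration movement windows.
CALIBRATION_SIGNS = {
    "A": {"pelvis": -1.0, "thigh_l": 1.0, "thigh_r": 1.0, "shank_l": 1.0, "shank_r": 1.0},
    "B": {"pelvis": -1.0, "thigh_l": 1.0, "thigh_r": 1.0, "shank_l": -1.0, "shank_r": -1.0},
    "C": {"pelvis": -1.0, "thigh_l": -1.0, "thigh_r": -1.0, "shank_l": -1.0, "shank_r": -1.0},
}


def _calib_angles(kind: str, cfg: SyntheticConfig, t: np.ndarray) -> dict:
    """Joint-angle profiles for the calibration recordings.

    Two brisk repetitions per movement so every segment exceeds the
    functional-calibration excitation threshold (peak |w| > 1 rad/s).
    """
    n = len(t)
    zeros = np.zeros(n)
    ang = {k: zeros.copy() for k in (
        "pelvis_tilt", "pelvis_list", "pelvis_rot",
        "hip_l", "hip_r", "knee_l", "knee_r", "dz_mm", "dx_mm",
    )}
    if kind == "calibA":
        # bow (pelvis), then right and left thigh rises with a stiff knee
        for t0 in (6.0, 8.0):
            ang["pelvis_tilt"] += _bump(t, t0, 1.3, -40.0)
        for t0 in (10.5, 12.5):
            ang["hip_r"] += _bump(t, t0, 1.4, 75.0)
            ang["knee_r"] += _bump(t, t0, 1.4, 0.45 * 75.0)
        for t0 in (15.5, 17.5):
            ang["hip_l"] += _bump(t, t0, 1.4, 75.0)
            ang["knee_l"] += _bump(t, t0, 1.4, 0.45 * 75.0)
    elif kind == "calibB":
        for t0 in (6.0, 8.5):
            knee = _bump(t, t0, 1.4, 100.0)
            ang["knee_l"] += knee
            ang["knee_r"] += knee
            ang["hip_l"] += 0.72 * knee
            ang["hip_r"] += 0.72 * knee
            ang["pelvis_tilt"] += -0.32 * knee
        ang["anchor_feet"] = True
    elif kind == "calibC":
        # inclined plank: the whole body pivots forward about the ankles;
        # the pelvis rotation propagates down the chain unchanged
        for t0 in (6.0, 8.5):
            ang["pelvis_tilt"] += _bump(t, t0, 1.4, -32.0)
        ang["anchor_feet"] = True
    elif kind in ("neutral", "static"):
        pass
    else:
        raise InvalidConfigError(f"unknown calibration recording {kind!r}")
    return ang


#: Per-segment analysis windows (s) of the calibration movement phases.
CALIBRATION_WINDOWS = {
    "calibA": {
        "pelvis": (5.8, 9.6),
        "thigh_r": (10.3, 14.2), "shank_r": (10.3, 14.2),
        "thigh_l": (15.3, 19.2), "shank_l": (15.3, 19.2),
    },
    "calibB": {seg: (5.8, 10.2) for seg in SEGMENTS},
    "calibC": {seg: (5.8, 10.2) for seg in SEGMENTS},
}

CALIBRATION_DURATIONS = {"calibA": 20.5, "calibB": 11.0, "calibC": 11.0,
                         "neutral": 8.0, "static": 8.0}


@dataclass
class TrialData:
    """One synthetic recording: IMU streams, markers, windows, ground truth."""

    name: str
    role: str  # neutral | calibA | calibB | calibC | compass | static | movement
    movement: str = ""
    intensity: float = 0.0
    repetition: int = 0
    imu: dict[str, ImuRecord] = field(default_factory=dict)
    markers: MarkerSet | None = None
    static_window: tuple[float, float] = (0.5, 5.0)
    movement_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    analysis_window: tuple[float, float] | None = None
    bone: dict[str, QuaternionSeries] = field(default_factory=dict)
    skin: dict[str, QuaternionSeries] = field(default_factory=dict)
    sta_deg: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SubjectTruth:
    """Everything injected for one subject, for oracle checks."""

    q_mount: dict[str, np.ndarray]  # q_body^sensor per segment
    q_frame_error: dict[str, np.ndarray]  # calibration frame error per segment
    frame_error_deg: float
    gyro_bias: dict[str, np.ndarray]
    sta_axis: dict[str, np.ndarray]
    hand_eye: np.ndarray  # true q_GRF^IRF


@dataclass
class SubjectData:
    subject_id: str
    trials: list[TrialData]
    truth: SubjectTruth
    inter_asis: float
    leg_length: float

    def trial(self, name: str) -> TrialData:
        for tr in self.trials:
            if tr.name == name:
                return tr
        raise KeyError(name)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    geometry: SkeletonGeometry
    subjects: list[SubjectData]


def _subject_randomization(cfg: SyntheticConfig, rng: np.random.Generator, geometry):
    """Per-subject mounting, frame error, STA axes and sensor biases."""
    q_mount, q_err, bias, sta_axis = {}, {}, {}, {}
    for seg in cfg.segments:
        _, q_b2s = geometry.mounts[seg]
        tweak = qfrom_axis_angle(rng.normal(size=3), np.radians(rng.uniform(2.0, 10.0)))
        q_mount[seg] = qmul(q_b2s, tweak)
        # frame-definition error: axial rotation about the longitudinal axis
        sign = 1.0 if rng.random() < 0.5 else -1.0
        q_err[seg] = qfrom_axis_angle(_EY, sign * np.radians(cfg.mounting_error_deg))
        bias[seg] = rng.normal(0.0, cfg.gyro_bias_sigma, 3)
        ax = rng.normal(size=3)
        sta_axis[seg] = ax / np.linalg.norm(ax)
    return SubjectTruth(
        q_mount=q_mount,
        q_frame_error=q_err,
        frame_error_deg=cfg.mounting_error_deg,
        gyro_bias=bias,
        sta_axis=sta_axis,
        hand_eye=cfg.hand_eye_true,
    )


def generate_trial(
    cfg: SyntheticConfig,
    role: str,
    truth: SubjectTruth,
    geometry: SkeletonGeometry,
    rng: np.random.Generator | None,
    name: str = "",
    repetition: int = 0,
) -> TrialData:
    """One complete recording (IMU + markers + ground truth).

    ``role`` is "movement" for the configured movement trial, or one of
    the calibration recordings.  Calibration recordings carry the injected
    frame error; all recordings carry STA, mounting and sensor errors.
    """
    if role == "compass":
        n = int(round(4.0 * cfg.marker_rate)) + 1
        ts = np.arange(n) / cfg.marker_rate
        heading = np.radians(cfg.mag_declination_deg)
        direction = np.array([np.cos(heading), np.sin(heading), 0.0])
        tail = np.tile(np.array([0.0, 0.0, 50.0]), (n, 1)) - 400.0 * direction
        tip = tail + 800.0 * direction
        if rng is not None and cfg.marker_noise_mm > 0:
            tail = tail + rng.normal(0.0, cfg.marker_noise_mm, tail.shape)
            tip = tip + rng.normal(0.0, cfg.marker_noise_mm, tip.shape)
        markers = MarkerSet(ts, {"COMPASS_TAIL": tail, "COMPASS_TIP": tip})
        return TrialData(name=name or "compass", role="compass", markers=markers)

    if role == "movement":
        motion = generate_segment_motion(cfg, geometry)
        duration = cfg.duration
        windows = {}
    else:
        duration = CALIBRATION_DURATIONS[role]
        n = int(round(duration * cfg.imu_rate)) + 1
        t = np.arange(n) / cfg.imu_rate
        ang = _calib_angles(role, cfg, t)
        frame_error = truth.q_frame_error if role.startswith("calib") else None
        motion = _motion_from_angles(cfg, t, ang, [], geometry, frame_error)
        windows = CALIBRATION_WINDOWS.get(role, {})

    skin, sta = {}, {}
    for seg in cfg.segments:
        seg_impacts = [(ti, f[seg]) for ti, f in motion.impacts if seg in f]
        skin[seg], sta[seg] = inject_sta(
            motion.bone[seg],
            motion.flexion_deg[seg],
            cfg.sta_gain,
            truth.sta_axis[seg],
            impacts=seg_impacts,
            impact_amplitude_deg=cfg.impact_amplitude_deg,
            impact_freq_hz=cfg.impact_freq_hz,
            impact_tau_s=cfg.impact_tau_s,
        )

    mounts = {seg: (geometry.mounts[seg][0], truth.q_mount[seg]) for seg in cfg.segments}
    markers = synthesize_marker_set(
        motion, skin, geometry, mounts,
        marker_rate=cfg.marker_rate, noise_mm=cfg.marker_noise_mm, rng=rng,
    )
    imu = {
        seg: synthesize_imu_signals(
            skin[seg], motion.origins[seg], mounts[seg], cfg,
            gyro_bias=truth.gyro_bias[seg], rng=rng, sensor_id=seg,
        )
        for seg in cfg.segments
    }
    step = max(1, int(round(cfg.imu_rate / cfg.marker_rate)))
    sl = slice(None, None, step)
    bone250 = {
        seg: QuaternionSeries(
            motion.timestamps[sl], motion.bone[seg].q[sl], "GRF", seg
        )
        for seg in cfg.segments
    }
    skin250 = {
        seg: QuaternionSeries(motion.timestamps[sl], skin[seg].q[sl], "GRF", "skin")
        for seg in cfg.segments
    }
    sta250 = {seg: sta[seg][sl] for seg in cfg.segments}
    return TrialData(
        name=name or role,
        role=role,
        movement=cfg.movement if role == "movement" else "",
        intensity=cfg.intensity if role == "movement" else 0.0,
        repetition=repetition,
        imu=imu,
        markers=markers,
        static_window=(0.5, 5.0),
        movement_windows=windows,
        analysis_window=(cfg.lead_in + 0.5, duration - 0.2) if role == "movement" else None,
        bone=bone250,
        skin=skin250,
        sta_deg=sta250,
    )


def generate_dataset(
    cfg: SyntheticConfig | None = None,
    n_subjects: int = 1,
    repetitions: int = 1,
    trials: dict[str, tuple[str, float]] | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """A full multi-subject dataset for the nine-trial protocol.

    ``trials`` maps trial names to (movement family, intensity); the
    default is the full nine-trial catalogue.  Each subject gets randomized
    mounting rotations, frame errors, STA axes and gyro biases, all
    recorded in the returned ground truth; the seed fixes everything.
    """
    cfg = cfg or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    trials = trials if trials is not None else dict(TRIAL_CATALOGUE)
    geometry = default_geometry()
    root_rng = np.random.default_rng(cfg.seed)
    subjects = []
    for si in range(n_subjects):
        rng = np.random.default_rng(root_rng.integers(2**31))
        truth = _subject_randomization(cfg, rng, geometry)
        trial_list = []
        for role in ("neutral", "calibA", "calibB", "calibC", "compass", "static"):
            trial_list.append(
                generate_trial(replace(cfg, movement="squat", intensity=0.0),
                               role, truth, geometry, rng)
            )
        for tname, (family, intensity) in trials.items():
            dur = {"squat_jump": 12.0, "kick": 11.0}.get(family, cfg.duration)
            tcfg = replace(cfg, movement=family, intensity=intensity, duration=dur)
            for rep in range(1, repetitions + 1):
                trial_list.append(
                    generate_trial(
                        tcfg, "movement", truth, geometry, rng,
                        name=f"{tname}_rep{rep}", repetition=rep,
                    )
                )
                trial_list[-1].movement = tname
        subjects.append(
            SubjectData(
                subject_id=f"subject{si + 1:02d}",
                trials=trial_list,
                truth=truth,
                inter_asis=geometry.inter_asis,
                leg_length=geometry.leg_length,
            )
        )
    return SyntheticDataset(config=cfg, geometry=geometry, subjects=subjects)
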