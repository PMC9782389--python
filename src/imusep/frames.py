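"""Optoelectronic frames: anatomical-landmark body frames and cluster frames.

Builds, from low-pass-filtered marker trajectories in the camera global
reference frame (GRF):

* per-segment anatomical body frames (AL-mcbf) for the pelvis, thighs and
  shanks, following the ISB axis convention — X anterior, Y proximal/up,
  Z to the subject's right;
* per-sample rigid-marker-cluster frames (RMC-sf) via a least-squares rigid
  rotation fit, the cluster's local coordinates being defined so that the
  cluster frame coincides with the IMU sensor frame.

Marker positions are in millimetres at the camera rate (250 Hz nominal).
Gap filling is out of scope: NaN samples raise a GapError.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DegenerateFrameError, GapError, InvalidInputError
from .quat import QuaternionSeries, enforce_continuity, qfrom_matrix

__all__ = [
    "MarkerSet",
    "SubjectAnthropometry",
    "LANDMARK_NAMES",
    "BELL_FRACTIONS",
    "lowpass_markers",
    "cluster_frame",
    "hip_joint_center",
    "pelvis_frame",
    "thigh_frame",
    "shank_frame",
]

#: The 16 anatomical-landmark markers of the lower-body set.
LANDMARK_NAMES = (
    "LASIS", "RASIS", "LPSIS", "RPSIS",
    "LTHIGH", "RTHIGH", "LMEP", "RMEP", "LLEP", "RLEP",
    "LSHANK", "RSHANK", "LMMAL", "RMMAL", "LLMAL", "RLMAL",
)

#: Hip-joint-centre regression offsets from the ASIS midpoint, as fractions
#: of the inter-ASIS distance, in the pelvic anatomical frame
#: (X anterior, Y up, Z right); the Z fraction is mirrored for the left hip.
BELL_FRACTIONS = (-0.19, -0.30, 0.36)


@dataclass
class MarkerSet:
    """Named marker position trajectories (mm) at a common uniform rate."""

    timestamps: np.ndarray
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = len(self.timestamps)
        clean = {}
        for name, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (n, 3):
                raise InvalidInputError(f"marker {name!r} shape {pos.shape} != ({n}, 3)")
            clean[name] = pos
        self.positions = clean

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[name]

    def window(self, t0: float, t1: float) -> "MarkerSet":
        m = (self.timestamps >= t0 - 1e-9) & (self.timestamps <= t1 + 1e-9)
        return MarkerSet(self.timestamps[m], {k: v[m] for k, v in self.positions.items()})

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.positions]
        if missing:
            raise GapError(f"missing markers: {missing}")
        for n in names:
            bad = np.where(~np.isfinite(self.positions[n]).all(axis=1))[0]
            if bad.size:
                t0, t1 = self.timestamps[bad[0]], self.timestamps[bad[-1]]
                raise GapError(
                    f"marker {n!r} has {bad.size} NaN samples between "
                    f"t={t0:.3f}s and t={t1:.3f}s (gap filling is out of scope)"
                )


@dataclass
class SubjectAnthropometry:
    """Leg length and inter-ASIS distance in millimetres."""

    leg_length: float
    inter_asis_distance: float

    def __post_init__(self):
        if self.leg_length <= 0 or self.inter_asis_distance <= 0:
            raise InvalidInputError("anthropometry measures must be positive")
        if self.leg_length <= self.inter_asis_distance:
            raise InvalidInputError("leg length must exceed the inter-ASIS distance")


def lowpass_markers(ms: MarkerSet, order: int = 4, fc: float = 8.0) -> MarkerSet:
    """Zero-phase low-pass Butterworth filtering of every trajectory.

    A Butterworth of the given order is applied forward and backward
    (zero net phase), with reflected end padding.  Defaults: order 4,
    cut-off 8 Hz at the 250 Hz marker rate.
    """
    for name in ms.positions:
        ms.require(name)
    sos = signal.butter(order, fc, btype="low", fs=ms.rate, output="sos")
    out = {
        name: signal.sosfiltfilt(sos, pos, axis=0, padtype="even")
        for name, pos in ms.positions.items()
    }
    return MarkerSet(ms.timestamps.copy(), out)


def _kabsch_batch(world: np.ndarray, local: np.ndarray) -> np.ndarray:
    """Batched least-squares rotations local -> world.

    world: (n, k, 3) marker positions per sample; local: (k, 3) reference
    coordinates.  Returns (n, 3, 3) proper rotation matrices minimizing
    ``sum_i |R local_i - world_i|^2`` after centering.
    """
    lc = local - local.mean(axis=0)
    wc = world - world.mean(axis=1, keepdims=True)
    H = np.einsum("ki,nkj->nij", lc, wc)  # (n, 3, 3) cross-covariance
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nij,nkj->nik", np.transpose(Vt, (0, 2, 1)), U))
    D = np.repeat(np.eye(3)[np.newaxis], len(H), axis=0)
    D[:, 2, 2] = np.sign(det)
    # R maps local to world: R = V D U^T with H = local^T world = U S Vt
    return np.einsum("nji,njk,nlk->nil", Vt, D, U)


def cluster_frame(
    ms: MarkerSet,
    marker_names: tuple[str, ...],
    geometry: np.ndarray,
    rigid_warn_mm: float = 5.0,
) -> QuaternionSeries:
    """Per-sample rigid rotation from cluster-local coordinates to GRF.

    ``geometry`` holds the local coordinates (mm) of the cluster markers in
    the cluster frame, which by construction equals the IMU sensor frame, so
    the result is ``q_t(GRF -> RMC-sf)``.  A rigid-body fit residual above
    ``rigid_warn_mm`` triggers a rigidity warning.
    """
    ms.require(*marker_names)
    geometry = np.asarray(geometry, dtype=float)
    if len(marker_names) < 3 or geometry.shape != (len(marker_names), 3):
        raise InvalidInputError("need >= 3 markers with matching local geometry")
    gc = geometry - geometry.mean(axis=0)
    s = np.linalg.svd(gc, compute_uv=False)
    if s[1] < 1e-6 * max(s[0], 1.0):
        raise DegenerateFrameError("cluster geometry is collinear")
    world = np.stack([ms[n] for n in marker_names], axis=1)  # (n, k, 3)
    R = _kabsch_batch(world, geometry)
    fitted = np.einsum("nij,kj->nki", R, gc) + world.mean(axis=1, keepdims=True)
    resid = np.linalg.norm(fitted - world, axis=-1).max()
    if resid > rigid_warn_mm:
        warnings.warn(
            f"rigid-body residual {resid:.1f} mm exceeds {rigid_warn_mm} mm",
            stacklevel=2,
        )
    q = np.array([qfrom_matrix(Ri) for Ri in R])
    return enforce_continuity(
        QuaternionSeries(ms.timestamps.copy(), q, source_frame="GRF", target_frame="RMC-sf")
    )


def _pelvis_axes(lasis, rasis, lpsis, rpsis):
    """ISB pelvic axes per sample. Returns (x, y, z) arrays of shape (n, 3)."""
    mid_asis = 0.5 * (lasis + rasis)
    mid_psis = 0.5 * (lpsis + rpsis)
    z = rasis - lasis
    zn = np.linalg.norm(z, axis=-1, keepdims=True)
    if np.any(zn < 1e-9):
        raise DegenerateFrameError("ASIS markers coincide")
    z = z / zn
    v = mid_asis - mid_psis  # anterior-ish, in the marker plane
    x = v - np.sum(v * z, axis=-1, keepdims=True) * z
    xn = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(xn < 1e-9):
        raise DegenerateFrameError("pelvis markers are collinear")
    x = x / xn
    y = np.cross(z, x)
    return x, y, z


def hip_joint_center(
    ms: MarkerSet,
    side: str,
    anthro: SubjectAnthropometry | None = None,
    fractions: tuple[float, float, float] = BELL_FRACTIONS,
) -> np.ndarray:
    """Hip joint centre trajectory (mm, GRF) from the pelvis markers.

    Regression offsets are fractions of the inter-ASIS distance expressed in
    the pelvic anatomical frame, lateral component mirrored for the left
    side.  ``anthro``, when given, is used only to sanity-check the
    marker-derived inter-ASIS distance.
    """
    if side not in ("L", "R"):
        raise InvalidInputError("side must be 'L' or 'R'")
    ms.require("LASIS", "RASIS", "LPSIS", "RPSIS")
    lasis, rasis = ms["LASIS"], ms["RASIS"]
    x, y, z = _pelvis_axes(lasis, rasis, ms["LPSIS"], ms["RPSIS"])
    iad = np.linalg.norm(rasis - lasis, axis=-1, keepdims=True)
    if anthro is not None:
        measured = float(iad.mean())
        if abs(measured - anthro.inter_asis_distance) > 0.25 * anthro.inter_asis_distance:
            warnings.warn(
                f"marker inter-ASIS distance {measured:.0f} mm deviates from the "
                f"anthropometry value {anthro.inter_asis_distance:.0f} mm",
                stacklevel=2,
            )
    fx, fy, fz = fractions
    if side == "L":
        fz = -fz
    mid_asis = 0.5 * (lasis + rasis)
    return mid_asis + iad * (fx * x + fy * y + fz * z)


def _frames_from_axes(ts, x, y, z, target_frame: str) -> QuaternionSeries:
    """Assemble a GRF->body series from per-sample orthonormal axis columns."""
    R = np.stack([x, y, z], axis=-1)
    q = np.array([qfrom_matrix(Ri) for Ri in R])
    return enforce_continuity(
        QuaternionSeries(np.asarray(ts, dtype=float).copy(), q, "GRF", target_frame)
    )


def pelvis_frame(ms: MarkerSet) -> QuaternionSeries:
    """Pelvic anatomical frame series ``q_t(GRF -> AL-mcbf pelvis)``.

    Z along RASIS-LASIS (to the right), X anterior in the plane of the ASIS
    midpoint and PSIS midpoint, Y up completing the right-handed triad.
    """
    ms.require("LASIS", "RASIS", "LPSIS", "RPSIS")
    x, y, z = _pelvis_axes(ms["LASIS"], ms["RASIS"], ms["LPSIS"], ms["RPSIS"])
    return _frames_from_axes(ms.timestamps, x, y, z, "AL-mcbf")


def _orthonormal_from_yz(y_raw, z_raw):
    """Y primary (normalized), X = Y x Z_temp, Z recomputed. All (n, 3)."""
    yn = np.linalg.norm(y_raw, axis=-1, keepdims=True)
    if np.any(yn < 1e-9):
        raise DegenerateFrameError("longitudinal axis degenerate")
    y = y_raw / yn
    x = np.cross(y, z_raw)
    xn = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(xn < 1e-9):
        raise DegenerateFrameError("mediolateral axis collinear with longitudinal axis")
    x = x / xn
    z = np.cross(x, y)
    return x, y, z


def thigh_frame(ms: MarkerSet, side: str, hjc: np.ndarray) -> QuaternionSeries:
    """Thigh anatomical frame: Y from the epicondyle midpoint toward the HJC,
    Z lateral (to the subject's right) via the epicondyle line, X anterior."""
    if side not in ("L", "R"):
        raise InvalidInputError("side must be 'L' or 'R'")
    mep, lep = f"{side}MEP", f"{side}LEP"
    ms.require(mep, lep)
    hjc = np.asarray(hjc, dtype=float)
    knee_mid = 0.5 * (ms[mep] + ms[lep])
    y_raw = hjc - knee_mid
    z_temp = (ms[lep] - ms[mep]) if side == "R" else (ms[mep] - ms[lep])
    x, y, z = _orthonormal_from_yz(y_raw, z_temp)
    return _frames_from_axes(ms.timestamps, x, y, z, "AL-mcbf")


def shank_frame(ms: MarkerSet, side: str) -> QuaternionSeries:
    """Shank anatomical frame: Y from the malleoli midpoint toward the
    epicondyle midpoint, Z lateral via the epicondyle line, X anterior."""
    if side not in ("L", "R"):
        raise InvalidInputError("side must be 'L' or 'R'")
    mep, lep = f"{side}MEP", f"{side}LEP"
    mmal, lmal = f"{side}MMAL", f"{side}LMAL"
    ms.require(mep, lep, mmal, lmal)
    ankle_mid = 0.5 * (ms[mmal] + ms[lmal])
    knee_mid = 0.5 * (ms[mep] + ms[lep])
    y_raw = knee_mid - ankle_mid
    z_temp = (ms[lep] - ms[mep]) if side == "R" else (ms[mep] - ms[lep])
    x, y, z = _orthonormal_from_yz(y_raw, z_temp)
    return _frames_from_axes(ms.timestamps, x, y, z, "AL-mcbf")
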