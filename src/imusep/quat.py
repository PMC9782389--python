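"""Quaternion algebra and timestamped quaternion series.

Conventions
-----------
* Quaternions are scalar-first Hamilton quaternions, stored as numpy arrays
  ``[w, x, y, z]``.
* ``q_A^B`` denotes the orientation of frame B relative to frame A: the
  rotation matrix ``R(q_A^B)`` has the axes of B as columns, expressed in A,
  so coordinates transform as ``v_A = R(q_A^B) v_B``.
* Frames chain by right-multiplication: ``q_A^C = q_A^B ⊗ q_B^C``.
* ``q`` and ``-q`` encode the same rotation; all angle computations are
  sign-invariant, and series are made sign-continuous before averaging.

All functions accept either a single quaternion ``(4,)`` or a stack
``(n, 4)`` and broadcast accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateFrameError, EmptyInputError, InvalidInputError

__all__ = [
    "Quaternion",
    "QuaternionSeries",
    "IDENTITY",
    "qnorm",
    "qmul",
    "qinv",
    "qrotate",
    "qfrom_axis_angle",
    "qfrom_axes",
    "qfrom_matrix",
    "qto_matrix",
    "qangle",
    "qrel",
    "enforce_continuity",
    "qmean",
]

Quaternion = np.ndarray  # shape (4,), scalar-first [w, x, y, z]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise InvalidInputError("non-finite component in quaternion input")


def _asq(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise InvalidInputError(f"quaternion must have 4 components, got shape {q.shape}")
    return q


def qnorm(q) -> np.ndarray:
    """Normalize to unit norm. Raises on zero-norm or non-finite input."""
    q = _asq(q)
    _check_finite(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise InvalidInputError("zero-norm quaternion")
    return q / n


def qmul(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b``, renormalized.

    Chains frames: ``q_A^C = qmul(q_A^B, q_B^C)``.
    """
    a, b = _asq(a), _asq(b)
    _check_finite(a, b)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    return qnorm(out)


def qinv(q) -> np.ndarray:
    """Inverse of a unit quaternion (its conjugate)."""
    q = _asq(q)
    _check_finite(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qrotate(q, v) -> np.ndarray:
    """Rotate/re-express a 3-vector: ``v' = q ⊗ v ⊗ q*`` (i.e. ``R(q) v``).

    For ``q = q_A^B`` this maps B-frame coordinates into A-frame coordinates.
    """
    q = _asq(q)
    v = np.asarray(v, dtype=float)
    _check_finite(q, v)
    w = q[..., :1]
    u = q[..., 1:]
    # Rodrigues form of the sandwich product; broadcasts over stacks.
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def qfrom_axis_angle(axis, angle_rad: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    _check_finite(axis)
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise InvalidInputError("zero-length rotation axis")
    axis = axis / n
    angle = np.asarray(angle_rad, dtype=float)
    half = angle[..., np.newaxis] / 2.0
    w = np.cos(half) * np.ones_like(axis[..., :1])
    return np.concatenate([w, np.sin(half) * axis], axis=-1)


def qto_matrix(q) -> np.ndarray:
    """Rotation matrix with the columns of ``R`` = child axes in the parent."""
    q = qnorm(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    row0 = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1)
    row1 = np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1)
    row2 = np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def qfrom_matrix(R) -> np.ndarray:
    """Quaternion of a proper rotation matrix (Shepperd's method), w >= 0."""
    R = np.asarray(R, dtype=float)
    _check_finite(R)
    if R.shape != (3, 3):
        raise InvalidInputError("rotation matrix must be 3x3")
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(R[i, i] - R[j, j] - R[k, k] + 1.0) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    q = qnorm(q)
    return q if q[0] >= 0 else -q


def qfrom_axes(x, y, z, tol: float = 1e-6) -> np.ndarray:
    """Quaternion whose rotation matrix has columns ``x, y, z``.

    The triad must be right-handed and orthonormal within ``tol``; it is
    re-orthogonalized internally (x kept, y projected, z recomputed).
    Returned with deterministic sign ``w >= 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_finite(x, y, z)
    nx, ny, nz = np.linalg.norm(x), np.linalg.norm(y), np.linalg.norm(z)
    if min(nx, ny, nz) < 1e-12:
        raise DegenerateFrameError("zero-length axis")
    x, y, z = x / nx, y / ny, z / nz
    if abs(abs(np.dot(x, y)) - 1.0) < 1e-9 or abs(abs(np.dot(x, z)) - 1.0) < 1e-9:
        raise DegenerateFrameError("collinear axes")
    R = np.column_stack([x, y, z])
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > 1e-3 or np.linalg.det(R) < 0:
        raise DegenerateFrameError(
            f"axes not a right-handed orthonormal triad (deviation {err:.2e})"
        )
    # Gram-Schmidt re-orthogonalization, x as the anchor.
    y = y - np.dot(y, x) * x
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return qfrom_matrix(np.column_stack([x, y, z]))


def qangle(q) -> np.ndarray:
    """Smallest rotation angle of ``q`` in degrees, in [0, 180].

    Sign-invariant: ``qangle(q) == qangle(-q)``.
    """
    q = _asq(q)
    _check_finite(q)
    n = np.linalg.norm(q, axis=-1)
    w = np.clip(np.abs(q[..., 0]) / np.where(n == 0, 1.0, n), 0.0, 1.0)
    return np.degrees(2.0 * np.arccos(w))


def qrel(qa, qb) -> np.ndarray:
    """Relative rotation ``qinv(qa) ⊗ qb``.

    With ``qa = q_G^A`` and ``qb = q_G^B`` (same reference G) this is
    ``q_A^B``, the rotation between the two frames.
    """
    return qmul(qinv(qa), qb)


@dataclass
class QuaternionSeries:
    """A uniformly sampled sequence of unit quaternions between two frames.

    Attributes
    ----------
    timestamps : (n,) seconds, strictly increasing and uniform
    q : (n, 4) scalar-first unit quaternions
    source_frame, target_frame : frame labels (e.g. "GRF", "IMU-sf")
    """

    timestamps: np.ndarray
    q: np.ndarray
    source_frame: str = ""
    target_frame: str = ""

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if len(self.timestamps) != len(self.q):
            raise InvalidInputError("timestamps and quaternions differ in length")
        if len(self.q) and not np.all(np.isfinite(self.q)):
            raise InvalidInputError("non-finite quaternion in series")

    def __len__(self) -> int:
        return len(self.q)

    @property
    def dt(self) -> float:
        if len(self.timestamps) < 2:
            raise EmptyInputError("series too short to define a sample interval")
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def normalized(self) -> "QuaternionSeries":
        return replace(self, q=qnorm(self.q))

    def window(self, t0: float, t1: float) -> "QuaternionSeries":
        """Sub-series with t0 <= t <= t1 (inclusive)."""
        m = (self.timestamps >= t0 - 1e-9) & (self.timestamps <= t1 + 1e-9)
        return replace(self, timestamps=self.timestamps[m], q=self.q[m])


def enforce_continuity(s: QuaternionSeries) -> QuaternionSeries:
    """Flip signs so consecutive quaternions have non-negative dot product.

    The represented rotations are unchanged (q and -q are the same rotation).
    """
    if len(s) == 0:
        raise EmptyInputError("cannot enforce continuity on an empty series")
    q = s.q.copy()
    dots = np.einsum("ij,ij->i", q[:-1], q[1:])
    # cumulative parity of sign flips
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flips[:, np.newaxis]
    return replace(s, q=q)


def qmean(s: QuaternionSeries, dispersion_warn_deg: float = 30.0) -> np.ndarray:
    """Component-wise mean quaternion, renormalized.

    Implements the literal time average used for static-trial alignments:
    sign continuity is enforced first, then the arithmetic mean of the
    components is taken and renormalized.  This is accurate for the
    small-dispersion (static-trial) regime; a dispersion above
    ``dispersion_warn_deg`` about the mean triggers a warning because the
    chordal average degrades for wide spreads.
    """
    if len(s) == 0:
        raise EmptyInputError("cannot average an empty series")
    s = enforce_continuity(s)
    m = qnorm(s.q.mean(axis=0))
    spread = qangle(qrel(np.broadcast_to(m, s.q.shape), s.q))
    if spread.max() > dispersion_warn_deg:
        warnings.warn(
            f"quaternion dispersion {spread.max():.1f} deg exceeds "
            f"{dispersion_warn_deg} deg; arithmetic mean may be inaccurate",
            stacklevel=2,
        )
    return m if m[0] >= 0 else -m
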