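"""Unit-quaternion primitives for sensor-orientation processing.

Quaternions are scalar-first ``(w, x, y, z)`` numpy arrays using the Hamilton
product convention, matching common IMU firmware output. A rotation and its
negation describe the same physical orientation (double cover); all public
functions canonicalize the sign so downstream angles are unambiguous.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "normalize_quaternion",
    "quat_multiply",
    "quat_conjugate",
    "relative_rotation",
    "from_axis_angle",
    "axis_angle",
    "to_rotation_matrix",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

_MIN_NORM = 1e-9


class InvalidQuaternionError(ValueError):
    """Raised for degenerate (near-zero-norm) orientation samples."""


def normalize_quaternion(q, *, context: str = "") -> np.ndarray:
    """Return the unit quaternion with canonical sign (w >= 0).

    Parameters
    ----------
    q : array-like, shape (4,)
        Scalar-first quaternion components.
    context : str
        Identifier (timestamp/sensor) echoed in the error message for
        degenerate samples.
    """
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n <= _MIN_NORM:
        raise InvalidQuaternionError(
            f"near-zero quaternion norm ({n:.3g}){': ' + context if context else ''}"
        )
    q = q / n
    if q[0] < 0:
        q = -q
    return q


def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product a ⊗ b (apply b's rotation, then a's)."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_conjugate(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def relative_rotation(q_proximal, q_distal) -> np.ndarray:
    """Rotation of the distal sensor expressed in the proximal sensor's frame.

    Returns ``q_proximal^{-1} ⊗ q_distal`` so that composing the proximal
    orientation with the result recovers the distal orientation. This is the
    per-joint quantity from which every joint angle is derived.
    """
    qp = normalize_quaternion(q_proximal)
    qd = normalize_quaternion(q_distal)
    return normalize_quaternion(quat_multiply(quat_conjugate(qp), qd))


def from_axis_angle(axis, angle_deg: float) -> np.ndarray:
    """Unit quaternion rotating by ``angle_deg`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = np.deg2rad(angle_deg) / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def axis_angle(q_rel, axis) -> float:
    """Signed twist of ``q_rel`` about ``axis`` via swing–twist decomposition.

    The 3-D relative rotation is reduced to the single rotation axis relevant
    for the joint: the twist component about ``axis`` is isolated and its
    signed angle returned in degrees, in (-180, 180]. A pure swing (no
    component about the axis) yields 0°.
    """
    q = normalize_quaternion(q_rel)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = float(np.dot(q[1:], axis))
    # twist = normalize((w, (v·a) a)); its angle has sign of v·a
    if abs(proj) <= 1e-15 and abs(q[0]) <= 1e-15:
        # 180° pure-swing rotation: no twist about this axis
        return 0.0
    angle = 2.0 * np.degrees(np.arctan2(proj, q[0]))
    if angle <= -180.0:
        angle += 360.0
    elif angle > 180.0:
        angle -= 360.0
    return float(angle)


def to_rotation_matrix(q) -> np.ndarray:
    """3×3 rotation matrix of a unit quaternion."""
    w, x, y, z = normalize_quaternion(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
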