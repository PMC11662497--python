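"""Glove sensor topology, hand model, calibration and joint-angle extraction.

The glove carries eleven nine-axis orientation sensors: a main board on the
dorsum of the hand (the central reference for the proximal phalanges and the
first metacarpal), one sensor on the proximal and one on the middle phalanx
of each long finger, and two thumb sensors (first metacarpal, proximal
phalanx). Each sample is a set of eleven global orientation quaternions at
roughly 25 Hz.

Joint angles are computed by expressing the distal sensor's rotation in the
proximal sensor's frame and reducing that relative rotation to the joint's
rotation axis (swing–twist). Before a run, a *Reset* captures the
zero-degree position; every subsequent orientation is measured relative to
it, so all joint angles on the reset posture are exactly 0°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .quaternions import (
    axis_angle,
    normalize_quaternion,
    quat_conjugate,
    quat_multiply,
    relative_rotation,
)

__all__ = [
    "SensorId",
    "GloveFrame",
    "JointDefinition",
    "HandModel",
    "CalibrationState",
    "JointAngleSeries",
    "default_hand_model",
    "apply_zero_reset",
    "joint_angle_series",
    "FINGERS",
    "NOMINAL_RATE_HZ",
]

NOMINAL_RATE_HZ = 25.0
#: gaps longer than this multiple of the nominal interval are flagged
GAP_FACTOR = 5.0

FINGERS = ("INDEX", "MIDDLE", "RING", "LITTLE")


class SensorId(str, Enum):
    """The eleven glove sensors (dorsal placement)."""

    MAIN = "MAIN"            # dorsum main board: central reference
    TH_MC = "TH_MC"          # thumb, first metacarpal
    TH_PP = "TH_PP"          # thumb, proximal phalanx
    INDEX_PP = "INDEX_PP"
    MIDDLE_PP = "MIDDLE_PP"
    RING_PP = "RING_PP"
    LITTLE_PP = "LITTLE_PP"
    INDEX_MP = "INDEX_MP"    # middle phalanges of the long fingers
    MIDDLE_MP = "MIDDLE_MP"
    RING_MP = "RING_MP"
    LITTLE_MP = "LITTLE_MP"


ALL_SENSORS: tuple[SensorId, ...] = tuple(SensorId)


class CalibrationError(ValueError):
    """Reset frame unusable (missing sensor, degenerate orientation)."""


class StreamError(ValueError):
    """Malformed glove stream (missing sensors, bad timestamps)."""


@dataclass(frozen=True)
class GloveFrame:
    """One timestamped set of the eleven sensor orientations."""

    timestamp: float
    orientations: Mapping[SensorId, np.ndarray]

    def __post_init__(self):
        missing = [s for s in ALL_SENSORS if s not in self.orientations]
        if missing:
            raise StreamError(
                f"frame at t={self.timestamp}: missing sensors "
                + ", ".join(s.value for s in missing)
            )

    def normalized(self) -> "GloveFrame":
        return GloveFrame(
            self.timestamp,
            {
                s: normalize_quaternion(q, context=f"t={self.timestamp} sensor={s.value}")
                for s, q in self.orientations.items()
            },
        )


@dataclass(frozen=True)
class JointDefinition:
    """One named angle: sensor pair, rotation axis (proximal frame), sign."""

    proximal: SensorId
    distal: SensorId
    axis: np.ndarray
    sign: float = 1.0

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if not np.isfinite(n) or n == 0:
            raise ValueError("rotation axis must be non-zero")
        object.__setattr__(self, "axis", a / n)


# Local sensor frames (model convention, not disclosed by the device):
# x = mediolateral (flexion axis), y = longitudinal pointing distal,
# z = palmar-dorsal normal.
FLEXION_AXIS = np.array([1.0, 0.0, 0.0])
PALM_NORMAL_AXIS = np.array([0.0, 0.0, 1.0])
#: oblique thumb-opposition axis, a model constant
OPPOSITION_AXIS = np.array([0.0, 0.5, 0.866])


@dataclass
class HandModel:
    """Named joint/angle definitions mapping sensor pairs to rotation axes."""

    joints: dict[str, JointDefinition]

    def angle_names(self) -> tuple[str, ...]:
        return tuple(self.joints)

    def __getitem__(self, name: str) -> JointDefinition:
        return self.joints[name]


def default_hand_model() -> HandModel:
    """The documented default model.

    MCP angles pair the main board with each proximal phalanx, PIP angles
    pair proximal with middle phalanx (flexion about the mediolateral axis);
    SPREAD is the twist of the little-finger proximal phalanx relative to the
    index about the palm normal; CMC_OPPOSITION is the twist of the thumb
    metacarpal relative to the main board about a fixed oblique axis.
    """
    joints: dict[str, JointDefinition] = {}
    for f in FINGERS:
        joints[f"MCP_{f}"] = JointDefinition(
            SensorId.MAIN, SensorId(f"{f}_PP"), FLEXION_AXIS
        )
        joints[f"PIP_{f}"] = JointDefinition(
            SensorId(f"{f}_PP"), SensorId(f"{f}_MP"), FLEXION_AXIS
        )
    joints["SPREAD"] = JointDefinition(
        SensorId.INDEX_PP, SensorId.LITTLE_PP, PALM_NORMAL_AXIS
    )
    joints["CMC_OPPOSITION"] = JointDefinition(
        SensorId.MAIN, SensorId.TH_MC, OPPOSITION_AXIS
    )
    return HandModel(joints)


@dataclass
class CalibrationState:
    """Reference orientations captured at Reset (the zero-degree position)."""

    reference: dict[SensorId, np.ndarray]
    pattern_amplitudes: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, reset_frame: GloveFrame) -> "CalibrationState":
        try:
            frame = reset_frame.normalized()
        except Exception as exc:  # degenerate quaternion in the reset
            raise CalibrationError(str(exc)) from exc
        return cls(reference=dict(frame.orientations))


def apply_zero_reset(
    stream: Iterable[GloveFrame], reset_frame: GloveFrame
) -> list[GloveFrame]:
    """Re-express every sensor orientation relative to its Reset orientation.

    After calibration the reset posture maps to the identity for every
    sensor, so all joint angles evaluated on it are 0° by construction.
    Idempotent once calibrated against an identity reference.
    """
    cal = CalibrationState.from_frame(reset_frame)
    inv_ref = {s: quat_conjugate(q) for s, q in cal.reference.items()}
    out = []
    for frame in stream:
        frame = frame.normalized()
        out.append(
            GloveFrame(
                frame.timestamp,
                {
                    s: normalize_quaternion(quat_multiply(inv_ref[s], q))
                    for s, q in frame.orientations.items()
                },
            )
        )
    return out


@dataclass
class JointAngleSeries:
    """Time-resolved angle in degrees for one named joint."""

    name: str
    timestamps: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.timestamps.shape != self.angles_deg.shape:
            raise ValueError("timestamps and angles must have equal length")

    def __len__(self) -> int:
        return len(self.timestamps)


def _unwrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Continuity unwrapping so noise near ±180° cannot flip the sign."""
    if len(angles) < 2:
        return angles
    return np.degrees(np.unwrap(np.radians(angles)))


def joint_angle_series(
    stream: Sequence[GloveFrame], model: HandModel, joint: str
) -> JointAngleSeries:
    """Per-frame joint angle for one named angle of a *calibrated* stream.

    Each angle is the signed twist about the joint's rotation axis of the
    relative rotation between its proximal and distal sensor. Timestamps are
    preserved; an empty stream yields an empty series.
    """
    jd = model[joint]
    ts = np.array([f.timestamp for f in stream], dtype=float)
    angles = np.array(
        [
            jd.sign
            * axis_angle(
                relative_rotation(
                    f.orientations[jd.proximal], f.orientations[jd.distal]
                ),
                jd.axis,
            )
            for f in stream
        ],
        dtype=float,
    )
    return JointAngleSeries(joint, ts, _unwrap_degrees(angles))


def flag_gaps(stream: Sequence[GloveFrame], rate_hz: float = NOMINAL_RATE_HZ) -> list[int]:
    """Indices i where the interval t[i] - t[i-1] exceeds 5× nominal."""
    ts = np.array([f.timestamp for f in stream], dtype=float)
    if len(ts) < 2:
        return []
    dt = np.diff(ts)
    return list(np.nonzero(dt > GAP_FACTOR / rate_hz)[0] + 1)
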