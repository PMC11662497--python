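"""Range-of-motion extraction from joint-angle signals.

An assessment is one traversal of a standardized course of 50 alternating
obstacles; half of them demand the movement direction mediated by the
pattern's hand nerve, so a clean run yields 25 analyzable movements. For
each movement the difference between the maximum and the minimum angle is
the Δ-angle; the revised Δ-angle list's mean is the outcome parameter
(mean ROM, degrees).

Three movement patterns are supported:

* ``FINGER_SPREAD`` — spread angle between index and little finger (ulnar).
* ``THUMB_OPPOSITION`` — CMC opposition angle of the thumb (median).
* ``FIST_OPENING`` — composite flexion: mean over the four long fingers of
  (MCP + PIP) bending angle (radial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .kinematics import FINGERS, JointAngleSeries

__all__ = [
    "Pattern",
    "MovementPattern",
    "PATTERNS",
    "CourseConfig",
    "MovementSegment",
    "DeltaAngle",
    "AssessmentResult",
    "pattern_signal",
    "segment_movements",
    "delta_angle",
    "revise_deltas",
    "assessment_rom",
    "extract_assessment",
]


class Pattern(str, Enum):
    FINGER_SPREAD = "FINGER_SPREAD"
    THUMB_OPPOSITION = "THUMB_OPPOSITION"
    FIST_OPENING = "FIST_OPENING"


@dataclass(frozen=True)
class MovementPattern:
    """A movement pattern: contributing angles, aggregation, ceiling."""

    name: Pattern
    angle_names: tuple[str, ...]
    nerve: str                  # metadata only
    ceiling_deg: float          # physiological plausibility ceiling


PATTERNS: dict[Pattern, MovementPattern] = {
    Pattern.FINGER_SPREAD: MovementPattern(
        Pattern.FINGER_SPREAD, ("SPREAD",), "ulnar", 90.0
    ),
    Pattern.THUMB_OPPOSITION: MovementPattern(
        Pattern.THUMB_OPPOSITION, ("CMC_OPPOSITION",), "median", 180.0
    ),
    Pattern.FIST_OPENING: MovementPattern(
        Pattern.FIST_OPENING,
        tuple(f"MCP_{f}" for f in FINGERS) + tuple(f"PIP_{f}" for f in FINGERS),
        "radial",
        360.0,
    ),
}


@dataclass(frozen=True)
class CourseConfig:
    """The standardized obstacle course (50 alternating obstacles)."""

    n_obstacles: int = 50

    def __post_init__(self):
        if self.n_obstacles % 2:
            raise ValueError("n_obstacles must be even (alternating course)")

    @property
    def n_target_movements(self) -> int:
        return self.n_obstacles // 2


@dataclass(frozen=True)
class MovementSegment:
    """One trough→peak excursion in the aggregate signal."""

    start: int
    end: int
    trough_deg: float
    peak_deg: float
    direction: str = "target"

    def __post_init__(self):
        if self.peak_deg < self.trough_deg:
            raise ValueError("segment peak below trough")
        if self.end < self.start:
            raise ValueError("segment indices out of order")


@dataclass(frozen=True)
class DeltaAngle:
    """Per-movement ROM sample: peak − trough, with revision bookkeeping."""

    value_deg: float
    segment: MovementSegment
    kept: bool = True
    discard_reason: str | None = None


@dataclass
class AssessmentResult:
    """Outcome of one glove assessment for one movement pattern."""

    pattern: Pattern
    subject_id: str | None
    timepoint: str | None
    deltas: list[DeltaAngle]
    revised: list[DeltaAngle] = field(default_factory=list)

    @property
    def rom_mean_deg(self) -> float:
        """Mean of the kept Δ-angles; NaN if every movement was discarded."""
        if not self.revised:
            return float("nan")
        return float(np.mean([d.value_deg for d in self.revised]))

    @property
    def n_movements_kept(self) -> int:
        return len(self.revised)


def pattern_signal(
    series: Mapping[str, JointAngleSeries], pattern: MovementPattern
) -> JointAngleSeries:
    """Aggregate joint-angle series into the pattern's scalar signal.

    Single-angle patterns (spread, opposition) pass through; fist opening is
    the mean over the four long fingers of the per-finger composite flexion
    MCP + PIP, so units stay in degrees of composite flexion.
    """
    missing = [a for a in pattern.angle_names if a not in series]
    if missing:
        raise KeyError(f"pattern {pattern.name.value} missing angle series: {missing}")
    first = series[pattern.angle_names[0]]
    for a in pattern.angle_names[1:]:
        if not np.array_equal(series[a].timestamps, first.timestamps):
            raise ValueError(
                f"timestamp mismatch between {pattern.angle_names[0]} and {a}"
            )
    if len(pattern.angle_names) == 1:
        return JointAngleSeries(
            pattern.name.value, first.timestamps, first.angles_deg.copy()
        )
    # FIST_OPENING: mean over fingers of (MCP_f + PIP_f)
    per_finger = [
        series[f"MCP_{f}"].angles_deg + series[f"PIP_{f}"].angles_deg for f in FINGERS
    ]
    return JointAngleSeries(
        pattern.name.value, first.timestamps, np.mean(per_finger, axis=0)
    )


def segment_movements(
    signal: JointAngleSeries,
    course: CourseConfig = CourseConfig(),
    min_prominence_deg: float = 10.0,
) -> list[MovementSegment]:
    """Detect alternating trough→peak movements by prominence-based peaks.

    The effective prominence is ``max(min_prominence_deg, 20% of the run's
    global amplitude)``: robust to plateau noise without any assumption on
    movement timing. Each detected peak is paired with the signal minimum
    since the previous peak (or the start of the run), yielding one
    target-direction segment per oscillation cycle. A flat run yields an
    empty list with a warning, never an exception.
    """
    x = np.asarray(signal.angles_deg, dtype=float)
    if len(x) == 0:
        warnings.warn("empty signal: no movements detected", stacklevel=2)
        return []
    amplitude = float(np.max(x) - np.min(x))
    prominence = max(min_prominence_deg, 0.2 * amplitude)
    peaks, _ = find_peaks(x, prominence=prominence)
    # a run ending mid-stroke can leave a final rising edge without an
    # interior maximum; count the endpoint as a peak if it is prominent
    if len(x) > 1:
        last_base = peaks[-1] if len(peaks) else 0
        tail_min = float(np.min(x[last_base:]))
        if x[-1] - tail_min >= prominence and (len(peaks) == 0 or peaks[-1] != len(x) - 1):
            peaks = np.append(peaks, len(x) - 1)
    if len(peaks) == 0:
        warnings.warn("no movements detected in signal", stacklevel=2)
        return []
    segments: list[MovementSegment] = []
    prev = 0
    for p in peaks:
        window = x[prev : p + 1]
        t_idx = prev + int(np.argmin(window))
        segments.append(
            MovementSegment(
                start=t_idx,
                end=int(p),
                trough_deg=float(x[t_idx]),
                peak_deg=float(x[p]),
            )
        )
        prev = int(p)
    return segments


def delta_angle(segment: MovementSegment) -> DeltaAngle:
    """Δ-angle of one movement: peak minus trough, in degrees."""
    return DeltaAngle(value_deg=segment.peak_deg - segment.trough_deg, segment=segment)


def revise_deltas(
    deltas: Sequence[DeltaAngle],
    pattern: MovementPattern,
    floor_fraction: float = 0.25,
) -> list[DeltaAngle]:
    """Revise a Δ-angle run: drop implausible values, keep order.

    Discards Δ-angles above the pattern's physiological ceiling and
    incomplete movements below ``floor_fraction`` × the run median. Every
    discard carries a reason code; kept + discarded = detected.
    """
    if not deltas:
        return []
    values = np.array([d.value_deg for d in deltas])
    med = float(np.median(values))
    floor = floor_fraction * med
    out = []
    for d in deltas:
        if d.value_deg > pattern.ceiling_deg:
            out.append(
                DeltaAngle(d.value_deg, d.segment, kept=False,
                           discard_reason=f"above ceiling {pattern.ceiling_deg}°")
            )
        elif d.value_deg < floor:
            out.append(
                DeltaAngle(d.value_deg, d.segment, kept=False,
                           discard_reason=f"below {floor_fraction}×median ({floor:.1f}°)")
            )
        else:
            out.append(d)
    if not any(d.kept for d in out):
        warnings.warn("all Δ-angles discarded during revision", stacklevel=2)
    return out


def assessment_rom(
    revised: Sequence[DeltaAngle],
    pattern: Pattern,
    subject_id: str | None = None,
    timepoint: str | None = None,
) -> AssessmentResult:
    """Assemble the assessment outcome: mean ROM over kept Δ-angles.

    With every movement discarded (or none detected) the outcome is missing
    (NaN), mirroring patients unable to perform a pattern — never zero.
    """
    kept = [d for d in revised if d.kept]
    return AssessmentResult(
        pattern=Pattern(pattern),
        subject_id=subject_id,
        timepoint=timepoint,
        deltas=list(revised),
        revised=kept,
    )


def extract_assessment(
    series: Mapping[str, JointAngleSeries],
    pattern: Pattern,
    course: CourseConfig = CourseConfig(),
    min_prominence_deg: float = 10.0,
    floor_fraction: float = 0.25,
    subject_id: str | None = None,
    timepoint: str | None = None,
) -> AssessmentResult:
    """Full extraction for one pattern: aggregate → segment → Δ → revise → mean."""
    mp = PATTERNS[Pattern(pattern)]
    signal = pattern_signal(series, mp)
    segments = segment_movements(signal, course, min_prominence_deg)
    deltas = [delta_angle(s) for s in segments]
    revised = revise_deltas(deltas, mp, floor_fraction) if deltas else []
    return assessment_rom(revised, Pattern(pattern), subject_id, timepoint)
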