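"""Synthetic glove streams and synthetic validation cohorts.

Two generators make the whole pipeline testable without any recorded data:

``simulate_run``
    Forward kinematics: programmed joint-angle trajectories over the
    50-obstacle alternating course (raised-cosine strokes 0 → ROM → 0) are
    converted into the eleven sensor orientation quaternions consistent with
    the hand model's axes, optionally perturbed by small random orientation
    noise. The inverse of the extraction pipeline, exact at zero noise.

``simulate_cohort``
    A latent-variable (Gaussian-copula-like) patient cohort: one
    subject-level ability factor drives per-pattern ROM, grip strength,
    ordinal clinician scores and patient-reported disability, so group
    separation, test–retest reliability and cross-sectional correlations
    are all programmable. Default group means/SDs reproduce the printed
    impaired vs non-impaired summaries (finger spread 32.7 (15.8)° vs
    47.0 (6.7)°; thumb opposition 91.6 (36.1)° vs 117.3 (15.6)°; fist
    opening 129.2 (36.2)° vs 154.5 (12.4)°).

All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import (
    FINGERS,
    GloveFrame,
    HandModel,
    SensorId,
    default_hand_model,
)
from .quaternions import IDENTITY, from_axis_angle, normalize_quaternion, quat_multiply
from .rom import PATTERNS, Pattern

__all__ = [
    "SimulationConfig",
    "GroupParams",
    "CohortConfig",
    "simulate_run",
    "simulate_cohort",
    "inject_missingness",
    "MissingnessRule",
    "TIMEPOINTS",
]

TIMEPOINTS = ("T1", "T2", "T3", "T4")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated glove run."""

    pattern: Pattern
    rom_deg: float = 120.0
    rate_hz: float = 25.0
    n_obstacles: int = 50
    seconds_per_obstacle: float = 1.0
    noise_sd_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        ceiling = PATTERNS[Pattern(self.pattern)].ceiling_deg
        if not 0 <= self.rom_deg <= ceiling:
            raise ValueError(
                f"rom_deg={self.rom_deg} outside [0, {ceiling}] for "
                f"{Pattern(self.pattern).value}"
            )


def _stroke_profile(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Timestamps and aggregate-signal trajectory over the course.

    Each pair of alternating obstacles is one raised-cosine oscillation
    0 → ROM → 0; a 50-obstacle course therefore contains 25 target-direction
    (trough→peak) movements.
    """
    n_cycles = config.n_obstacles // 2
    duration = config.n_obstacles * config.seconds_per_obstacle
    n_samples = int(round(duration * config.rate_hz)) + 1
    t = np.arange(n_samples) / config.rate_hz
    cycle_period = 2.0 * config.seconds_per_obstacle
    phase = np.clip(t / cycle_period, 0, n_cycles)
    angle = config.rom_deg * 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    return t, angle


def _frame_from_joint_targets(
    timestamp: float,
    targets: dict[str, float],
    model: HandModel,
    rng: np.random.Generator | None,
    noise_sd_deg: float,
) -> GloveFrame:
    """Compose sensor orientations realizing the given joint angles.

    Sensors are chained proximal→distal: each distal orientation is the
    proximal orientation composed with a rotation about the joint axis.
    """
    orientations: dict[SensorId, np.ndarray] = {s: IDENTITY.copy() for s in SensorId}
    # order matters: PP sensors before MP sensors (chained frames)
    chain = (
        [(f"MCP_{f}",) for f in FINGERS]
        + [(f"PIP_{f}",) for f in FINGERS]
        + [("SPREAD",), ("CMC_OPPOSITION",)]
    )
    for (name,) in chain:
        if name not in targets:
            continue
        jd = model[name]
        q_rel = from_axis_angle(jd.axis, jd.sign * targets[name])
        orientations[jd.distal] = normalize_quaternion(
            quat_multiply(orientations[jd.proximal], q_rel)
        )
    if rng is not None and noise_sd_deg > 0:
        for s in SensorId:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            q_noise = from_axis_angle(axis, rng.normal(0.0, noise_sd_deg))
            orientations[s] = normalize_quaternion(
                quat_multiply(orientations[s], q_noise)
            )
    return GloveFrame(timestamp, orientations)


def _joint_targets(pattern: Pattern, angle: float) -> dict[str, float]:
    """Distribute the aggregate signal value over contributing joints."""
    if pattern is Pattern.FINGER_SPREAD:
        return {"SPREAD": angle}
    if pattern is Pattern.THUMB_OPPOSITION:
        return {"CMC_OPPOSITION": angle}
    # fist opening: aggregate = mean over fingers of (MCP+PIP);
    # split evenly so MCP = PIP = aggregate / 2
    targets = {}
    for f in FINGERS:
        targets[f"MCP_{f}"] = angle / 2.0
        targets[f"PIP_{f}"] = angle / 2.0
    return targets


def simulate_run(
    config: SimulationConfig, model: HandModel | None = None
) -> tuple[GloveFrame, list[GloveFrame]]:
    """Simulate one glove assessment run.

    Returns the reset frame (zero-degree position, all sensors at identity)
    and the frame sequence of the course traversal.
    """
    model = model or default_hand_model()
    pattern = Pattern(config.pattern)
    rng = np.random.default_rng(config.seed)
    t, trajectory = _stroke_profile(config)
    reset = _frame_from_joint_targets(0.0, {}, model, None, 0.0)
    frames = [
        _frame_from_joint_targets(
            float(ti),
            _joint_targets(pattern, float(a)),
            model,
            rng,
            config.noise_sd_deg,
        )
        for ti, a in zip(t, trajectory)
    ]
    return reset, frames


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: printed impaired / non-impaired ROM summaries (mean, SD) in degrees
DEFAULT_GROUP_ROM = {
    Pattern.FINGER_SPREAD: ((32.7, 15.8), (47.0, 6.7)),
    Pattern.THUMB_OPPOSITION: ((91.6, 36.1), (117.3, 15.6)),
    Pattern.FIST_OPENING: ((129.2, 36.2), (154.5, 12.4)),
}

#: grip-strength marginals per group, kPa (synthetic choice: subgroup grip
#: summaries are not published; values give a clearly separated but
#: overlapping distribution typical of Vigorimeter readings)
DEFAULT_GROUP_GRIP = ((45.0, 20.0), (85.0, 18.0))

#: cross-sectional correlation targets between ROM and clinical scores,
#: matching the published magnitudes (grip ~0.6-0.8, MRC ~0.3-0.45,
#: INCAT ~ -0.4 to -0.66, R-ODS ~0.25-0.5)
DEFAULT_CORR_TARGETS = {
    "vigorimeter_kpa": 0.70,
    "mrc_arm": 0.40,
    "incat_arm": -0.55,
    "rods_logits": 0.40,
    "ncv_ms": 0.35,
    "csa_mm2": -0.20,
}


@dataclass(frozen=True)
class GroupParams:
    """Per-group marginal for a continuous outcome."""

    mean: float
    sd: float


@dataclass
class CohortConfig:
    """Design of a synthetic validation cohort.

    The defaults are the study conditions: 14 impaired vs 11 non-impaired
    subjects, four analysis timepoints, subject-level test–retest
    correlation 0.9 and the printed per-pattern group means/SDs.
    """

    n_impaired: int = 14
    n_control: int = 11
    n_timepoints: int = 4
    test_retest_rho: float = 0.9
    group_rom: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_ROM))
    group_grip: tuple = DEFAULT_GROUP_GRIP
    corr_targets: dict = field(default_factory=lambda: dict(DEFAULT_CORR_TARGETS))
    time_slope_deg: float = 0.0          # per-timepoint drift, 0 = stable cohort
    include_ncs_hrus: bool = True        # NCV / CSA columns (T2 and T4 only)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_retest_rho <= 1:
            raise ValueError("test_retest_rho must be in (0, 1]")
        for r in self.corr_targets.values():
            if abs(r) / np.sqrt(self.test_retest_rho) > 1:
                raise ValueError(
                    f"correlation target {r} infeasible at "
                    f"test_retest_rho={self.test_retest_rho}"
                )


ROM_COLUMNS = {
    Pattern.FINGER_SPREAD: "rom_finger_spread_deg",
    Pattern.THUMB_OPPOSITION: "rom_thumb_opposition_deg",
    Pattern.FIST_OPENING: "rom_fist_opening_deg",
}

MRC_ARM_MAX = 20     # 4 muscle pairs × MRC 0-5, summed over the arm
INCAT_ARM_MAX = 5


def _score_latent(rng, u_subject, loading, n_timepoints):
    """Visit-level latent correlated with the ability factor ``u_subject``."""
    loading = float(np.clip(loading, -1.0, 1.0))
    eps = rng.normal(size=(len(u_subject), n_timepoints))
    return loading * u_subject[:, None] + np.sqrt(1 - loading**2) * eps


def simulate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Simulate a subject × timepoint cohort table.

    One latent ability factor U_i per subject drives everything: per-visit
    ROM latents load on U_i with sqrt(test_retest_rho) (so consecutive
    visits correlate at rho), and each clinical score loads with
    target_r / sqrt(rho) so its cross-sectional correlation with ROM comes
    out near the target. Group labels are assigned by design, never by
    thresholding outcomes. Ordinal scores arise by thresholding a latent
    disability; NCV/CSA are observed only at T2 and T4, as in the study
    schedule.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_impaired + config.n_control
    groups = np.array(
        ["impaired"] * config.n_impaired + ["control"] * config.n_control
    )
    tps = TIMEPOINTS[: config.n_timepoints]
    u = rng.normal(size=n)                       # subject ability factor
    sr = np.sqrt(config.test_retest_rho)

    rows: dict[str, list] = {c: [] for c in (
        "subject_id", "timepoint", "group", "age_years", "sex",
        *ROM_COLUMNS.values(), "vigorimeter_kpa", "mrc_arm",
        "incat_arm", "rods_logits", "ncv_ms", "csa_mm2",
    )}

    age = np.round(rng.normal(64.2, 9.7, size=n)).astype(int)
    sex = rng.choice(["m", "f"], size=n, p=[0.8, 0.2])  # cohort skews male

    rom_latent = {
        p: _score_latent(rng, u, sr, config.n_timepoints) for p in Pattern
    }
    score_latent = {
        name: _score_latent(rng, u, config.corr_targets[name] / sr,
                            config.n_timepoints)
        for name in config.corr_targets
    }

    for i in range(n):
        g = 0 if groups[i] == "impaired" else 1
        for j, tp in enumerate(tps):
            rows["subject_id"].append(f"S{i + 1:02d}")
            rows["timepoint"].append(tp)
            rows["group"].append(groups[i])
            rows["age_years"].append(int(age[i]))
            rows["sex"].append(sex[i])
            for p, col in ROM_COLUMNS.items():
                mean, sd = config.group_rom[p][g]
                val = mean + sd * rom_latent[p][i, j] + config.time_slope_deg * j
                rows[col].append(max(val, 0.0))
            gm, gs = config.group_grip[g]
            rows["vigorimeter_kpa"].append(
                max(gm + gs * score_latent["vigorimeter_kpa"][i, j], 0.0)
            )
            # ordinal scores: threshold latent function/disability; impaired
            # group shifted toward worse scores
            func = score_latent["mrc_arm"][i, j] + (0.0 if g else -1.5)
            mrc = MRC_ARM_MAX + np.floor(np.minimum(func, 0.0) * 3.0)
            rows["mrc_arm"].append(int(np.clip(mrc, 0, MRC_ARM_MAX)))
            dis = score_latent["incat_arm"][i, j] + (1.2 if g == 0 else -0.8)
            incat = np.floor(np.maximum(dis, 0.0))
            rows["incat_arm"].append(int(np.clip(incat, 0, INCAT_ARM_MAX)))
            rods = 2.0 + 2.5 * score_latent["rods_logits"][i, j] - (1.5 if g == 0 else 0.0)
            rows["rods_logits"].append(round(float(rods), 2))
            if config.include_ncs_hrus and tp in ("T2", "T4"):
                ncv = 52.0 + 6.0 * score_latent["ncv_ms"][i, j] - (4.0 if g == 0 else 0.0)
                csa = 11.0 + 2.5 * score_latent["csa_mm2"][i, j] + (1.5 if g == 0 else 0.0)
                rows["ncv_ms"].append(round(float(ncv), 1))
                rows["csa_mm2"].append(round(float(csa), 1))
            else:
                rows["ncv_ms"].append(np.nan)
                rows["csa_mm2"].append(np.nan)

    df = pd.DataFrame(rows)
    for col in ROM_COLUMNS.values():
        df[col] = df[col].round(1)
    df["vigorimeter_kpa"] = df["vigorimeter_kpa"].round(1)
    return df


@dataclass(frozen=True)
class MissingnessRule:
    """One deterministic-per-seed missingness injection.

    ``kind='pattern_inability'`` blanks a ROM column for ``n_subjects``
    impaired subjects at every timepoint (patients unable to perform the
    movement); ``kind='visit_skip'`` blanks all outcome columns for
    ``n_subjects`` subjects at one timepoint.
    """

    kind: str
    column: str | None = None
    n_subjects: int = 1
    timepoint: str | None = None
    group: str | None = "impaired"


OUTCOME_COLUMNS = [
    *ROM_COLUMNS.values(), "vigorimeter_kpa", "mrc_arm", "incat_arm",
    "rods_logits", "ncv_ms", "csa_mm2",
]


def inject_missingness(
    table: pd.DataFrame, rules: Sequence[MissingnessRule], seed: int = 0
) -> pd.DataFrame:
    """Apply missingness rules; subject choice is deterministic per seed."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for rule in rules:
        pool = out["subject_id"].unique() if rule.group is None else (
            out.loc[out["group"] == rule.group, "subject_id"].unique()
        )
        chosen = rng.choice(pool, size=rule.n_subjects, replace=False)
        if rule.kind == "pattern_inability":
            if rule.column is None:
                raise ValueError("pattern_inability rule needs a column")
            out.loc[out["subject_id"].isin(chosen), rule.column] = np.nan
        elif rule.kind == "visit_skip":
            if rule.timepoint is None:
                raise ValueError("visit_skip rule needs a timepoint")
            mask = out["subject_id"].isin(chosen) & (out["timepoint"] == rule.timepoint)
            out.loc[mask, OUTCOME_COLUMNS] = np.nan
        else:
            raise ValueError(f"unknown missingness rule kind: {rule.kind}")
    return out
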