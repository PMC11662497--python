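"""Simulate one glove assessment and extract its mean range of motion.

A virtual hand traverses the standardized 50-obstacle alternating course
performing the fist-opening pattern with a programmed ROM of 120° and a
little orientation noise. The extraction pipeline calibrates the stream
against the reset posture, computes MCP/PIP joint angles from the sensor
quaternions, aggregates them into the composite fist-opening signal,
segments the 25 target-direction movements and averages the revised
Δ-angles.
"""

from gloverom import (
    Pattern,
    PATTERNS,
    SimulationConfig,
    apply_zero_reset,
    default_hand_model,
    extract_assessment,
    joint_angle_series,
    simulate_run,
)

config = SimulationConfig(
    pattern=Pattern.FIST_OPENING,
    rom_deg=120.0,
    noise_sd_deg=0.5,
    seed=42,
)
model = default_hand_model()
reset, frames = simulate_run(config, model)
print(f"simulated {len(frames)} frames at 25 Hz (plus the reset frame)")

calibrated = apply_zero_reset(frames, reset)
angles = {
    name: joint_angle_series(calibrated, model, name)
    for name in PATTERNS[Pattern.FIST_OPENING].angle_names
}
result = extract_assessment(angles, Pattern.FIST_OPENING)

deltas = [d.value_deg for d in result.revised]
print(f"movements detected : {len(result.deltas)}")
print(f"movements kept     : {result.n_movements_kept}")
print(f"delta-angle range  : {min(deltas):.1f}–{max(deltas):.1f} deg")
print(f"mean ROM           : {result.rom_mean_deg:.1f} deg")
# The mean ROM is the per-assessment outcome; with 0.5 deg sensor noise it
# lands within a few tenths of a degree of the programmed 120 deg.
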