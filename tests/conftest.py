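import numpy as np
import pytest

from gloverom.kinematics import (
    apply_zero_reset,
    default_hand_model,
    joint_angle_series,
)
from gloverom.rom import PATTERNS, Pattern, extract_assessment
from gloverom.simulate import SimulationConfig, simulate_run


@pytest.fixture(scope="session")
def hand_model():
    return default_hand_model()


def run_extraction(pattern, rom_deg, noise_sd_deg=0.0, seed=0, n_obstacles=50,
                   model=None):
    """Simulate one run and push it through the full extraction pipeline."""
    model = model or default_hand_model()
    cfg = SimulationConfig(
        pattern=Pattern(pattern), rom_deg=rom_deg, noise_sd_deg=noise_sd_deg,
        seed=seed, n_obstacles=n_obstacles,
    )
    reset, frames = simulate_run(cfg, model)
    calibrated = apply_zero_reset(frames, reset)
    mp = PATTERNS[Pattern(pattern)]
    series = {a: joint_angle_series(calibrated, model, a)
              for a in mp.angle_names}
    return extract_assessment(series, Pattern(pattern))


@pytest.fixture(scope="session")
def clean_fist_assessment():
    return run_extraction(Pattern.FIST_OPENING, rom_deg=120.0)


def random_quaternion(rng):
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)
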