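import numpy as np
import pytest

from popdemix import EffectSpec, TaskDesign, generate_population


@pytest.fixture
def design_2x2():
    """Compact 2 x 2 design (30 bins) for fast tests."""
    return TaskDesign(
        name="wrist_orientation",
        parameter_levels=("horizontal", "vertical"),
        epoch_windows=((0, 1200),),
    )


@pytest.fixture
def design_3x2():
    """Compact reach-like 3 x 2 design (40 bins)."""
    return TaskDesign(
        name="reach_direction",
        parameter_levels=("left", "center", "right"),
        epoch_windows=((-800, 800),),
    )


@pytest.fixture
def mixed_spec():
    return EffectSpec(
        target_fractions={
            "condition_independent": 0.5,
            "parameter": 0.25,
            "visual": 0.15,
            "interaction": 0.1,
        },
        noise_model="gaussian",
        noise_sigma_hz=1.0,
        baseline_hz=30.0,
        signal_std_hz=8.0,
        trials_per_condition=(4, 6),
        seed=42,
    )


@pytest.fixture
def small_population(design_2x2, mixed_spec):
    return generate_population(design_2x2, 25, mixed_spec)


def random_centered_tensor(rng, n=12, s=3, v=2, t=10):
    x = rng.standard_normal((n, s, v, t))
    return x - x.mean(axis=(1, 2, 3), keepdims=True)
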