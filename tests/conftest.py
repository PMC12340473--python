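"""Shared fixtures: small phantom scenes generated at test time."""

import numpy as np
import pytest

from respiro.phantom import (
    PhantomConfig,
    breath_pattern_for_duration,
    render_scene,
)

FRAME_PERIOD = 0.033


def make_scene(
    seed: int,
    n_slices: int = 2,
    frames_per_slice: int = 240,
    image_size: int = 80,
    noise_sd: float = 0.02,
    period_s: float = 1.5,
    tidal_volume_l: float = 0.5,
    rotation_deg: float = 0.0,
    **config_kwargs,
):
    """A compact scene: fast tidal breathing so short blocks hold whole breaths."""
    duration = n_slices * frames_per_slice * FRAME_PERIOD
    rng = np.random.default_rng(seed)
    pattern = breath_pattern_for_duration(
        duration, tidal_volume_l=tidal_volume_l, period_s=period_s, jitter=0.05, rng=rng
    )
    config = PhantomConfig(
        breath_pattern=pattern,
        image_size=image_size,
        n_slices=n_slices,
        frames_per_slice=frames_per_slice,
        noise_sd=noise_sd,
        rotation_deg=rotation_deg,
        seed=seed,
        **config_kwargs,
    )
    return render_scene(config)


@pytest.fixture(scope="session")
def tiny_scene():
    """2 slices x 240 frames of 80x80 pixels, mildly noisy."""
    return make_scene(seed=101)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Pure diaphragm translation, no noise, no chest expansion: the
    parameter-recovery ground truth."""
    return make_scene(seed=202, noise_sd=0.0, chest_gain_mm_per_l=0.0, anatomy_jitter=0.0)
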