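from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from stavquant.scene import GranuleSpec, OpticsSpec, SceneSpec, render_scene

PX = 65.0
Z_STEP = 140.0


@pytest.fixture
def clean_optics() -> OpticsSpec:
    """No PSF, no background, no noise: pure geometry."""
    return OpticsSpec(psf_sigma_xy=0.0, psf_sigma_z=0.0, background=0.0, read_noise_sd=0.0)


def make_sphere_stack(
    radius_px: float,
    *,
    mode: str = "volume",
    shell_fraction: float = 1.0,
    optics: OpticsSpec | None = None,
    shape=(48, 96, 96),
    channel: str = "strep",
    noise: bool = False,
    amplitude: float = 100.0,
    seed: int = 0,
):
    """Render one centred spherical granule; returns (stack, center_px, scene)."""
    optics = optics or OpticsSpec(
        psf_sigma_xy=0.0, psf_sigma_z=0.0, background=0.0, read_noise_sd=0.0
    )
    center = (
        shape[0] * optics.z_step / 2,
        shape[1] * optics.pixel_size_xy / 2,
        shape[2] * optics.pixel_size_xy / 2,
    )
    g = GranuleSpec(
        center=center,
        radius=radius_px * optics.pixel_size_xy,
        channel=channel,
        labelling_mode=mode,
        shell_fraction=shell_fraction,
        amplitude=amplitude,
    )
    scene = SceneSpec(shape=shape, channels=(channel,), granules=(g,), optics=optics, seed=seed)
    stack, truth = render_scene(scene, noise=noise)
    # pixel-index coordinates of the physical centre (pixel i spans [i, i+1) * px)
    center_px = (center[1] / optics.pixel_size_xy - 0.5, center[2] / optics.pixel_size_xy - 0.5)
    return stack, center_px, scene, truth


@pytest.fixture
def sphere_stack_factory():
    return make_sphere_stack


def padded_profile(intensities, positions=None, channel="test"):
    """LineProfile from a short worked example, zero-padded to >= 8 samples.

    Padding with zeros at both ends preserves the baseline (0), the
    level, and every crossing position of the original example.
    """
    from stavquant.profiles import LineProfile

    y = np.asarray(intensities, dtype=float)
    if positions is None:
        positions = np.arange(y.size, dtype=float)
    x = np.asarray(positions, dtype=float)
    n_pad = max(0, 8 - y.size)
    left = n_pad // 2 + 1
    right = n_pad - n_pad // 2 + 1
    dx = x[1] - x[0]
    x_full = np.concatenate(
        [x[0] - dx * np.arange(left, 0, -1), x, x[-1] + dx * np.arange(1, right + 1)]
    )
    y_full = np.concatenate([np.zeros(left), y, np.zeros(right)])
    return LineProfile(
        positions=x_full - x_full[0],
        intensities=y_full,
        channel=channel,
        start_px=(0.0, 0.0),
        end_px=(0.0, float(x_full[-1])),
        width_px=1,
    ), float(x_full[0])
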