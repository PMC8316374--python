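"""Shared fixtures: small rendered scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from eltether.synthetic import ContactDwell, MotionSpec, SceneSpec, render_movie


@pytest.fixture(scope="session")
def contact_scene():
    """Two-channel 50-frame movie at 2.4 s/frame with a 10-dwell contact plan.

    Six dwells last at least 10 s, four are shorter; particles are confined
    so each stays put while its accumulation blinks on and off.
    """
    dt, nf = 2.4, 50
    motions = [
        MotionSpec("confined", D=0.005, dt=dt, n_frames=nf, R_c=0.2, loc_noise_sigma=0.0)
        for _ in range(10)
    ]
    plan = [
        ContactDwell(0, 0.0, 24.0),
        ContactDwell(1, 12.0, 48.0),
        ContactDwell(2, 2.4, 16.8),
        ContactDwell(3, 24.0, 117.6),
        ContactDwell(4, 48.0, 60.0),
        ContactDwell(5, 0.0, 12.0),
        ContactDwell(6, 0.0, 4.8),
        ContactDwell(7, 24.0, 26.4),
        ContactDwell(8, 50.4, 52.8),
        ContactDwell(9, 96.0, 98.4),
    ]
    scene = SceneSpec(
        shape_px=(200, 200),
        channels=("EL", "SNX19"),
        motions=motions,
        contact_plan=plan,
        rng_seed=5,
        spot_amplitude=200.0,
        er_network_amplitude=40.0,
        read_noise_sd=2.0,
    )
    stack, truth = render_movie(scene)
    return scene, stack, truth


@pytest.fixture(scope="session")
def three_class_movie():
    """Rendered 200-frame movie with 5 particles per motion class (SNR 10)."""
    dt, nf = 0.1, 200
    motions = []
    for _ in range(5):
        motions.append(MotionSpec("confined", D=0.05, dt=dt, n_frames=nf, R_c=0.25))
        motions.append(MotionSpec("free", D=0.05, dt=dt, n_frames=nf))
        motions.append(MotionSpec("directed", D=0.01, dt=dt, n_frames=nf, v=0.3))
    scene = SceneSpec(shape_px=(256, 256), motions=motions, rng_seed=21, read_noise_sd=2.0)
    stack, truth = render_movie(scene)
    return scene, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
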