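"""Shared fixtures: a small rendered synthetic scene reused across modules."""

import numpy as np
import pytest

from grainstereo import synthetic


@pytest.fixture(scope="session")
def small_scene():
    """Eight asymmetric grains with mild noise — the standard test scene."""
    return synthetic.sample_scene(n_grains=8, seed=11, noise_sigma=1.0)


@pytest.fixture(scope="session")
def small_scene_rendered(small_scene):
    return synthetic.render_stereo(small_scene)


@pytest.fixture(scope="session")
def board_only_scene():
    """A grain-free board render for circle-detection tests."""
    scene = synthetic.sample_scene(n_grains=0, seed=3, noise_sigma=0.0)
    left, right = synthetic.render_stereo(scene)
    return scene, left, right


def asymmetric_profile(rng=None, n=360):
    """A smooth, elongated, non-symmetric polar signature (no 180-deg tie)."""
    th = np.radians(np.arange(n))
    h = 40.0 + 25.0 * np.cos(2 * th) + 6.0 * np.cos(th + 0.7) + 2.0 * np.sin(3 * th)
    if rng is not None:
        h = h + rng.normal(0.0, 0.2, n)
    return h
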