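"""Shared fixtures: seeded phantoms at the two study grid sizes.

Phantom generation is the expensive step, so phantoms are session-scoped
and must be treated as read-only by tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from adipoct.phantom import PhantomSpec, fat_pad_spec, generate_phantom


@pytest.fixture(scope="session")
def phantom_default():
    """Default-size phantom (160x112x112, noise 25 HU, no motion)."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def pad_default(phantom_default):
    return fat_pad_spec(phantom_default.truth)


@pytest.fixture(scope="session")
def phantom_small():
    """64^3 phantom for structural tests where speed matters more than bias."""
    return generate_phantom(PhantomSpec(grid_shape=(64, 64, 64), seed=7))


@pytest.fixture(scope="session")
def phantom_small_noiseless():
    """64^3 phantom with no noise and no blur: labels map exactly to HU means."""
    return generate_phantom(
        PhantomSpec(grid_shape=(64, 64, 64), seed=3, noise_sd_hu=0.0, psf_sigma_vox=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
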