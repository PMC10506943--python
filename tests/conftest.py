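"""Shared fixtures: small phantoms sized for test runtime.

The small phantom (40 mm cube, 5 frames) keeps per-test tracking in the
seconds range; the default-size reference phantom is reserved for the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from prmstrain.phantom import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    base = dict(
        grid_shape=(40, 40, 40),
        n_frames=5,
        arc_radius=12.0,
        tube_radius=3.0,
        psf_sigma=(1.0, 1.0, 1.0),
        noise_level=0.05,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_spec(), seed=11)


@pytest.fixture(scope="session")
def small_avulsed_phantom():
    return generate_phantom(small_spec(condition="avulsed_left"), seed=11)


@pytest.fixture(scope="session")
def speckle_volume(small_phantom):
    """One fully developed speckle frame."""
    return small_phantom.volumes.frame(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
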