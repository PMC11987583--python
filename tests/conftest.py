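"""Shared fixtures: small deterministic simulations reused across test files."""

from __future__ import annotations

import numpy as np
import pytest

import fourd as fd


@pytest.fixture(scope="session")
def demo_field():
    """Unrestricted random fibre field on the desk-scale recipe."""
    return fd.simulate_field(fd.demo_recipe(seed=31))


@pytest.fixture(scope="session")
def demo_image(demo_field):
    """Unbiased render of the demo field (512x512)."""
    return fd.render_image(demo_field, None, seed=31)


@pytest.fixture(scope="session")
def polarised_pair(demo_field):
    """Polarisation-resolved channel pair with emission strength 0.5."""
    return fd.simulate_polarised_pair(demo_field, 0.5, seed=31)


@pytest.fixture()
def rng():
    # function-scoped: each test sees the same fresh stream regardless of
    # which other tests ran before it
    return np.random.default_rng(1234)
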