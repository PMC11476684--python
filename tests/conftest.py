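"""Shared fixtures: small synthetic slides generated once per session."""

from dataclasses import replace

import numpy as np
import pytest

from hemux.fixtures import FixtureSpec, generate_pair
from hemux.panel import MarkerPanel


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """Desk-scale paired slide: 512 px, 64 px tiles, planted warp."""
    return replace(
        FixtureSpec(),
        image_size=512,
        n_cells=4000,
        tile_size_px=64,
        field_sigma_px=24.0,
        warp_period_tiles=8.0,
    )


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return generate_pair(small_spec)


@pytest.fixture(scope="session")
def small_pair_nowarp(small_spec):
    spec = replace(
        small_spec,
        rotation_deg=0.0,
        scale=1.0,
        translation=(0.0, 0.0),
        warp_amplitude_px=0.0,
    )
    return generate_pair(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def panel16() -> MarkerPanel:
    return MarkerPanel()
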