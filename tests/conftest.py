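"""Shared fixtures: programmatically built colony masks and tiny plates."""

from __future__ import annotations

import numpy as np
import pytest

from psicic.masks import RED, WHITE


def make_colony_mask(size: int, radius: float, sectors) -> np.ndarray:
    """Ideal colony crop: white disk with red angular sectors, centered.

    ``sectors`` is a list of half-open [start, end) intervals in degrees
    measured as atan2(row - c, col - c) mod 360 about the crop center.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = (size - 1) / 2
    d = np.hypot(yy - c, xx - c)
    ang = np.degrees(np.arctan2(yy - c, xx - c)) % 360
    m = np.zeros((size, size), np.uint8)
    m[d <= radius] = WHITE
    for start, end in sectors:
        span = (end - start) % 360 or 360
        m[(d <= radius) & (((ang - start) % 360) < span)] = RED
    return m


@pytest.fixture
def colony_mask():
    return make_colony_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
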