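"""Shared fixtures: analytic shapes with known morphometrics."""

from __future__ import annotations

import numpy as np
import pytest


def blank(shape=(64, 64)) -> np.ndarray:
    return np.zeros(shape, dtype=bool)


@pytest.fixture
def rectangle_10x100():
    """Filled 10x100 rectangle (area 1000 px^2, medial length ~100 px)."""
    m = blank((20, 110))
    m[5:15, 5:105] = True
    return m


@pytest.fixture
def rectangle_5x101():
    m = blank((15, 111))
    m[5:10, 5:106] = True
    return m


@pytest.fixture
def diagonal_101():
    """Perfect 45-degree 1-px line of 101 pixels."""
    m = blank((110, 110))
    idx = np.arange(101)
    m[4 + idx, 4 + idx] = True
    return m


@pytest.fixture
def plus_sign():
    """Two crossing 41-px 1-px-wide lines sharing their midpoints."""
    m = blank((50, 50))
    m[25, 5:46] = True
    m[5:46, 25] = True
    return m


@pytest.fixture
def y_shape():
    """Y: a vertical stem and two diagonal arms, all well over 15 px."""
    m = blank((60, 60))
    m[30:55, 30] = True            # stem down
    idx = np.arange(1, 26)
    m[30 - idx, 30 - idx] = True   # arm up-left
    m[30 - idx, 30 + idx] = True   # arm up-right
    m[30, 30] = True
    return m


@pytest.fixture
def ring():
    """Closed 1-px ring (no endpoints, no junctions)."""
    m = blank((40, 40))
    m[10, 10:31] = True
    m[30, 10:31] = True
    m[10:31, 10] = True
    m[10:31, 30] = True
    return m


def random_blob_mask(rng: np.random.Generator, shape=(80, 80), n_blobs=6):
    """Random connected-ish blob mask used by topology-preservation tests."""
    from scipy import ndimage

    m = np.zeros(shape, bool)
    for _ in range(n_blobs):
        r, c = rng.integers(5, shape[0] - 5), rng.integers(5, shape[1] - 5)
        rad = rng.integers(2, 9)
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        m |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
    m = ndimage.binary_opening(m, np.ones((2, 2)))
    return m


def random_histogram(rng: np.random.Generator):
    """Random multi-modal 256-bin histogram for threshold oracle tests."""
    from tubemorph.detect import IntensityHistogram

    counts = np.zeros(256, dtype=np.int64)
    for _ in range(rng.integers(2, 5)):
        mu = rng.integers(10, 246)
        sd = rng.uniform(3, 25)
        n = rng.integers(200, 5000)
        samples = np.clip(np.round(rng.normal(mu, sd, n)), 0, 255).astype(int)
        counts += np.bincount(samples, minlength=256)
    counts += np.bincount(
        rng.integers(0, 256, rng.integers(0, 300)), minlength=256
    )
    return IntensityHistogram(counts, int(counts.sum()))
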