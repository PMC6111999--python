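import math

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def shaded_blob_image(seed: int = 0, n: int = 161) -> np.ndarray:
    """Bright background with three dark blobs, each shaded along +x.

    Odd-sized on purpose: 90-degree rotation then maps the even
    downsampling grid onto itself, so the detector sees the same samples
    in the rotated frame.  Mild seeded noise breaks the exact plateau
    ties a noise-free raster would produce.
    """
    img = np.full((n, n), 200.0)
    yy, xx = np.mgrid[0:n, 0:n]
    for (cy, cx, r) in [(48, 56, 9), (112, 96, 11), (60, 120, 7)]:
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        core = 60 + 3.0 * (xx - cx)
        img = np.where(d < r, core + (200 - core) * np.clip((d - r + 2) / 2, 0, 1), img)
    img = img + np.random.default_rng(seed).normal(0, 1.0, (n, n))
    return np.clip(img, 0, 255).astype(np.uint8)


def gaussian_blob_image(n: int = 64, sigma: float = 3.0, contrast: float = 0.6) -> np.ndarray:
    """Single isotropic dark blob on a bright background (float [0,1])."""
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2
    blob = contrast * np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * sigma ** 2))
    return 0.8 - blob


def step_edge_image(n: int = 128) -> np.ndarray:
    img = np.zeros((n, n), dtype=np.uint8)
    img[:, n // 2:] = 200
    return img


@pytest.fixture
def blob_fixture():
    return shaded_blob_image()


@pytest.fixture
def step_edge():
    return step_edge_image()
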