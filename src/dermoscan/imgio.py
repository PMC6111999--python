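"""Image loading/saving and pixel-level transforms.

Images are plain numpy arrays: an RGB image is a ``(h, w, 3)`` uint8 array,
a grayscale image a ``(h, w)`` uint8 array, both with channel values in
[0, 255].  Every transform in this module preserves dimensions and keeps
outputs inside [0, 255].

The grayscale conversion, gamma correction and contrast adjustment follow
the exact pixel formulas used by the cluster-extraction stage:

* gray:      C = floor((R + G + B) / 3)
* gamma:     C -> round(255 * (C/255)**gamma)
* contrast:  C -> F * (C - 128) + 128, with F = 259*(omega+255) / (255*(259-omega)),
             clamped to [0, 255]
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as sk_resize

__all__ = [
    "Histogram",
    "load_image",
    "save_image",
    "to_gray",
    "gamma_correct",
    "adjust_contrast",
    "histograms",
    "resize",
]


@dataclass(frozen=True)
class Histogram:
    """256-bin intensity histogram of one channel of an image."""

    bins: np.ndarray  # shape (256,), non-negative counts
    channel: str  # one of {"gray", "R", "G", "B"}

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=np.int64)
        if bins.shape != (256,):
            raise ValueError("histogram must have exactly 256 bins")
        if (bins < 0).any():
            raise ValueError("histogram counts must be non-negative")
        object.__setattr__(self, "bins", bins)

    def normalized(self) -> np.ndarray:
        """Unit-mass copy of the bins (float); zero histogram stays zero."""
        total = self.bins.sum()
        if total == 0:
            return np.zeros(256, dtype=float)
        return self.bins / float(total)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) RGB image, got shape {img.shape}")
    return img


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected (h, w) grayscale image, got shape {img.shape}")
    return img


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG/BMP file as an ``(h, w, 3)`` uint8 RGB array.

    Alpha channels are discarded; grayscale files are replicated across the
    three channels.  Raises ``FileNotFoundError`` for missing files and
    ``ValueError`` for undecodable bytes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            im.load()
            rgb = im.convert("RGB")
    except (UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    return np.asarray(rgb, dtype=np.uint8)


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB or grayscale uint8 array to *path* (format from suffix)."""
    arr = np.asarray(img, dtype=np.uint8)
    Image.fromarray(arr).save(Path(path))


def to_gray(img: np.ndarray) -> np.ndarray:
    """Channel-average grayscale: C = floor((R + G + B) / 3), uint8."""
    img = _check_rgb(img)
    s = img.astype(np.uint32).sum(axis=2)
    return (s // 3).astype(np.uint8)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma correction C -> round(255 * (C/255)**gamma), clamped to [0, 255].

    gamma = 1 is a pixel-exact identity; gamma = 0 is rejected.
    """
    img = _check_gray(img)
    if gamma == 0:
        raise ValueError("gamma must be nonzero")
    lut = np.floor(255.0 * (np.arange(256) / 255.0) ** gamma + 0.5)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img]


def adjust_contrast(img: np.ndarray, omega: float) -> np.ndarray:
    """Contrast stretch about mid-gray with level *omega* in [-255, 255].

    F = 259*(omega + 255) / (255*(259 - omega)); C -> F*(C - 128) + 128,
    rounded half-up and clamped to [0, 255].  omega = 0 gives F = 1, a
    pixel-exact identity; 128 is a fixed point for every omega.
    """
    img = _check_gray(img)
    if not -255 <= omega <= 255:
        raise ValueError("omega must lie in [-255, 255]")
    factor = 259.0 * (omega + 255.0) / (255.0 * (259.0 - omega))
    lut = np.floor(factor * (np.arange(256, dtype=float) - 128.0) + 128.0 + 0.5)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img]


def histograms(img: np.ndarray) -> list[Histogram]:
    """Per-channel 256-bin histograms in the order gray, R, G, B."""
    img = _check_rgb(img)
    out = [Histogram(np.bincount(to_gray(img).ravel(), minlength=256), "gray")]
    for idx, name in enumerate("RGB"):
        counts = np.bincount(img[..., idx].ravel(), minlength=256)
        out.append(Histogram(counts, name))
    return out


def resize(img: np.ndarray, target_w: int, target_h: int) -> np.ndarray:
    """Bilinear resize of an RGB image to exactly (target_h, target_w)."""
    img = _check_rgb(img)
    if target_w < 1 or target_h < 1:
        raise ValueError("target dimensions must be positive")
    if (img.shape[1], img.shape[0]) == (target_w, target_h):
        return img.copy()
    out = sk_resize(img.astype(float), (target_h, target_w), order=1,
                    anti_aliasing=False, preserve_range=True)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
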