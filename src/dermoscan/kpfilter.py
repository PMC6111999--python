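"""Key-point screening against background, palette and shape priors.

Household photos contain far more furniture than skin.  Three cheap
filters discard key points that cannot be skin marks before the expensive
cluster/classification stages run:

* background filter — key points already present (same position, same
  color) in reference photos of the empty room are scene furniture;
* palette filter — key points whose local color is far from every skin
  tone anchor are clothing, jewelry or wall;
* elongation filter — key points sitting on long thin same-color shapes
  (borders, seams, cables) are discarded by growing the local region and
  testing its bounding-box aspect ratio.

All filters preserve order, never add key points, and are idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import imgio
from .clusterer import region_grow
from .scalespace import KeyPoint, SiftParams, detect_keypoints

__all__ = [
    "BackgroundReference",
    "SkinPalette",
    "DEFAULT_SKIN_PALETTE",
    "build_background_reference",
    "filter_background",
    "filter_palette",
    "filter_elongated",
]


@dataclass
class BackgroundReference:
    """Key points of the empty scene: (x, y, (R, G, B)) per entry."""

    entries: list[tuple[int, int, tuple[int, int, int]]]
    source_count: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source_count": self.source_count,
            "entries": [[x, y, list(color)] for x, y, color in self.entries],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundReference":
        payload = json.loads(Path(path).read_text())
        entries = [(int(x), int(y), (int(c[0]), int(c[1]), int(c[2])))
                   for x, y, c in payload["entries"]]
        return cls(entries=entries, source_count=int(payload["source_count"]))


@dataclass
class SkinPalette:
    """Anchor skin tones with a per-channel matching tolerance."""

    colors: list[tuple[int, int, int]]
    tolerance: int = 40

    def __post_init__(self) -> None:
        if not self.colors:
            raise ValueError("palette needs at least one anchor color")
        if not 0 <= self.tolerance <= 255:
            raise ValueError("tolerance must be in [0, 255]")

    def matches(self, color: np.ndarray) -> bool:
        anchors = np.asarray(self.colors, dtype=float)
        return bool((np.abs(anchors - np.asarray(color, dtype=float)).max(axis=1)
                     <= self.tolerance).any())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"colors": [list(c) for c in self.colors], "tolerance": self.tolerance}))

    @classmethod
    def from_json(cls, path: str | Path) -> "SkinPalette":
        payload = json.loads(Path(path).read_text())
        return cls(colors=[tuple(c) for c in payload["colors"]],
                   tolerance=int(payload["tolerance"]))


# Twelve anchor tones spanning pale to deep skin; a stand-in default a
# user is expected to override with tones of the actual household.
DEFAULT_SKIN_PALETTE = SkinPalette(
    colors=[
        (255, 224, 196), (245, 210, 180), (240, 195, 165), (228, 185, 150),
        (222, 170, 135), (210, 160, 125), (190, 140, 105), (170, 120, 90),
        (145, 100, 75), (120, 80, 60), (95, 65, 50), (70, 48, 38),
    ],
    tolerance=40,
)


def build_background_reference(
    photos: list[np.ndarray],
    params: SiftParams | None = None,
) -> BackgroundReference:
    """Detect key points in empty-room photos and store position + color.

    Entries are deduplicated by rounded coordinates (first photo wins).
    All photos must share the camera frame dimensions.
    """
    if not photos:
        raise ValueError("need at least one reference photo")
    shape = np.asarray(photos[0]).shape
    seen: dict[tuple[int, int], tuple[int, int, int]] = {}
    for photo in photos:
        photo = np.asarray(photo)
        if photo.shape != shape:
            raise ValueError("reference photos must share dimensions")
        gray = imgio.to_gray(photo)
        for kp in detect_keypoints(gray, params, descriptors=False):
            xi, yi = int(round(kp.x)), int(round(kp.y))
            if (xi, yi) not in seen:
                c = photo[yi, xi]
                seen[(xi, yi)] = (int(c[0]), int(c[1]), int(c[2]))
    entries = [(x, y, color) for (x, y), color in seen.items()]
    return BackgroundReference(entries=entries, source_count=len(photos))


def filter_background(
    kps: list[KeyPoint],
    img: np.ndarray,
    ref: BackgroundReference,
    pos_tol: int = 2,
    color_tol: int = 20,
) -> list[KeyPoint]:
    """Drop key points that re-appear at a stored background position.

    A key point is removed iff some reference entry lies within
    ``pos_tol`` pixels (per axis) of its rounded position AND the image
    color at the key point is within ``color_tol`` per channel of the
    stored color.
    """
    if not ref.entries:
        return list(kps)
    img = np.asarray(img)
    pos = np.array([[x, y] for x, y, _ in ref.entries], dtype=float)
    col = np.array([c for _, _, c in ref.entries], dtype=float)
    out: list[KeyPoint] = []
    for kp in kps:
        xi, yi = int(round(kp.x)), int(round(kp.y))
        near = np.abs(pos - [xi, yi]).max(axis=1) <= pos_tol
        if near.any():
            pixel = img[yi, xi].astype(float)
            if (np.abs(col[near] - pixel).max(axis=1) <= color_tol).any():
                continue
        out.append(kp)
    return out


def _median_color(img: np.ndarray, xi: int, yi: int) -> np.ndarray:
    h, w = img.shape[:2]
    y0, y1 = max(0, yi - 1), min(h, yi + 2)
    x0, x1 = max(0, xi - 1), min(w, xi + 2)
    patch = img[y0:y1, x0:x1].reshape(-1, 3)
    return np.median(patch, axis=0)


def filter_palette(
    kps: list[KeyPoint],
    img: np.ndarray,
    palette: SkinPalette | None = None,
) -> list[KeyPoint]:
    """Keep key points whose 3x3 median color matches a palette anchor."""
    palette = palette or DEFAULT_SKIN_PALETTE
    img = np.asarray(img)
    out = []
    for kp in kps:
        xi, yi = int(round(kp.x)), int(round(kp.y))
        if palette.matches(_median_color(img, xi, yi)):
            out.append(kp)
    return out


def filter_elongated(
    kps: list[KeyPoint],
    img: np.ndarray,
    aspect_limit: float = 5.0,
    tol: int = 10,
) -> list[KeyPoint]:
    """Drop key points sitting on long thin same-color structures.

    The same-intensity region around each key point is grown on the
    grayscale image (capped at 4096 px — larger regions are area-like,
    not line-like) and the key point is removed when the region
    bounding-box aspect ratio exceeds ``aspect_limit``.
    """
    if aspect_limit <= 1:
        raise ValueError("aspect_limit must exceed 1")
    gray = imgio.to_gray(np.asarray(img))
    out = []
    for kp in kps:
        xi, yi = int(round(kp.x)), int(round(kp.y))
        region = region_grow(gray, (yi, xi), tol, max_size=4096)
        if region.aspect_ratio <= aspect_limit:
            out.append(kp)
    return out
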