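"""Cluster extraction: turn each surviving key point into a normalized crop.

For every key point the pipeline crops a window of 15%w x 15%h around it,
simplifies the window (grayscale -> gamma correction -> contrast boost),
grows the same-intensity region containing the key point, rejects regions
covering more than 30% of the full image (the point sits on background,
not on a mark), crops to the region bounding box, restores the original
colors, and resizes to a uniform target size for classification.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from . import imgio
from .scalespace import KeyPoint

__all__ = ["ClusterParams", "PixelRegion", "Cluster", "region_grow",
           "extract_cluster", "clusters_from_image", "save_cluster"]


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the cluster-extraction stage.

    window_frac: crop window as a fraction of (w, h) of the full image.
    reject_frac: a grown region covering more than this fraction of the
        crop window disqualifies the key point (uniform background).
    gamma: gamma-correction coefficient applied to the window.
    omega: contrast level in [-255, 255] applied after gamma.
    color_tol: same-intensity tolerance for region growth (on the
        gamma/contrast-processed grayscale window).
    min_region: regions below this pixel count are rejected as noise.
    target_dim: (width, height) of the final uniform cluster image.
    """

    window_frac: float = 0.15
    reject_frac: float = 0.30
    gamma: float = 1.5
    omega: float = 128.0
    color_tol: int = 10
    min_region: int = 9
    target_dim: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if not 0 < self.window_frac < 1:
            raise ValueError("window_frac must be in (0, 1)")
        if not 0 < self.reject_frac < 1:
            raise ValueError("reject_frac must be in (0, 1)")
        if self.target_dim[0] < 8 or self.target_dim[1] < 8:
            raise ValueError("target_dim must be at least 8x8")


@dataclass
class PixelRegion:
    """4-connected pixel set grown from a seed."""

    mask: np.ndarray  # bool (h, w) of the image it was grown on
    seed: tuple[int, int]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) inclusive
    size: int

    @property
    def pixels(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in zip(*np.nonzero(self.mask))}

    @property
    def aspect_ratio(self) -> float:
        """Bounding-box long side over short side (>= 1)."""
        h = self.bbox[2] - self.bbox[0] + 1
        w = self.bbox[3] - self.bbox[1] + 1
        return max(h, w) / max(1, min(h, w))


def region_grow(
    img: np.ndarray,
    seed: tuple[int, int],
    tol: float,
    max_size: int | None = None,
) -> PixelRegion:
    """Grow the maximal 4-connected region around *seed*.

    A pixel belongs to the region iff it is 4-connected to the seed
    through pixels whose intensity lies within *tol* of the SEED
    intensity.  Implemented with an explicit queue (breadth-first), never
    recursion, so deep regions cannot overflow the interpreter stack.
    ``max_size`` optionally stops growth early (the mask is then a
    truncated but still connected subset).
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("region_grow expects a 2-D grayscale image")
    h, w = arr.shape
    si, sj = int(seed[0]), int(seed[1])
    if not (0 <= si < h and 0 <= sj < w):
        raise ValueError(f"seed {seed} outside image of shape {arr.shape}")

    seed_val = arr[si, sj]
    accept = np.abs(arr - seed_val) <= tol
    mask = np.zeros((h, w), dtype=bool)
    mask[si, sj] = True
    queue: deque[tuple[int, int]] = deque([(si, sj)])
    size = 1
    while queue:
        i, j = queue.popleft()
        for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if 0 <= ni < h and 0 <= nj < w and accept[ni, nj] and not mask[ni, nj]:
                mask[ni, nj] = True
                size += 1
                queue.append((ni, nj))
                if max_size is not None and size >= max_size:
                    queue.clear()
                    break
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
    return PixelRegion(mask=mask, seed=(si, sj), bbox=bbox, size=size)


@dataclass
class Cluster:
    """Normalized sub-image around one key point."""

    image: np.ndarray  # (target_h, target_w, 3) uint8
    source_keypoint: KeyPoint | None
    region_size: int
    state: str = "raw"  # raw -> screened -> blurred
    bbox: tuple[int, int, int, int] | None = None  # full-image coords, inclusive
    region_pixels: frozenset[tuple[int, int]] | None = field(default=None, repr=False)
    screen: "object | None" = None  # ScreenDecision once screened


def _window_bounds(center: int, size: int, limit: int) -> tuple[int, int]:
    """Start/stop of a crop of *size* centered at *center*, clipped to [0, limit)."""
    start = center - size // 2
    start = max(0, min(start, limit - size))
    return start, start + size


def extract_cluster(
    img: np.ndarray,
    kp: KeyPoint,
    params: ClusterParams | None = None,
) -> Cluster | None:
    """Build a cluster for one key point, or ``None`` when rejected.

    Rejection happens when the grown region covers more than
    ``reject_frac`` of the crop-window area (the point sits on uniform
    background, not on a compact mark) or fewer than ``min_region``
    pixels (isolated noise).
    """
    params = params or ClusterParams()
    img = np.asarray(img)
    h, w = img.shape[:2]
    xi, yi = int(round(kp.x)), int(round(kp.y))
    if not (0 <= xi < w and 0 <= yi < h):
        raise ValueError("key point outside image")

    win_w = max(3, int(np.ceil(params.window_frac * w)))
    win_h = max(3, int(np.ceil(params.window_frac * h)))
    x0, x1 = _window_bounds(xi, win_w, w)
    y0, y1 = _window_bounds(yi, win_h, h)
    window = img[y0:y1, x0:x1]

    gray = imgio.to_gray(window)
    gray = imgio.gamma_correct(gray, params.gamma)
    gray = imgio.adjust_contrast(gray, params.omega)

    region = region_grow(gray, (yi - y0, xi - x0), params.color_tol)
    if region.size > params.reject_frac * win_w * win_h:
        return None
    if region.size < params.min_region:
        return None

    r0, c0, r1, c1 = region.bbox
    # restore original colors over the region bounding box
    color_crop = window[r0:r1 + 1, c0:c1 + 1]
    resized = imgio.resize(color_crop, params.target_dim[0], params.target_dim[1])
    pixels = frozenset((int(i) + y0, int(j) + x0) for i, j in zip(*np.nonzero(region.mask)))
    return Cluster(
        image=resized,
        source_keypoint=kp,
        region_size=region.size,
        state="raw",
        bbox=(r0 + y0, c0 + x0, r1 + y0, c1 + x0),
        region_pixels=pixels,
    )


def clusters_from_image(
    img: np.ndarray,
    kps: list[KeyPoint],
    params: ClusterParams | None = None,
) -> list[Cluster]:
    """Extract a cluster per key point and merge near-duplicates.

    Two clusters whose grown regions overlap by more than 50% (of the
    smaller region) describe the same mark; the one with the larger
    detector response is kept.
    """
    params = params or ClusterParams()
    clusters = [c for c in (extract_cluster(img, kp, params) for kp in kps) if c is not None]
    clusters.sort(key=lambda c: abs(c.source_keypoint.response) if c.source_keypoint else 0.0,
                  reverse=True)
    kept: list[Cluster] = []
    for cand in clusters:
        dup = False
        for other in kept:
            inter = len(cand.region_pixels & other.region_pixels)
            smaller = min(len(cand.region_pixels), len(other.region_pixels))
            if smaller and inter / smaller > 0.5:
                dup = True
                break
        if not dup:
            kept.append(cand)
    return kept


def save_cluster(cluster: Cluster, directory: str | Path, stem: str, idx: int) -> Path:
    """Write the cluster PNG plus a JSON sidecar with its provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png = directory / f"{stem}_{idx}.png"
    imgio.save_image(cluster.image, png)
    kp = cluster.source_keypoint
    sidecar = {
        "keypoint": None if kp is None else {
            "x": kp.x, "y": kp.y, "sigma": kp.sigma,
            "orientation": kp.orientation, "response": kp.response,
        },
        "region_size": cluster.region_size,
        "state": cluster.state,
        "bbox": cluster.bbox,
    }
    png.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return png
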