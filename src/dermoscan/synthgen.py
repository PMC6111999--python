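"""Seeded generator of synthetic skin scenes and labeled cluster datasets.

The generator emulates the two kinds of input the pipeline consumes:

* household photos — a skin-textured body region next to a cluttered
  wall, with elliptical nevi rendered onto the skin and full ground
  truth (pixel masks, skin mask, clutter boxes) retained for testing;
* dermoscopy-like cluster crops — small labeled images of single nevi
  for training and screening databases.

Nevus appearance follows the clinical A-D warning signs: Asymmetry (the
two vertical halves of the ellipse have different heights), Border
fuzziness (a soft alpha ramp straddling the nominal outline, so the
half-opacity contour keeps the analytic area), Color variegation
(angular sectors of distinct shades) and Diameter.  The generator labels
a nevus ``suspicious`` whenever diameter exceeds 6 mm, asymmetry exceeds
0.5, or it carries 3+ shades; criterion E (evolution) is available as a
paired-scene mode that re-renders the same scene with an enlarged nevus.

The pixel scale is explicit: ``px_per_mm`` converts the clinical
diameter criterion into pixels (10 px/mm for close-up cluster crops,
4 px/mm for room-scale scenes).  Everything is bit-reproducible from
(parameters, seed).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import imgio
from .clusterer import Cluster

__all__ = [
    "NevusSpec",
    "SceneTruth",
    "render_nevus",
    "make_scene",
    "make_background_photos",
    "make_cluster_dataset",
    "make_skin_patches",
    "write_dataset",
]

SKIN_BASE = np.array([210.0, 160.0, 125.0])
WALL_BASE = np.array([186.0, 196.0, 210.0])  # cool blue-gray, off the skin palette
NEVUS_DARK = np.array([88.0, 58.0, 42.0])


@dataclass(frozen=True)
class NevusSpec:
    """Parameters of one rendered nevus.

    The label is forced to ``suspicious`` whenever the A, C or D warning
    sign fires (asymmetry > 0.5, 3+ shades, diameter > 6 mm), mirroring
    the clinical rule the classifier is meant to learn.
    """

    center: tuple[float, float]  # (x, y) pixels
    diameter_mm: float
    px_per_mm: float = 10.0
    asymmetry: float = 0.0
    border_fuzz: float = 0.0
    n_shades: int = 1
    base_color: tuple[float, float, float] = (88.0, 58.0, 42.0)
    label: str = "benign"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.px_per_mm <= 0:
            raise ValueError("diameter and pixel scale must be positive")
        if not 0 <= self.asymmetry <= 1 or not 0 <= self.border_fuzz <= 1:
            raise ValueError("asymmetry and border_fuzz must lie in [0, 1]")
        if self.n_shades < 1:
            raise ValueError("n_shades must be >= 1")
        if (self.diameter_mm > 6.0 or self.asymmetry > 0.5 or self.n_shades >= 3):
            object.__setattr__(self, "label", "suspicious")

    @property
    def radius_px(self) -> float:
        return self.diameter_mm * self.px_per_mm / 2.0

    @property
    def expected_area_px(self) -> float:
        """Analytic mask area: pi r^2 (1 - asymmetry/2)."""
        return math.pi * self.radius_px ** 2 * (1.0 - self.asymmetry / 2.0)


@dataclass
class SceneTruth:
    """A rendered scene plus everything needed to verify the pipeline."""

    image: np.ndarray  # (h, w, 3) uint8
    nevi: list[tuple[NevusSpec, np.ndarray]]  # spec + boolean pixel mask
    background_objects: list[tuple[int, int, int, int]]  # (x0, y0, x1, y1)
    skin_mask: np.ndarray  # bool (h, w)
    wall_image: np.ndarray = field(repr=False, default=None)  # empty-room render
    seed: int = 0


def render_nevus(canvas: np.ndarray, spec: NevusSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one nevus onto *canvas* (float RGB, modified in place).

    Returns the boolean ground-truth mask (alpha >= 0.5).  The outline is
    an ellipse with horizontal semi-axis r and vertical semi-axes
    b*(1 +/- asymmetry/2) for the upper/lower halves, where
    b = r*(1 - asymmetry/2); the half areas then sum to the analytic
    pi r^2 (1 - asymmetry/2).
    """
    h, w = canvas.shape[:2]
    cx, cy = spec.center
    r = spec.radius_px
    b = r * (1.0 - spec.asymmetry / 2.0)
    b_top = b * (1.0 + spec.asymmetry / 2.0)
    b_bot = b * (1.0 - spec.asymmetry / 2.0)

    pad = int(math.ceil(r * 1.5)) + 3
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    dx, dy = np.meshgrid(xs, ys)
    bv = np.where(dy < 0, b_top, b_bot)
    d = np.sqrt((dx / r) ** 2 + (dy / np.maximum(bv, 1e-9)) ** 2)

    fw = max(1e-6, 0.5 * spec.border_fuzz)  # fuzz band straddles d = 1
    alpha = np.clip((1.0 + fw / 2.0 - d) / fw, 0.0, 1.0)

    # color variegation: angular sectors with per-sector shade factors
    shades = np.asarray(spec.base_color, dtype=float)[None, :] * \
        (0.75 + 0.5 * rng.random(spec.n_shades))[:, None]
    if spec.n_shades == 1:
        sector = np.zeros_like(d, dtype=int)
    else:
        theta = (np.arctan2(dy, dx) + math.pi) / (2.0 * math.pi)
        offsets = rng.random()
        sector = ((theta + offsets) * spec.n_shades).astype(int) % spec.n_shades
    color = shades[sector]

    patch = canvas[y0:y1, x0:x1]
    patch[:] = alpha[..., None] * color + (1.0 - alpha[..., None]) * patch

    mask = np.zeros((h, w), dtype=bool)
    mask[y0:y1, x0:x1] = alpha >= 0.5
    return mask


def _skin_texture(h: int, w: int, rng: np.random.Generator,
                  tone: np.ndarray = SKIN_BASE, noise_sigma: float = 2.0) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    phase = rng.uniform(0, 2 * math.pi, size=2)
    lowfreq = 6.0 * np.sin(2 * math.pi * xx / max(w, 1) + phase[0]) \
        + 4.0 * np.sin(2 * math.pi * yy / max(h, 1) + phase[1])
    base = tone[None, None, :] + lowfreq[..., None]
    return base + rng.normal(0.0, noise_sigma, size=(h, w, 3))


def _wall_texture(h: int, w: int, rng: np.random.Generator,
                  clutter: int, noise_sigma: float = 1.5,
                  restrict_x: int | None = None) -> tuple[np.ndarray, list]:
    yy = np.mgrid[0:h, 0:w][0].astype(float)
    img = WALL_BASE[None, None, :] + (8.0 * yy / max(h, 1))[..., None]
    img = img + rng.normal(0.0, noise_sigma, size=(h, w, 3))
    boxes = []
    limit = restrict_x if restrict_x is not None else w
    for _ in range(clutter):
        bw = int(rng.integers(12, max(13, limit // 3)))
        bh = int(rng.integers(12, max(13, h // 4)))
        bx = int(rng.integers(0, max(1, limit - bw)))
        by = int(rng.integers(0, max(1, h - bh)))
        color = rng.uniform(30, 220, size=3)
        img[by:by + bh, bx:bx + bw] = color + rng.normal(0, 1.0, size=(bh, bw, 3))
        boxes.append((bx, by, bx + bw - 1, by + bh - 1))
    return img, boxes


def _random_specs(n: int, rng: np.random.Generator, px_per_mm: float,
                  force_label: str | None) -> list[dict]:
    specs = []
    for _ in range(n):
        suspicious = force_label == "suspicious" if force_label else bool(rng.random() < 0.5)
        if suspicious:
            specs.append(dict(
                diameter_mm=float(rng.uniform(5.0, 7.5)),
                asymmetry=float(rng.uniform(0.55, 0.85)),
                border_fuzz=float(rng.uniform(0.3, 0.7)),
                n_shades=int(rng.integers(3, 5)),
                px_per_mm=px_per_mm))
        else:
            specs.append(dict(
                diameter_mm=float(rng.uniform(2.2, 3.8)),
                asymmetry=float(rng.uniform(0.0, 0.25)),
                border_fuzz=float(rng.uniform(0.0, 0.2)),
                n_shades=1,
                px_per_mm=px_per_mm))
    return specs


def make_scene(w: int, h: int, n_nevi: int, clutter: int, seed: int,
               px_per_mm: float = 4.0,
               force_label: str | None = None,
               enlarge: float = 1.0) -> SceneTruth:
    """Render a body-plus-wall scene with ground truth.

    The right 70% of the frame is skin, the left 30% wall with *clutter*
    rectangles.  ``force_label`` pins every nevus to one class;
    ``enlarge`` scales all diameters (paired-scene evolution mode: render
    the same seed twice with enlarge > 1 to emulate a growing nevus).
    """
    if w < 128 or h < 128:
        raise ValueError("scene must be at least 128x128")
    rng = np.random.default_rng(seed)
    wall_rng = np.random.default_rng(rng.integers(2 ** 31))
    skin_x0 = int(0.3 * w)

    # clutter stays inside the wall strip so scene and empty-room renders
    # agree on every background feature
    wall_full, boxes = _wall_texture(h, w, wall_rng, clutter, restrict_x=skin_x0 - 8)
    canvas = wall_full.copy()
    skin = _skin_texture(h, w - skin_x0, rng)
    canvas[:, skin_x0:] = skin
    skin_mask = np.zeros((h, w), dtype=bool)
    skin_mask[:, skin_x0:] = True

    specs = _random_specs(n_nevi, rng, px_per_mm, force_label)
    nevi: list[tuple[NevusSpec, np.ndarray]] = []
    placed: list[tuple[float, float, float]] = []
    for sdict in specs:
        sdict = dict(sdict, diameter_mm=sdict["diameter_mm"] * enlarge)
        r = sdict["diameter_mm"] * px_per_mm / 2.0
        margin = r + 6
        for _ in range(200):
            cx = float(rng.uniform(skin_x0 + margin, w - margin))
            cy = float(rng.uniform(margin, h - margin))
            if all(math.hypot(cx - px, cy - py) > r + pr + 8 for px, py, pr in placed):
                break
        else:
            raise ValueError("cannot place nevi disjointly; reduce n_nevi")
        spec = NevusSpec(center=(cx, cy), **sdict)
        mask = render_nevus(canvas, spec, rng)
        nevi.append((spec, mask))
        placed.append((cx, cy, r))

    image = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    wall_image = np.clip(np.floor(wall_full + 0.5), 0, 255).astype(np.uint8)
    return SceneTruth(image=image, nevi=nevi, background_objects=boxes,
                      skin_mask=skin_mask, wall_image=wall_image, seed=seed)


def make_background_photos(scene: SceneTruth, n: int,
                           lighting_jitter: float = 0.0,
                           seed: int = 0) -> list[np.ndarray]:
    """Empty-room reference photos: the scene with skin replaced by wall.

    Each of the *n* photos gets an independent global brightness offset
    drawn uniformly from [-lighting_jitter, +lighting_jitter].
    """
    if n < 1:
        raise ValueError("need n >= 1 photos")
    rng = np.random.default_rng(seed)
    base = scene.wall_image.astype(float)
    photos = []
    for _ in range(n):
        offset = float(rng.uniform(-lighting_jitter, lighting_jitter)) if lighting_jitter else 0.0
        photos.append(np.clip(base + offset, 0, 255).astype(np.uint8))
    return photos


def _render_cluster(spec_kwargs: dict, rng: np.random.Generator,
                    target_dim: tuple[int, int], render_px: int = 96) -> tuple[Cluster, int]:
    """Render one nevus patch, crop to the mask box and resize (as the
    pipeline would), returning the cluster and its mask area."""
    canvas = _skin_texture(render_px, render_px, rng)
    center = (render_px / 2 + float(rng.uniform(-3, 3)),
              render_px / 2 + float(rng.uniform(-3, 3)))
    spec = NevusSpec(center=center, **spec_kwargs)
    mask = render_nevus(canvas, spec, rng)
    rows, cols = np.nonzero(mask)
    r0, r1 = max(0, rows.min() - 2), min(render_px, rows.max() + 3)
    c0, c1 = max(0, cols.min() - 2), min(render_px, cols.max() + 3)
    img = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    crop = imgio.resize(img[r0:r1, c0:c1], target_dim[0], target_dim[1])
    cluster = Cluster(image=crop, source_keypoint=None,
                      region_size=int(mask.sum()), state="raw",
                      bbox=(r0, c0, r1 - 1, c1 - 1))
    return cluster, int(mask.sum())


def make_cluster_dataset(n_per_class: int, target_dim: tuple[int, int] = (64, 64),
                         seed: int = 0,
                         benign_diameter_mm: tuple[float, float] = (2.5, 4.0),
                         suspicious_diameter_mm: tuple[float, float] = (4.2, 5.8),
                         ) -> list[tuple[Cluster, str]]:
    """Balanced labeled cluster set (benign first, then suspicious).

    Benign: near-round, single shade, sharp border, 2.5-4 mm.
    Suspicious: asymmetric, 3-5 shades, fuzzy border, 4.2-5.8 mm.
    Rendered at 10 px/mm and cropped/resized the way the pipeline crops
    real clusters.  The diameter ranges are exposed so class separation
    is controllable (widely separated ranges give clusters that are
    linearly separable on area alone).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[Cluster, str]] = []
    for _ in range(n_per_class):
        kwargs = dict(diameter_mm=float(rng.uniform(*benign_diameter_mm)),
                      asymmetry=float(rng.uniform(0.0, 0.25)),
                      border_fuzz=float(rng.uniform(0.0, 0.2)),
                      n_shades=1, px_per_mm=10.0)
        cluster, _ = _render_cluster(kwargs, rng, target_dim)
        out.append((cluster, "benign"))
    for _ in range(n_per_class):
        kwargs = dict(diameter_mm=float(rng.uniform(*suspicious_diameter_mm)),
                      asymmetry=float(rng.uniform(0.55, 0.9)),
                      border_fuzz=float(rng.uniform(0.4, 0.9)),
                      n_shades=int(rng.integers(3, 6)), px_per_mm=10.0)
        cluster, _ = _render_cluster(kwargs, rng, target_dim)
        out.append((cluster, "suspicious"))
    return out


def make_skin_patches(n: int, dim: tuple[int, int] = (64, 64), seed: int = 0) -> list[np.ndarray]:
    """Plain-skin exemplar images (no nevus) for screening databases."""
    rng = np.random.default_rng(seed)
    return [np.clip(np.floor(_skin_texture(dim[1], dim[0], rng) + 0.5), 0, 255).astype(np.uint8)
            for _ in range(n)]


def write_dataset(dataset: list[tuple[Cluster, str]], out_dir: str | Path) -> Path:
    """Write cluster PNGs plus a manifest CSV (path, label, region_size)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "region_size"])
        for idx, (cluster, label) in enumerate(dataset):
            name = f"cluster_{idx:04d}.png"
            imgio.save_image(cluster.image, out_dir / name)
            writer.writerow([name, label, cluster.region_size])
    return manifest
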