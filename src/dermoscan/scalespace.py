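"""Scale-space key-point detection (SIFT-style).

The detector follows the classic four stages:

1. Build a Gaussian scale space L(x, y, sigma) = G(sigma) * I per octave
   (each octave downsampled by 2) and the Difference-of-Gaussian stack
   D = L(k*sigma) - L(sigma).
2. Find candidate extrema: points strictly greater (or smaller) than all
   26 neighbours in the 3x3x3 cube spanning the adjacent DoG levels.
3. Localize candidates to sub-pixel accuracy with a second-order Taylor
   expansion of D, rejecting low-contrast points (|D(x_hat)| below a
   threshold on [0,1]-normalized intensities) and edge responses via the
   2x2 spatial Hessian ratio test tr(H)^2/det(H) >= (r+1)^2/r.
4. Assign one or more orientations from a gradient-magnitude-weighted
   histogram over the 3x3 neighbourhood (every peak above 80% of the
   maximum bin spawns a key point) and compute a 128-dimensional
   gradient-histogram descriptor on the orientation-aligned patch.

Coordinates: origin top-left, ``x`` rightward (columns), ``y`` downward
(rows).  Arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SiftParams",
    "ScaleSpace",
    "KeyPoint",
    "gaussian_kernel",
    "convolve",
    "build_scale_space",
    "detect_extrema",
    "localize_and_filter",
    "gradient_field",
    "assign_orientation",
    "compute_descriptor",
    "detect_keypoints",
    "dump_keypoints_csv",
]


@dataclass(frozen=True)
class SiftParams:
    """Detector parameters.

    sigma0: base blur of the first scale-space level.
    k: multiplicative scale step between levels (k^3 = 2 by default, so
       three DoG steps span one octave).
    levels_per_octave: number of DoG planes per octave (>= 3; extrema are
       searched on the interior planes only).
    octaves: number of downsampling octaves.
    contrast_threshold: minimum |D(x_hat)| on [0,1] intensities.
    r: edge-ratio parameter; key points with principal-curvature ratio
       above (r+1)^2/r are discarded as edge responses.
    orientation_bins: bins of the orientation histogram.
    """

    sigma0: float = 1.6
    k: float = 2.0 ** (1.0 / 3.0)
    levels_per_octave: int = 5
    octaves: int = 4
    contrast_threshold: float = 0.03
    r: float = 10.0
    orientation_bins: int = 36

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.k <= 1:
            raise ValueError("k must exceed 1")
        if self.levels_per_octave < 3:
            raise ValueError("need at least 3 DoG levels per octave")
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if self.contrast_threshold < 0:
            raise ValueError("contrast_threshold must be >= 0")
        if self.r <= 1:
            raise ValueError("edge ratio r must exceed 1")
        if self.orientation_bins < 1:
            raise ValueError("orientation_bins must be >= 1")

    @property
    def edge_ratio_limit(self) -> float:
        return (self.r + 1.0) ** 2 / self.r


@dataclass
class ScaleSpace:
    """Gaussian pyramid and DoG stack.

    gaussians[o] is a float array (levels_per_octave + 1, h_o, w_o);
    dogs[o][l] = gaussians[o][l + 1] - gaussians[o][l].
    """

    gaussians: list[np.ndarray]
    dogs: list[np.ndarray]
    params: SiftParams

    def sigma_at(self, octave: int, level: float) -> float:
        """Absolute scale of DoG/Gaussian level (fractional allowed)."""
        return self.params.sigma0 * (self.params.k ** level) * (2.0 ** octave)


@dataclass
class KeyPoint:
    """A localized scale-space feature in original-image coordinates."""

    x: float
    y: float
    sigma: float
    orientation: float = 0.0
    response: float = 0.0
    octave: int = 0
    level: float = 0.0
    descriptor: np.ndarray | None = field(default=None, repr=False)


def gaussian_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Discrete 2-D Gaussian on [-radius, radius]^2, normalized to sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = max(1, int(math.ceil(3.0 * sigma)))
    if radius < 1:
        raise ValueError("radius must be >= 1")
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    kern = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2)) / (2.0 * math.pi * sigma ** 2)
    return kern / kern.sum()


def convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dense 2-D convolution with edge-replicated borders (float output)."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValueError("kernel must be 2-D with odd side lengths")
    return ndimage.convolve(np.asarray(img, dtype=float), kernel, mode="nearest")


def build_scale_space(img: np.ndarray, params: SiftParams | None = None) -> ScaleSpace:
    """Gaussian pyramid + DoG stack for a grayscale image.

    Intensities are normalized to [0, 1] before blurring so that the
    contrast threshold has a fixed meaning.  Each octave holds
    ``levels_per_octave + 1`` Gaussian planes at sigma0 * k^l; the next
    octave starts from the plane whose blur has doubled, subsampled by 2.
    """
    params = params or SiftParams()
    base = np.asarray(img, dtype=float)
    if base.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if base.max() > 1.0:
        base = base / 255.0
    min_side = 2 ** (params.octaves - 1) * 8
    if min(base.shape) < 16 or min(base.shape) < min_side:
        raise ValueError(
            f"image {base.shape} too small for {params.octaves} octaves (needs >= {max(16, min_side)} px)"
        )

    n_gauss = params.levels_per_octave + 1
    # index of the plane whose relative blur is (closest to) 2*sigma0
    double_level = min(n_gauss - 1, round(math.log(2.0, params.k)))

    gaussians: list[np.ndarray] = []
    dogs: list[np.ndarray] = []
    current = ndimage.gaussian_filter(base, params.sigma0, mode="nearest")
    for octave in range(params.octaves):
        planes = [current]
        for lvl in range(1, n_gauss):
            s_prev = params.sigma0 * params.k ** (lvl - 1)
            s_next = params.sigma0 * params.k ** lvl
            inc = math.sqrt(s_next ** 2 - s_prev ** 2)
            planes.append(ndimage.gaussian_filter(planes[-1], inc, mode="nearest"))
        stack = np.stack(planes)
        gaussians.append(stack)
        dogs.append(stack[1:] - stack[:-1])
        current = planes[double_level][::2, ::2].copy()
    return ScaleSpace(gaussians=gaussians, dogs=dogs, params=params)


def detect_extrema(ss: ScaleSpace) -> list[tuple[int, int, int, int]]:
    """Candidate extrema as (octave, dog_level, y, x) octave coordinates.

    A point qualifies iff its DoG value is strictly greater than all 26
    neighbours in the 3x3x3 cube (own level plus both adjacent levels),
    or strictly smaller than all of them.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    out: list[tuple[int, int, int, int]] = []
    for octave, dog in enumerate(ss.dogs):
        if dog.shape[0] < 3:
            continue
        neigh_max = ndimage.maximum_filter(dog, footprint=footprint, mode="constant", cval=-np.inf)
        neigh_min = ndimage.minimum_filter(dog, footprint=footprint, mode="constant", cval=np.inf)
        is_ext = (dog > neigh_max) | (dog < neigh_min)
        is_ext[0, :, :] = is_ext[-1, :, :] = False
        is_ext[:, 0, :] = is_ext[:, -1, :] = False
        is_ext[:, :, 0] = is_ext[:, :, -1] = False
        for lvl, y, x in zip(*np.nonzero(is_ext)):
            out.append((octave, int(lvl), int(y), int(x)))
    return out


def _dog_derivatives(dog: np.ndarray, lvl: int, y: int, x: int) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of D at an interior sample, order (x, y, level)."""
    d = dog
    gx = 0.5 * (d[lvl, y, x + 1] - d[lvl, y, x - 1])
    gy = 0.5 * (d[lvl, y + 1, x] - d[lvl, y - 1, x])
    gs = 0.5 * (d[lvl + 1, y, x] - d[lvl - 1, y, x])
    c = d[lvl, y, x]
    dxx = d[lvl, y, x + 1] + d[lvl, y, x - 1] - 2 * c
    dyy = d[lvl, y + 1, x] + d[lvl, y - 1, x] - 2 * c
    dss = d[lvl + 1, y, x] + d[lvl - 1, y, x] - 2 * c
    dxy = 0.25 * (d[lvl, y + 1, x + 1] - d[lvl, y + 1, x - 1] - d[lvl, y - 1, x + 1] + d[lvl, y - 1, x - 1])
    dxs = 0.25 * (d[lvl + 1, y, x + 1] - d[lvl + 1, y, x - 1] - d[lvl - 1, y, x + 1] + d[lvl - 1, y, x - 1])
    dys = 0.25 * (d[lvl + 1, y + 1, x] - d[lvl + 1, y - 1, x] - d[lvl - 1, y + 1, x] + d[lvl - 1, y - 1, x])
    grad = np.array([gx, gy, gs])
    hess = np.array([[dxx, dxy, dxs], [dxy, dyy, dys], [dxs, dys, dss]])
    return grad, hess


def localize_and_filter(
    candidate: tuple[int, int, int, int],
    ss: ScaleSpace,
    params: SiftParams | None = None,
) -> KeyPoint | None:
    """Sub-pixel localization with contrast and edge rejection.

    Solves the Taylor stationary condition for the 3-D offset, re-anchors
    the candidate when an offset component exceeds 0.5 (up to 5 retries),
    rejects |D(x_hat)| < contrast_threshold, singular Hessians, and edge
    responses with tr(H)^2/det(H) >= (r+1)^2/r.  Returns ``None`` on
    rejection.
    """
    params = params or ss.params
    octave, lvl, y, x = candidate
    dog = ss.dogs[octave]
    n_lvl, h, w = dog.shape

    if not (1 <= lvl < n_lvl - 1 and 1 <= y < h - 1 and 1 <= x < w - 1):
        return None
    offset = np.zeros(3)
    for _ in range(5):
        grad, hess = _dog_derivatives(dog, lvl, y, x)
        try:
            offset = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(offset) <= 0.5):
            break
        # re-anchor towards the offset; clamped to the interior so an
        # extremum at the sampled boundary (octave seam) is interpolated
        # rather than lost
        x = int(np.clip(x + round(float(np.clip(offset[0], -1, 1))), 1, w - 2))
        y = int(np.clip(y + round(float(np.clip(offset[1], -1, 1))), 1, h - 2))
        lvl = int(np.clip(lvl + round(float(np.clip(offset[2], -1, 1))), 1, n_lvl - 2))
    else:
        # oscillation between adjacent cells: the extremum sits near the
        # shared boundary, so keep the last anchor with a clamped offset
        offset = np.clip(offset, -0.5, 0.5)

    value = dog[lvl, y, x] + 0.5 * float(grad @ offset)
    if abs(value) < params.contrast_threshold:
        return None

    # 2x2 spatial Hessian ratio test for edge-like responses
    dxx, dxy = hess[0, 0], hess[0, 1]
    dyy = hess[1, 1]
    det = dxx * dyy - dxy * dxy
    tr = dxx + dyy
    if det <= 0 or tr * tr / det >= params.edge_ratio_limit:
        return None

    scale = 2.0 ** octave
    return KeyPoint(
        x=(x + float(offset[0])) * scale,
        y=(y + float(offset[1])) * scale,
        sigma=ss.sigma_at(octave, lvl + float(offset[2])),
        response=float(value),
        octave=octave,
        level=lvl + float(offset[2]),
    )


def gradient_field(plane: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradient magnitude m and orientation phi by central differences.

    m = sqrt((L(x+1,y)-L(x-1,y))^2 + (L(x,y+1)-L(x,y-1))^2) (no 1/2
    factor), phi = atan2(dy, dx) in (-pi, pi].  The 1-pixel border is
    zeroed out.
    """
    p = np.asarray(plane, dtype=float)
    dx = np.zeros_like(p)
    dy = np.zeros_like(p)
    dx[1:-1, 1:-1] = p[1:-1, 2:] - p[1:-1, :-2]
    dy[1:-1, 1:-1] = p[2:, 1:-1] - p[:-2, 1:-1]
    m = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = 0.0
    return m, phi


def _octave_plane(kp: KeyPoint, ss: ScaleSpace) -> tuple[np.ndarray, int, int, float]:
    """Gaussian plane nearest kp.sigma plus octave-frame position."""
    lvl = int(np.clip(round(kp.level), 0, ss.gaussians[kp.octave].shape[0] - 1))
    plane = ss.gaussians[kp.octave][lvl]
    scale = 2.0 ** kp.octave
    xo = int(round(kp.x / scale))
    yo = int(round(kp.y / scale))
    sigma_rel = ss.params.sigma0 * ss.params.k ** lvl
    return plane, yo, xo, sigma_rel


def assign_orientation(kp: KeyPoint, ss: ScaleSpace, params: SiftParams | None = None) -> list[KeyPoint]:
    """Dominant gradient orientations of a key point.

    The orientation histogram is accumulated over the 3x3 neighbourhood of
    the key point on the Gaussian plane nearest its scale, each sample
    weighted by m * exp(-d^2 / (2 sigma^2)).  Every histogram peak at or
    above 80% of the maximum bin yields one oriented copy of the key
    point.  Border key points (no room for central differences) are
    rejected (empty list).
    """
    params = params or ss.params
    plane, yo, xo, sigma_rel = _octave_plane(kp, ss)
    h, w = plane.shape
    if not (2 <= yo < h - 2 and 2 <= xo < w - 2):
        return []
    m, phi = gradient_field(plane)
    nbins = params.orientation_bins
    hist = np.zeros(nbins)
    for dj in (-1, 0, 1):
        for di in (-1, 0, 1):
            yy, xx = yo + dj, xo + di
            dist = math.hypot(di, dj)
            weight = m[yy, xx] * math.exp(-(dist ** 2) / (2.0 * sigma_rel ** 2))
            ang = phi[yy, xx] % (2.0 * math.pi)
            b = int(ang / (2.0 * math.pi) * nbins) % nbins
            hist[b] += weight
    peak = hist.max()
    if peak <= 0:
        return []
    out: list[KeyPoint] = []
    for b in np.nonzero(hist >= 0.8 * peak)[0]:
        theta = (b + 0.5) * 2.0 * math.pi / nbins
        out.append(replace(kp, orientation=float(theta % (2.0 * math.pi))))
    return out


def compute_descriptor(kp: KeyPoint, ss: ScaleSpace) -> np.ndarray | None:
    """128-D gradient-histogram descriptor of an oriented key point.

    The 16x16 neighbourhood (octave frame) is rotated to the key-point
    orientation, split into 4x4 even areas, and each area contributes an
    8-bin histogram of gradient magnitudes by relative orientation.  The
    concatenated 128 values are L2-normalized; an all-zero vector (flat
    patch) is returned unnormalized.  Returns ``None`` when the rotated
    neighbourhood would leave the image.
    """
    plane, yo, xo, _ = _octave_plane(kp, ss)
    h, w = plane.shape
    half = 8
    # rotated 16x16 sampling grid; reject if any sample (plus 1px for
    # finite differences) falls outside the plane
    cos_t, sin_t = math.cos(kp.orientation), math.sin(kp.orientation)
    reach = half * math.sqrt(2.0) + 2
    if not (reach <= xo < w - reach and reach <= yo < h - reach):
        return None
    desc = np.zeros((4, 4, 8))
    for v in range(16):
        for u in range(16):
            du, dv = u - half + 0.5, v - half + 0.5
            sx = xo + du * cos_t - dv * sin_t
            sy = yo + du * sin_t + dv * cos_t
            gx = _bilinear(plane, sy, sx + 1) - _bilinear(plane, sy, sx - 1)
            gy = _bilinear(plane, sy + 1, sx) - _bilinear(plane, sy - 1, sx)
            mag = math.hypot(gx, gy)
            ang = (math.atan2(gy, gx) - kp.orientation) % (2.0 * math.pi)
            b = int(ang / (2.0 * math.pi) * 8) % 8
            desc[v // 4, u // 4, b] += mag
    vec = desc.ravel()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return vec


def _bilinear(plane: np.ndarray, y: float, x: float) -> float:
    y0, x0 = int(math.floor(y)), int(math.floor(x))
    fy, fx = y - y0, x - x0
    y1, x1 = min(y0 + 1, plane.shape[0] - 1), min(x0 + 1, plane.shape[1] - 1)
    y0, x0 = max(y0, 0), max(x0, 0)
    return float(
        plane[y0, x0] * (1 - fy) * (1 - fx)
        + plane[y0, x1] * (1 - fy) * fx
        + plane[y1, x0] * fy * (1 - fx)
        + plane[y1, x1] * fy * fx
    )


def detect_keypoints(
    img: np.ndarray,
    params: SiftParams | None = None,
    descriptors: bool = True,
) -> list[KeyPoint]:
    """Full detector: scale space -> extrema -> localization -> orientation.

    *img* is a 2-D grayscale array (uint8 or [0,1] float).  Descriptor
    computation can be skipped for speed when only positions are needed.
    """
    params = params or SiftParams()
    ss = build_scale_space(img, params)
    keypoints: list[KeyPoint] = []
    for cand in detect_extrema(ss):
        kp = localize_and_filter(cand, ss, params)
        if kp is None:
            continue
        for oriented in assign_orientation(kp, ss, params):
            if descriptors:
                vec = compute_descriptor(oriented, ss)
                if vec is None:
                    continue
                oriented.descriptor = vec
            keypoints.append(oriented)
    return keypoints


def dump_keypoints_csv(kps: list[KeyPoint], path: str | Path) -> None:
    """Debug dump: x, y, sigma, orientation, response per key point."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "sigma", "orientation", "response"])
        for kp in kps:
            writer.writerow([f"{kp.x:.3f}", f"{kp.y:.3f}", f"{kp.sigma:.4f}",
                             f"{kp.orientation:.4f}", f"{kp.response:.6f}"])
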