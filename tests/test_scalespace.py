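import math

import numpy as np
import pytest

from dermoscan.scalespace import (KeyPoint, ScaleSpace, SiftParams,
                                  assign_orientation, build_scale_space,
                                  compute_descriptor, convolve,
                                  detect_extrema, detect_keypoints,
                                  gaussian_kernel, gradient_field,
                                  localize_and_filter)
from conftest import gaussian_blob_image


def brute_force_convolve(img, kernel):
    """Direct quadruple-loop convolution with edge replication."""
    h, w = img.shape
    kh, kw = kernel.shape
    ry, rx = kh // 2, kw // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    # scipy convolve flips the kernel; mirror that here
                    yy = min(max(i - (a - ry), 0), h - 1)
                    xx = min(max(j - (b - rx), 0), w - 1)
                    acc += kernel[a, b] * img[yy, xx]
            out[i, j] = acc
    return out


def brute_force_extrema(dogs):
    """Exhaustive 26-neighbourhood scan of one octave's DoG cube."""
    found = []
    n, h, w = dogs.shape
    for l in range(1, n - 1):
        for y in range(1, h - 1):
            for x in range(1, w - 1):
                cube = dogs[l - 1:l + 2, y - 1:y + 2, x - 1:x + 2]
                centre = dogs[l, y, x]
                others = np.delete(cube.ravel(), 13)
                if (centre > others).all() or (centre < others).all():
                    found.append((l, y, x))
    return found


class TestGaussianKernel:
    def test_symmetry_and_normalization(self):
        k = gaussian_kernel(1.7, radius=4)
        assert k.shape == (9, 9)
        assert math.isclose(k.sum(), 1.0, abs_tol=1e-12)
        assert np.allclose(k, k.T)
        assert np.allclose(k, np.rot90(k))
        assert np.allclose(k, k[::-1, :])

    def test_unnormalized_center_value(self):
        # G(0,0) = 1/(2 pi sigma^2) = 1/(2 pi) for sigma = 1
        sigma, radius = 1.0, 5
        ax = np.arange(-radius, radius + 1, dtype=float)
        xx, yy = np.meshgrid(ax, ax)
        raw = np.exp(-(xx ** 2 + yy ** 2) / 2) / (2 * math.pi)
        assert math.isclose(raw[radius, radius], 1 / (2 * math.pi), rel_tol=1e-12)
        # and the normalized kernel is proportional to the raw sampling
        k = gaussian_kernel(sigma, radius)
        assert np.allclose(k, raw / raw.sum())

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.0)


class TestConvolve:
    def test_identity_kernel(self, rng):
        img = rng.random((6, 7))
        assert np.allclose(convolve(img, np.array([[1.0]])), img)

    def test_normalized_kernel_on_constant_image(self):
        blur = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=float) / 16
        img = np.full((5, 5), 3.25)
        assert np.allclose(convolve(img, blur), 3.25)

    def test_matches_brute_force_oracle(self, rng):
        img = rng.random((5, 5))
        kernel = rng.random((3, 3))
        assert np.allclose(convolve(img, kernel), brute_force_convolve(img, kernel))

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            convolve(rng.random((5, 5)), rng.random((2, 2)))


class TestScaleSpace:
    def test_constant_image_gives_zero_dogs(self):
        img = np.full((64, 64), 0.5)
        ss = build_scale_space(img, SiftParams(octaves=2))
        for dog in ss.dogs:
            assert np.allclose(dog, 0.0)

    def test_dog_definitional_identity(self, rng):
        img = rng.random((64, 64))
        ss = build_scale_space(img, SiftParams(octaves=2))
        for o in range(len(ss.dogs)):
            assert np.allclose(ss.dogs[o] + ss.gaussians[o][:-1], ss.gaussians[o][1:])

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_scale_space(np.zeros((12, 12)), SiftParams())

    def test_blob_response_decays_past_matched_scale(self):
        """A blob's DoG magnitude peaks near its size then decays."""
        img = gaussian_blob_image(n=96, sigma=3.0)
        ss = build_scale_space(img, SiftParams(octaves=3))
        c = 48
        profile = []  # (sigma, |D|) over the whole stack
        for o, dog in enumerate(ss.dogs):
            cc = c // 2 ** o
            profile.extend((ss.sigma_at(o, l), abs(dog[l, cc, cc]))
                           for l in range(dog.shape[0]))
        profile.sort()
        values = [v for _, v in profile]
        peak = int(np.argmax(values))
        tail = values[peak:]
        # octave seams re-sample the same sigma; allow resampling jitter
        assert all(a >= b - 5e-3 for a, b in zip(tail, tail[1:]))
        assert tail[-1] < 0.25 * values[peak]


class TestDetectExtrema:
    def test_flat_image_has_no_extrema(self):
        ss = build_scale_space(np.full((64, 64), 0.4), SiftParams(octaves=1))
        assert detect_extrema(ss) == []

    def test_blob_candidate_at_blob_position(self):
        img = gaussian_blob_image(n=64, sigma=3.0)
        ss = build_scale_space(img, SiftParams(octaves=2))
        cands = detect_extrema(ss)
        assert any(abs(x * 2 ** o - 32) <= 2 and abs(y * 2 ** o - 32) <= 2
                   for o, l, y, x in cands)

    def test_equals_exhaustive_enumeration(self, rng):
        """26-neighbour rule must agree with brute force on small stacks."""
        params = SiftParams(octaves=1)
        for trial in range(4):
            img = np.random.default_rng(trial).random((32, 32))
            ss = build_scale_space(img, params)
            got = sorted((l, y, x) for o, l, y, x in detect_extrema(ss))
            assert got == sorted(brute_force_extrema(ss.dogs[0]))

    def test_agreement_on_single_bright_pixel_stack(self):
        """An isolated pixel's scale is below the sampled range: both the
        detector and the exhaustive scan agree on what the 26-neighbour
        rule yields there."""
        img = np.zeros((64, 64), dtype=np.uint8)
        img[32, 32] = 255
        ss = build_scale_space(img, SiftParams(octaves=1))
        got = sorted((l, y, x) for o, l, y, x in detect_extrema(ss))
        assert got == sorted(brute_force_extrema(ss.dogs[0]))


class TestLocalizeAndFilter:
    def test_step_edge_candidates_all_rejected(self, step_edge):
        """Edge responses fail the principal-curvature ratio test."""
        ss = build_scale_space(step_edge, SiftParams(octaves=2))
        for cand in detect_extrema(ss):
            assert localize_and_filter(cand, ss) is None

    def test_blob_center_survives_with_small_ratio(self):
        img = gaussian_blob_image(n=64, sigma=3.0)
        params = SiftParams(octaves=2)
        ss = build_scale_space(img, params)
        kept = [localize_and_filter(c, ss, params) for c in detect_extrema(ss)]
        kept = [k for k in kept if k is not None]
        assert any(abs(k.x - 32) <= 2 and abs(k.y - 32) <= 2 for k in kept)

    def test_flat_saddle_rejected_by_contrast(self):
        """A candidate whose interpolated |D| is ~0 is always rejected."""
        params = SiftParams(octaves=1)
        ss = build_scale_space(np.full((64, 64), 0.5), params)
        # hand-build a degenerate candidate on the zero stack
        assert localize_and_filter((0, 1, 10, 10), ss, params) is None


class TestGradientsAndOrientation:
    def test_horizontal_ramp(self):
        n = 16
        plane = np.tile(np.arange(n, dtype=float), (n, 1))
        m, phi = gradient_field(plane)
        assert np.allclose(m[1:-1, 1:-1], 2.0)
        assert np.allclose(phi[1:-1, 1:-1], 0.0)

    def test_vertical_ramp(self):
        n = 16
        plane = np.tile(np.arange(n, dtype=float)[:, None], (1, n))
        m, phi = gradient_field(plane)
        assert np.allclose(m[1:-1, 1:-1], 2.0)
        assert np.allclose(phi[1:-1, 1:-1], math.pi / 2)

    def test_orientations_shift_by_quarter_turn_under_rotation(self, blob_fixture):
        img = blob_fixture
        n = img.shape[0]
        rot = np.rot90(img, k=-1).copy()
        kps = detect_keypoints(img, descriptors=False)
        kps_r = detect_keypoints(rot, descriptors=False)
        assert kps and kps_r
        binw = 2 * math.pi / 36
        matched = checked = 0
        for kp in kps:
            xr, yr = (n - 1) - kp.y, kp.x
            close = [k for k in kps_r if abs(k.x - xr) < 3 and abs(k.y - yr) < 3]
            if not close:
                continue
            checked += 1
            err = min(abs((((k.orientation - kp.orientation) - math.pi / 2) + math.pi)
                          % (2 * math.pi) - math.pi) for k in close)
            matched += err <= binw + 1e-9
        assert checked > 0 and matched == checked

    def test_keypoint_count_stable_under_quarter_rotations(self, blob_fixture):
        counts = []
        for k in range(4):
            img = np.rot90(blob_fixture, k=k).copy()
            pos = {(round(p.x), round(p.y)) for p in detect_keypoints(img, descriptors=False)}
            counts.append(len(pos))
        assert max(counts) <= math.ceil(min(counts) * 1.1)


class TestDescriptor:
    def test_constant_patch_gives_zero_vector(self):
        ss = build_scale_space(np.full((64, 64), 0.5), SiftParams(octaves=1))
        kp = KeyPoint(x=32, y=32, sigma=1.6, orientation=0.3, octave=0, level=1)
        vec = compute_descriptor(kp, ss)
        assert vec is not None and vec.shape == (128,) and np.allclose(vec, 0.0)

    def test_unit_norm_on_structured_patch(self, blob_fixture):
        kps = detect_keypoints(blob_fixture)
        assert kps
        for kp in kps:
            assert kp.descriptor.shape == (128,)
            assert math.isclose(np.linalg.norm(kp.descriptor), 1.0, abs_tol=1e-9)

    def test_rotation_invariance_of_descriptor(self, blob_fixture):
        n = blob_fixture.shape[0]
        kps = detect_keypoints(blob_fixture)
        kps_r = detect_keypoints(np.rot90(blob_fixture, k=-1).copy())
        pairs = 0
        for kp in kps:
            xr, yr = (n - 1) - kp.y, kp.x
            close = [k for k in kps_r if abs(k.x - xr) < 3 and abs(k.y - yr) < 3]
            if close:
                pairs += 1
                assert min(np.linalg.norm(kp.descriptor - k.descriptor)
                           for k in close) < 0.2
        assert pairs > 0


class TestDetectorProperties:
    def test_no_keypoints_on_flat_image(self):
        assert detect_keypoints(np.full((128, 128), 128, dtype=np.uint8)) == []

    def test_no_keypoints_on_step_edge(self, step_edge):
        assert detect_keypoints(step_edge, descriptors=False) == []

    def test_intensity_doubling_keeps_positions(self, blob_fixture):
        half = (blob_fixture.astype(float) / 2).astype(np.uint8)
        dbl = (half.astype(int) * 2).astype(np.uint8)
        p1 = {(round(k.x), round(k.y)) for k in detect_keypoints(half, descriptors=False)}
        p2 = {(round(k.x), round(k.y)) for k in detect_keypoints(dbl, descriptors=False)}
        assert p1 and p1 == p2
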