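import math

import numpy as np
import pytest

from dermoscan import cnn
from dermoscan.clusterer import Cluster
from dermoscan.cnn import (BLUR_KERNEL, EMBOSS_KERNEL, CnnClassifier, CnnModel,
                           ConvLayer, DenseLayer, PoolLayer, TrainingConfig,
                           backprop_step, build_default_model, conv_forward,
                           dense_forward, pool_forward, predict, train)


def brute_force_conv(plane, kernel, stride=1):
    """Direct quadruple-loop valid correlation (single plane, 2-D kernel)."""
    h, w = plane.shape
    m = kernel.shape[0]
    oh, ow = (h - m) // stride + 1, (w - m) // stride + 1
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            acc = 0.0
            for a in range(m):
                for b in range(m):
                    acc += kernel[a, b] * plane[i * stride + a, j * stride + b]
            out[i, j] = acc
    return out


def gradient_check(model, x, y, eps=1e-5):
    """Max relative error between analytic and central-difference grads."""
    cfg = TrainingConfig(learning_rate=0.0)

    def loss_of():
        out = model.forward(x, train=False)
        t = cnn._targets_for(y, out.shape[1], cfg.target)
        return float(np.mean((out - t) ** 2))

    out = model.forward(x, train=True)
    t = cnn._targets_for(y, out.shape[1], cfg.target)
    _, grad = cnn._loss_and_grad(out, t)
    analytic = {}
    g = grad
    for li, layer in reversed(list(enumerate(model.layers))):
        g, dw = layer.backward(g)
        if dw is not None:
            analytic[li] = dw
    worst = 0.0
    for li, layer in enumerate(model.layers):
        if not getattr(layer, "trainable", False):
            continue
        W = layer.weights
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = W[idx]
            W[idx] = orig + eps
            lp = loss_of()
            W[idx] = orig - eps
            lm = loss_of()
            W[idx] = orig
            fd = (lp - lm) / (2 * eps)
            a = analytic[li][idx]
            worst = max(worst, abs(fd - a) / max(abs(fd) + abs(a), 1e-8))
    return worst


class TestNamedKernels:
    def test_blur_kernel_exact_values(self):
        assert np.array_equal(BLUR_KERNEL * 16,
                              np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]]))

    def test_emboss_kernel_sums_to_one(self):
        assert np.array_equal(EMBOSS_KERNEL,
                              np.array([[-2, -1, 0], [-1, 1, 1], [0, 1, 2]]))
        assert EMBOSS_KERNEL.sum() == 1.0

    def test_emboss_on_constant_plane_is_identity(self):
        plane = np.full((7, 7), 4.5)
        out = conv_forward(plane, EMBOSS_KERNEL)
        assert np.allclose(out[..., 0], 4.5)


class TestConvForward:
    def test_matches_brute_force_exhaustively(self):
        """Oracle equivalence on every plane size up to 8x8."""
        rng = np.random.default_rng(0)
        for n in range(3, 9):
            plane = rng.random((n, n))
            kernel = rng.random((3, 3))
            out = conv_forward(plane, kernel)
            assert np.allclose(out[..., 0], brute_force_conv(plane, kernel))

    def test_stride_two_matches_oracle(self):
        rng = np.random.default_rng(1)
        plane = rng.random((8, 8))
        kernel = rng.random((3, 3))
        out = conv_forward(plane, kernel, stride=2)
        assert np.allclose(out[..., 0], brute_force_conv(plane, kernel, stride=2))

    def test_output_side_formula(self):
        # floor((N - m)/S) + 1 with N=10, m=3, S=2 -> 4
        layer = ConvLayer(4, 3, 2)
        assert layer.out_shape((10, 10, 1)) == (4, 4, 4)

    def test_kernel_larger_than_plane_rejected(self):
        with pytest.raises(ValueError):
            conv_forward(np.zeros((2, 2)), np.ones((3, 3)))


class TestPoolForward:
    def test_nine_to_three(self, rng):
        out = pool_forward(rng.random((9, 9)))
        assert out.shape == (3, 3, 1)

    def test_tile_of_one_to_nine_gives_nine(self):
        tile = np.arange(1, 10, dtype=float).reshape(3, 3)
        assert pool_forward(tile)[0, 0, 0] == 9.0

    def test_weighted_degenerate_mu_reads_red_channel(self, rng):
        tile = rng.random((3, 3, 3))
        out = pool_forward(tile, mode="weighted_color_max", mu=(1.0, 0.0, 0.0))
        assert out[0, 0, 0] == pytest.approx(tile[..., 0].max())

    def test_bad_mu_rejected(self):
        with pytest.raises(ValueError):
            PoolLayer(mode="weighted_color_max", mu=(0.5, 0.2, 0.2))

    def test_pad_by_replication_gives_ceil_size(self, rng):
        out = pool_forward(rng.random((10, 11)))
        assert out.shape == (4, 4, 1)


class TestDenseForward:
    def test_zero_weights_give_zero_outputs(self):
        layer = DenseLayer(3, weights=np.zeros((5, 3)))
        assert np.array_equal(dense_forward(np.ones(5), layer), np.zeros(3))

    def test_single_unit_tanh_value(self):
        layer = DenseLayer(1, weights=np.ones((2, 1)))
        out = dense_forward(np.array([0.5, 0.5]), layer)
        assert out[0] == pytest.approx(math.tanh(1.0))

    def test_outputs_strictly_inside_unit_interval(self, rng):
        layer = DenseLayer(4, weights=rng.normal(0, 0.5, size=(10, 4)))
        out = dense_forward(rng.normal(0, 1, size=10), layer)
        assert (np.abs(out) < 1).all()

    def test_size_mismatch_rejected(self):
        layer = DenseLayer(2, weights=np.zeros((4, 2)))
        with pytest.raises(ValueError):
            dense_forward(np.ones(5), layer)


class TestBackprop:
    def test_zero_learning_rate_keeps_weights_bit_identical(self, rng):
        model = build_default_model((12, 12, 2), (2,), (3,))
        model.init_weights(rng)
        before = [l.weights.copy() for l in model.layers
                  if getattr(l, "trainable", False)]
        x = rng.random((4, 12, 12, 2))
        backprop_step(model, x, np.array([0, 1, 0, 1]), TrainingConfig(learning_rate=0.0))
        after = [l.weights for l in model.layers if getattr(l, "trainable", False)]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_analytic_gradients_match_finite_differences(self, rng):
        """Chain-rule gradients vs central differences on a model with two
        conv layers, pooling with edge padding, and two dense layers."""
        model = build_default_model((14, 14, 3), (2, 3), (4,))
        model.init_weights(rng)
        x = rng.random((2, 14, 14, 3))
        assert gradient_check(model, x, np.array([1, 0])) < 1e-4

    def test_gradients_with_weighted_pooling(self, rng):
        model = build_default_model((15, 15, 3), (2,), (3,),
                                    pool_mode="weighted_color_max", mu=(0.5, 0.3, 0.2))
        model.init_weights(rng)
        x = rng.random((2, 15, 15, 3))
        assert gradient_check(model, x, np.array([0, 1])) < 1e-4

    def test_repeated_steps_descend(self, rng):
        model = build_default_model((12, 12, 1), (2,), (4,))
        model.init_weights(rng)
        x = rng.random((1, 12, 12, 1))
        y = np.array([1])
        cfg = TrainingConfig(learning_rate=0.05)
        losses = [backprop_step(model, x, y, cfg) for _ in range(50)]
        assert all(a >= b - 1e-12 for a, b in zip(losses[10:], losses[11:]))

    def test_pooling_layers_have_no_trainable_weights(self):
        model = build_default_model()
        pools = [l for l in model.layers if isinstance(l, PoolLayer)]
        assert pools and all(not p.trainable for p in pools)


def disk_dataset(n_per_class=100, dim=24, seed=0):
    """Linearly separable toy set: dark disks vs plain skin tone."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            img = np.full((dim, dim), 0.7) + rng.normal(0, 0.02, (dim, dim))
            if label == 1:
                yy, xx = np.mgrid[0:dim, 0:dim]
                r = rng.uniform(4, 7)
                cy, cx = dim / 2 + rng.uniform(-2, 2), dim / 2 + rng.uniform(-2, 2)
                img[(yy - cy) ** 2 + (xx - cx) ** 2 < r ** 2] = 0.25
            xs.append(np.clip(img, 0, 1)[..., None])
            ys.append(label)
    return np.stack(xs), np.array(ys)


class TestTrain:
    def test_same_seed_reproduces_weights_bit_exactly(self):
        x, y = disk_dataset(10, seed=3)
        runs = []
        for _ in range(2):
            model = build_default_model((24, 24, 1), (2,), (4,))
            hist = train(model, x, y, TrainingConfig(epochs=3, seed=9))
            runs.append((hist, [l.weights.copy() for l in model.layers
                                if getattr(l, "trainable", False)]))
        assert runs[0][0] == runs[1][0]
        assert all(np.array_equal(a, b) for a, b in zip(runs[0][1], runs[1][1]))

    def test_separable_disks_reach_095_training_accuracy(self):
        """Dark disks vs plain skin (n=200) within 30 epochs."""
        x, y = disk_dataset(100, seed=0)
        model = build_default_model((24, 24, 1), (4,), (8,))
        train(model, x, y, TrainingConfig(epochs=30, seed=0))
        out = model.forward(x)
        preds = (out[:, 1] > out[:, 0]).astype(int)
        assert (preds == y).mean() >= 0.95

    def test_single_class_data_rejected(self, rng):
        model = build_default_model((12, 12, 1), (2,), (3,))
        with pytest.raises(ValueError):
            train(model, rng.random((4, 12, 12, 1)), np.zeros(4, dtype=int))

    def test_loss_history_finite(self):
        x, y = disk_dataset(8, seed=1)
        model = build_default_model((24, 24, 1), (2,), (3,))
        hist = train(model, x, y, TrainingConfig(epochs=5, seed=1))
        assert len(hist) == 5 and np.isfinite(hist).all()


class TestPredict:
    def _blurred(self, img):
        return Cluster(image=img, source_keypoint=None, region_size=10,
                       state="blurred")

    def test_untrained_model_rejected(self, rng):
        model = build_default_model((8, 8, 1), (2,), (2,))
        model.init_weights(rng)
        with pytest.raises(RuntimeError):
            predict(model, self._blurred(np.zeros((8, 8, 1), dtype=np.uint8)))

    def test_unblurred_cluster_rejected(self):
        x, y = disk_dataset(4, dim=8, seed=0)
        model = build_default_model((8, 8, 1), (2,), (2,))
        train(model, x, y, TrainingConfig(epochs=1, seed=0))
        c = Cluster(image=np.zeros((8, 8, 1), dtype=np.uint8),
                    source_keypoint=None, region_size=1, state="raw")
        with pytest.raises(ValueError):
            predict(model, c)

    def test_score_in_unit_interval_and_probabilities_sum_to_one(self):
        x, y = disk_dataset(6, dim=8, seed=2)
        model = build_default_model((8, 8, 1), (2,), (2,))
        train(model, x, y, TrainingConfig(epochs=2, seed=2))
        label, score = predict(model, self._blurred((x[0] * 255).astype(np.uint8)))
        assert label in ("benign", "suspicious")
        assert 0.0 <= score <= 1.0

    def test_symmetric_outputs_tie_to_benign(self):
        """Identical output weights give score 0.5, resolved as benign."""
        layer = DenseLayer(2, weights=np.ones((4, 2)))
        model = CnnModel([cnn.FlattenLayer(), DenseLayer(4), layer], (2, 2, 1))
        model.layers[1].weights = np.full((4, 4), 0.1)
        model.trained = True
        label, score = predict(model, self._blurred(np.full((2, 2, 1), 100, dtype=np.uint8)))
        assert score == pytest.approx(0.5)
        assert label == "benign"


class TestSerialization:
    def test_save_load_predict_bit_identical(self, tmp_path, rng):
        x, y = disk_dataset(6, dim=12, seed=4)
        model = build_default_model((12, 12, 1), (2,), (3,))
        train(model, x, y, TrainingConfig(epochs=2, seed=4))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = CnnModel.from_json(path)
        assert loaded.trained
        assert np.array_equal(model.forward(x), loaded.forward(x))


class TestCnnClassifier:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        x, y = disk_dataset(20, dim=16, seed=5)
        clf = CnnClassifier(conv_filters=(4,), dense_units=(8,), epochs=40,
                            random_state=5)
        clone(clf)  # get_params/set_params round-trip
        clf.fit(x, y)
        assert list(clf.classes_) == [0, 1]
        probs = clf.predict_proba(x)
        assert probs.shape == (len(x), 2)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert clf.score(x, y) >= 0.9

    def test_multiclass_rejected(self, rng):
        clf = CnnClassifier(epochs=1)
        with pytest.raises(ValueError):
            clf.fit(rng.random((6, 8, 8, 1)), np.array([0, 1, 2, 0, 1, 2]))
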