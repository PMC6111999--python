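"""From-scratch convolutional neural network for cluster classification.

The network is a stack of three layer types:

* convolutional — a bank of odd-sized kernels slid over the input planes
  with stride S, valid region only (output side = floor((N - m)/S) + 1).
  Layers are linear; the named 3x3 kernels (Gaussian blur, emboss) are
  available both as fixed filters and as weight initializations.
* pooling — each non-overlapping 3x3 tile collapses to one value: the
  plain maximum, or for RGB stacks the weighted color maximum
  mu1*max R + mu2*max G + mu3*max B with mu summing to 1.  Pooling holds
  no trainable weights; gradients are routed to the argmax positions.
* fully connected — y_k = tanh(sum_j w_jk x_j), outputs in (-1, 1).

Training is plain gradient descent on a mean-squared error over the two
tanh outputs (targets +/-0.9), with gradients computed layer by layer via
the chain rule.  Everything is seeded and bit-reproducible.

``CnnClassifier`` exposes the network as a scikit-learn estimator
(fit/predict/predict_proba); the module-level ``train``/``predict``
functions are thin wrappers over it for pipeline use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .clusterer import Cluster

__all__ = [
    "BLUR_KERNEL",
    "EMBOSS_KERNEL",
    "ConvLayer",
    "PoolLayer",
    "DenseLayer",
    "FlattenLayer",
    "CnnModel",
    "TrainingConfig",
    "TrainingDiverged",
    "build_default_model",
    "conv_forward",
    "pool_forward",
    "dense_forward",
    "backprop_step",
    "train",
    "predict",
    "CnnClassifier",
]

# Gaussian blur: (1/16) [1 2 1; 2 4 2; 1 2 1]
BLUR_KERNEL = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=float) / 16.0
# Emboss: entries sum to 1, so constant planes pass through unchanged
EMBOSS_KERNEL = np.array([[-2, -1, 0], [-1, 1, 1], [0, 1, 2]], dtype=float)


class TrainingDiverged(RuntimeError):
    """Raised when the batch loss becomes non-finite."""


class ConvLayer:
    """Valid-region convolution bank; weights shape (filters, m, m, c_in)."""

    trainable = True

    def __init__(self, n_filters: int, kernel_size: int = 3, stride: int = 1,
                 weights: np.ndarray | None = None):
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("kernel size must be odd and positive")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.stride = stride
        self.weights = weights  # set by init_weights once c_in is known
        self._x_windows: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def init_weights(self, c_in: int, rng: np.random.Generator) -> None:
        m = self.kernel_size
        self.weights = rng.uniform(-0.1, 0.1, size=(self.n_filters, m, m, c_in))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        m, s = self.kernel_size, self.stride
        if x.shape[1] < m or x.shape[2] < m:
            raise ValueError("kernel larger than input plane")
        if self.weights is None:
            raise RuntimeError("conv layer weights not initialized")
        win = sliding_window_view(x, (m, m), axis=(1, 2))[:, ::s, ::s]
        out = np.einsum("bijcuv,fuvc->bijf", win, self.weights, optimize=True)
        if train:
            self._x_windows = win
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (dx, dweights)."""
        m, s = self.kernel_size, self.stride
        win = self._x_windows
        dw = np.einsum("bijcuv,bijf->fuvc", win, dout, optimize=True)
        # transpose convolution: dilate dout by the stride, zero-pad by
        # m-1, correlate with the flipped kernels
        b, oh, ow, f = dout.shape
        dh, dw_ = (oh - 1) * s + 1, (ow - 1) * s + 1
        dil = np.zeros((b, dh, dw_, f))
        dil[:, ::s, ::s] = dout
        pad = np.pad(dil, ((0, 0), (m - 1, m - 1), (m - 1, m - 1), (0, 0)))
        win2 = sliding_window_view(pad, (m, m), axis=(1, 2))
        wflip = self.weights[:, ::-1, ::-1, :]
        dx_core = np.einsum("bijfuv,fuvc->bijc", win2, wflip, optimize=True)
        _, h, w, c = self._in_shape
        dx = np.zeros(self._in_shape)
        dx[:, : dx_core.shape[1], : dx_core.shape[2]] = dx_core
        return dx, dw

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        h, w, _ = in_shape
        m, s = self.kernel_size, self.stride
        return ((h - m) // s + 1, (w - m) // s + 1, self.n_filters)

    def spec(self) -> dict:
        return {"type": "conv", "n_filters": self.n_filters,
                "kernel_size": self.kernel_size, "stride": self.stride}


class PoolLayer:
    """Fixed 3x3 pooling: plain max or weighted color max. No weights."""

    trainable = False
    WINDOW = 3

    def __init__(self, mode: str = "plain_max",
                 mu: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)):
        if mode not in ("plain_max", "weighted_color_max"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        if mode == "weighted_color_max" and not math.isclose(sum(mu), 1.0, abs_tol=1e-9):
            raise ValueError("mu weights must sum to 1 in weighted mode")
        self.mode = mode
        self.mu = tuple(float(v) for v in mu)
        self._cache: tuple | None = None

    @staticmethod
    def _tile(x: np.ndarray) -> tuple[np.ndarray, int, int, tuple[int, int]]:
        b, h, w, c = x.shape
        ph, pw = (-h) % 3, (-w) % 3
        xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="edge")
        ho, wo = xp.shape[1] // 3, xp.shape[2] // 3
        tiles = (xp.reshape(b, ho, 3, wo, 3, c)
                 .transpose(0, 1, 3, 5, 2, 4)
                 .reshape(b, ho, wo, c, 9))
        return tiles, ho, wo, (ph, pw)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        tiles, ho, wo, pad = self._tile(x)
        if self.mode == "weighted_color_max":
            if x.shape[3] != 3:
                raise ValueError("weighted_color_max needs exactly 3 input planes")
            arg = tiles.argmax(axis=-1)  # (b, ho, wo, 3)
            maxes = np.take_along_axis(tiles, arg[..., None], axis=-1)[..., 0]
            out = (maxes * np.asarray(self.mu)).sum(axis=-1, keepdims=True)
        else:
            arg = tiles.argmax(axis=-1)
            out = np.take_along_axis(tiles, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape, pad)
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, None]:
        arg, in_shape, (ph, pw) = self._cache
        b, h, w, c = in_shape
        ho, wo = arg.shape[1], arg.shape[2]
        g9 = np.zeros((b, ho, wo, c, 9))
        if self.mode == "weighted_color_max":
            routed = dout * np.asarray(self.mu)  # broadcast (b,ho,wo,1)->(b,ho,wo,3)
        else:
            routed = dout
        np.put_along_axis(g9, arg[..., None], routed[..., None], axis=-1)
        gpad = (g9.reshape(b, ho, wo, c, 3, 3)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(b, ho * 3, wo * 3, c))
        # fold gradients of the edge-replicated pad back onto the edge
        if ph:
            gpad[:, h - 1] += gpad[:, h:].sum(axis=1)
        if pw:
            gpad[:, :, w - 1] += gpad[:, :, w:].sum(axis=2)
        return gpad[:, :h, :w], None

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        h, w, c = in_shape
        c_out = 1 if self.mode == "weighted_color_max" else c
        return (math.ceil(h / 3), math.ceil(w / 3), c_out)

    def spec(self) -> dict:
        return {"type": "pool", "mode": self.mode, "mu": list(self.mu)}


class FlattenLayer:
    trainable = False

    def __init__(self) -> None:
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, None]:
        return dout.reshape(self._in_shape), None

    def spec(self) -> dict:
        return {"type": "flatten"}


class DenseLayer:
    """Fully connected tanh layer; weights shape (n_in, n_units), no bias."""

    trainable = True

    def __init__(self, n_units: int, weights: np.ndarray | None = None):
        self.n_units = n_units
        self.weights = weights
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def init_weights(self, n_in: int, rng: np.random.Generator) -> None:
        self.weights = rng.uniform(-0.1, 0.1, size=(n_in, self.n_units))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.weights is None:
            raise RuntimeError("dense layer weights not initialized")
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"dense input size {x.shape[1]} != weight rows {self.weights.shape[0]}")
        y = np.tanh(x @ self.weights)
        if train:
            self._x, self._y = x, y
        return y

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dz = dout * (1.0 - self._y ** 2)  # tanh' = 1 - tanh^2
        dw = self._x.T @ dz
        dx = dz @ self.weights.T
        return dx, dw

    def spec(self) -> dict:
        return {"type": "dense", "n_units": self.n_units}


@dataclass
class TrainingConfig:
    learning_rate: float = 0.05
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    target: float = 0.9  # tanh targets are +/- target

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class CnnModel:
    """Ordered layer stack with shape checking and JSON serialization."""

    def __init__(self, layers: list, input_dim: tuple[int, int, int]):
        self.layers = layers
        self.input_dim = tuple(input_dim)  # (h, w, channels)
        self.trained = False

    # -- construction ---------------------------------------------------
    def init_weights(self, rng: np.random.Generator) -> None:
        shape = self.input_dim
        for layer in self.layers:
            if isinstance(layer, ConvLayer):
                layer.init_weights(shape[2], rng)
                shape = layer.out_shape(shape)
            elif isinstance(layer, PoolLayer):
                shape = layer.out_shape(shape)
            elif isinstance(layer, FlattenLayer):
                shape = (shape[0] * shape[1] * shape[2],)
            elif isinstance(layer, DenseLayer):
                layer.init_weights(shape[0], rng)
                shape = (layer.n_units,)
        self.n_outputs = shape[0]
        self.trained = False

    # -- inference ------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def n_parameters(self) -> int:
        return sum(layer.weights.size for layer in self.layers
                   if getattr(layer, "trainable", False) and layer.weights is not None)

    # -- persistence ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "input_dim": list(self.input_dim),
            "trained": self.trained,
            "layers": [
                {**layer.spec(),
                 "weights": (layer.weights.tolist()
                             if getattr(layer, "trainable", False) and layer.weights is not None
                             else None)}
                for layer in self.layers
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CnnModel":
        payload = json.loads(Path(path).read_text())
        layers: list = []
        for spec in payload["layers"]:
            kind = spec["type"]
            if kind == "conv":
                layer = ConvLayer(spec["n_filters"], spec["kernel_size"], spec["stride"])
            elif kind == "pool":
                layer = PoolLayer(spec["mode"], tuple(spec["mu"]))
            elif kind == "flatten":
                layer = FlattenLayer()
            elif kind == "dense":
                layer = DenseLayer(spec["n_units"])
            else:
                raise ValueError(f"unknown layer type {kind!r}")
            if spec.get("weights") is not None:
                layer.weights = np.asarray(spec["weights"], dtype=float)
            layers.append(layer)
        model = cls(layers, tuple(payload["input_dim"]))
        model.trained = bool(payload["trained"])
        return model


def build_default_model(input_dim: tuple[int, int, int] = (64, 64, 3),
                        conv_filters: tuple[int, ...] = (8, 16),
                        dense_units: tuple[int, ...] = (32,),
                        pool_mode: str = "plain_max",
                        mu: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                        stride: int = 1) -> CnnModel:
    """conv->pool blocks followed by dense tanh layers and 2 outputs.

    ``weighted_color_max`` pooling needs exactly 3 input planes, so when
    selected it is applied once, directly on the RGB input, before the
    conv blocks; pools between conv blocks are always plain max.
    """
    layers: list = []
    if pool_mode == "weighted_color_max":
        if input_dim[2] != 3:
            raise ValueError("weighted_color_max needs RGB input")
        layers.append(PoolLayer("weighted_color_max", mu))
    for f in conv_filters:
        layers.append(ConvLayer(f, 3, stride))
        layers.append(PoolLayer("plain_max"))
    layers.append(FlattenLayer())
    for units in dense_units:
        layers.append(DenseLayer(units))
    layers.append(DenseLayer(2))
    return CnnModel(layers, input_dim)


# ---------------------------------------------------------------------------
# functional surface used by the pipeline and the tests
# ---------------------------------------------------------------------------

def conv_forward(planes: np.ndarray, filters: list[np.ndarray] | np.ndarray,
                 stride: int = 1) -> np.ndarray:
    """Apply a filter bank to a plane stack (h, w, c) -> (h', w', n_filters).

    Single-plane 2-D input is accepted; 2-D filters are applied to every
    input plane identically (summed over planes).
    """
    x = np.asarray(planes, dtype=float)
    if x.ndim == 2:
        x = x[..., None]
    filt = [np.asarray(f, dtype=float) for f in
            (filters if isinstance(filters, (list, tuple)) else [filters])]
    weights = np.stack([np.repeat(f[:, :, None], x.shape[2], axis=2) if f.ndim == 2 else f
                        for f in filt])
    layer = ConvLayer(weights.shape[0], weights.shape[1], stride, weights=weights)
    return layer.forward(x[None])[0]


def pool_forward(planes: np.ndarray, mode: str = "plain_max",
                 mu: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)) -> np.ndarray:
    """3x3 pooling of a plane stack (h, w, c)."""
    x = np.asarray(planes, dtype=float)
    if x.ndim == 2:
        x = x[..., None]
    return PoolLayer(mode, mu).forward(x[None])[0]


def dense_forward(x: np.ndarray, layer: DenseLayer) -> np.ndarray:
    """y_k = tanh(sum_j w_jk x_j) for a single input vector."""
    return layer.forward(np.asarray(x, dtype=float)[None])[0]


def _loss_and_grad(y: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    diff = y - targets
    loss = float(np.mean(diff ** 2))
    grad = 2.0 * diff / diff.size
    return loss, grad


def _targets_for(y_idx: np.ndarray, n_out: int, target: float) -> np.ndarray:
    t = -target * np.ones((len(y_idx), n_out))
    t[np.arange(len(y_idx)), y_idx] = target
    return t


def backprop_step(model: CnnModel, x: np.ndarray, y_idx: np.ndarray,
                  cfg: TrainingConfig) -> float:
    """One gradient-descent step on a batch; returns the batch loss.

    x: (batch, h, w, c) floats in [0, 1]; y_idx: integer class indices.
    Pooling/flatten layers route gradients but receive no update.
    """
    out = model.forward(x, train=True)
    targets = _targets_for(np.asarray(y_idx), out.shape[1], cfg.target)
    loss, grad = _loss_and_grad(out, targets)
    if not np.isfinite(loss):
        raise TrainingDiverged(f"non-finite loss {loss}")
    for layer in reversed(model.layers):
        grad, dw = layer.backward(grad)
        if dw is not None:
            layer.weights = layer.weights - cfg.learning_rate * dw
    return loss


def train(model: CnnModel, x: np.ndarray, y_idx: np.ndarray,
          cfg: TrainingConfig | None = None) -> list[float]:
    """Seeded training loop; returns the per-epoch mean loss history."""
    cfg = cfg or TrainingConfig()
    y_idx = np.asarray(y_idx)
    if len(np.unique(y_idx)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    model.init_weights(rng)
    n = len(x)
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            losses.append(backprop_step(model, x[sel], y_idx[sel], cfg))
        history.append(float(np.mean(losses)))
    model.trained = True
    return history


def predict(model: CnnModel, c: Cluster) -> tuple[str, float]:
    """Classify a blurred cluster; returns (label, suspicious probability).

    The two tanh outputs are mapped to [0, 1] via (y + 1)/2 and
    renormalized to sum 1; exact ties resolve to benign.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    if c.state != "blurred":
        raise ValueError("cluster must be screened and blurred before prediction")
    x = np.asarray(c.image, dtype=float)[None] / 255.0
    y = model.forward(x)[0]
    probs = (y + 1.0) / 2.0
    total = probs.sum()
    probs = probs / total if total > 0 else np.array([0.5, 0.5])
    label = "suspicious" if probs[1] > 0.5 else "benign"
    return label, float(probs[1])


class CnnClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator around the from-scratch CNN.

    Parameters mirror the default architecture: ``conv_filters`` filter
    counts per conv/pool block, ``dense_units`` hidden tanh layers, a
    final 2-unit output layer.  Input X is an (n, h, w, c) array of uint8
    images or floats in [0, 1]; y holds two class labels (the sorted
    first label plays the benign role).
    """

    def __init__(self, conv_filters: tuple[int, ...] = (8, 16),
                 dense_units: tuple[int, ...] = (32,),
                 pool_mode: str = "plain_max",
                 mu: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                 stride: int = 1,
                 learning_rate: float = 0.05,
                 epochs: int = 30,
                 batch_size: int = 16,
                 target: float = 0.9,
                 random_state: int = 0):
        self.conv_filters = conv_filters
        self.dense_units = dense_units
        self.pool_mode = pool_mode
        self.mu = mu
        self.stride = stride
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.target = target
        self.random_state = random_state

    def _prepare(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        if x.max() > 1.0:
            x = x / 255.0
        return x

    def fit(self, X, y):
        x = self._prepare(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("CnnClassifier is a binary classifier")
        y_idx = np.searchsorted(self.classes_, y)
        self.model_ = build_default_model(
            input_dim=x.shape[1:], conv_filters=tuple(self.conv_filters),
            dense_units=tuple(self.dense_units), pool_mode=self.pool_mode,
            mu=tuple(self.mu), stride=self.stride)
        cfg = TrainingConfig(learning_rate=self.learning_rate, epochs=self.epochs,
                             batch_size=self.batch_size, seed=self.random_state,
                             target=self.target)
        self.loss_history_ = train(self.model_, x, y_idx, cfg)
        self.n_features_in_ = int(np.prod(x.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        x = self._prepare(X)
        y = self.model_.forward(x)
        probs = (y + 1.0) / 2.0
        totals = probs.sum(axis=1, keepdims=True)
        safe = np.where(totals > 0, totals, 1.0)
        probs = np.where(totals > 0, probs / safe, 0.5)
        return probs

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        # strict > keeps exact 0.5 ties on the first (benign) class
        return self.classes_[(probs[:, 1] > 0.5).astype(int)]
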