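"""Small convolutional networks for image classification and segmentation.

Two compact CNNs operate on single-channel ultrasound images:

* a 16-named-layer / 3-convolution classifier mapping a whole image to
  three class probabilities (normal / benign / malignant), and
* an 11-named-layer / 3-convolution segmenter that labels every pixel,
  producing a tumor-probability map on the input grid.

Layer counting follows the convention in which every named layer — input,
convolution, batch-norm, activation, pooling, fully-connected, softmax and
the output layer — counts toward the total; the layer lists are overridable
through :class:`NetConfig`.

The numerics are implemented directly in numpy (im2col convolution,
batch normalization, 2x2 max pooling, nearest-neighbor upsampling, dense
layers, softmax cross-entropy, Adam) with manual backpropagation and seeded
initialization, so training is deterministic on a single CPU.  Loss is
cross-entropy for both tasks, with optional class weighting for the
segmenter's rare tumor pixels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# layers


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base layer: forward/backward over (B, C, H, W) activations."""

    name = "layer"
    is_marker = False  # marker layers count toward the named total but do no math

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats) that a
        checkpoint must capture alongside the weights."""
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Input(Layer):
    name = "input"
    is_marker = True


class Softmax(Layer):
    """Marker for the class-probability head; applied outside the loss path."""

    name = "softmax"
    is_marker = True


class ClassOutput(Layer):
    name = "classoutput"
    is_marker = True


class PixelSoftmax(Layer):
    name = "pixelsoftmax"
    is_marker = True


class PixelOutput(Layer):
    name = "pixeloutput"
    is_marker = True


class Conv2D(Layer):
    """3x3 (by default) same-padding convolution via im2col."""

    name = "conv"

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)))
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # B,C,H,W,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * self.k * self.k)
        out = cols @ self.w.value.T + self.b.value
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._x_shape
        k, p = self.k, self.k // 2
        g2 = grad.transpose(0, 2, 3, 1).reshape(B * H * W, self.c_out)
        self.w.grad = g2.T @ self._cols
        self.b.grad = g2.sum(axis=0)
        dcols = (g2 @ self.w.value).reshape(B, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, :, p:p + H, p:p + W]


class BatchNorm2D(Layer):
    name = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad = (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (g - gsum / n - xhat * gx / n)


class ReLU(Layer):
    name = "relu"

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2, stride-2 max pooling; ties break to the first maximum."""

    name = "maxpool"

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(B, C, H // 2, W // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        flat = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        out = flat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = self._shape = None
        return out.reshape(B, C, H, W)


class Upsample2(Layer):
    """Nearest-neighbor 2x upsampling (the decoder step of the segmenter)."""

    name = "upsample"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H2, W2 = grad.shape
        return grad.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))


class Dense(Layer):
    """Fully connected layer; flattens its input like a MATLAB fc layer."""

    name = "fullyconnected"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in)))
        self.b = Param(np.zeros(n_out))
        self._x = None
        self._in_shape = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        flat = x.reshape(x.shape[0], -1)
        if train:
            self._x, self._in_shape = flat, x.shape
        return flat @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad = grad.T @ self._x
        self.b.grad = grad.sum(axis=0)
        out = (grad @ self.w.value).reshape(self._in_shape)
        self._x = self._in_shape = None
        return out


# ---------------------------------------------------------------------------
# network / config


@dataclasses.dataclass
class NetConfig:
    """Architecture and training hyperparameters for both networks.

    ``iterations`` are optimizer steps; the reference runs used 3000
    (classifier) and 5000 (segmenter) on the full dataset, and desk-scale
    callers pass much smaller budgets.  ``class_weight`` (segmenter only)
    weights the rare tumor class in the pixel cross-entropy; ``None`` means
    inverse-frequency weights estimated from the training masks.
    """

    task: str = "classify"
    image_size: tuple[int, int] = (256, 256)
    n_classes: int = 3
    conv_channels: tuple[int, ...] = (8, 16, 32)
    iterations: int = 3000
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    val_interval: int | None = None  # default: iterations // 10
    class_weight: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.task not in ("classify", "segment"):
            raise ValueError("task must be 'classify' or 'segment'")
        if self.task == "segment" and self.n_classes == 3:
            self.n_classes = 2
        h, w = self.image_size
        depth = 3 if self.task == "classify" else 1
        if h % (2 ** depth) or w % (2 ** depth):
            raise ValueError(f"image_size {self.image_size} must be divisible by {2 ** depth}")
        n_conv = 3 if self.task == "classify" else 2
        if len(self.conv_channels) < n_conv:
            raise ValueError(f"need at least {n_conv} conv channel widths for {self.task}")


class Network:
    """An ordered list of named layers with a shared forward/backward pass."""

    def __init__(self, layers: Sequence[Layer], cfg: NetConfig):
        self.layers = list(layers)
        self.cfg = cfg
        self.fitted = False

    @property
    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_conv(self) -> int:
        return sum(1 for layer in self.layers if isinstance(layer, Conv2D))

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            if not layer.is_marker:
                x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            if not layer.is_marker:
                grad = layer.backward(grad)

    def get_weights(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        state += [b.copy() for layer in self.layers for b in layer.buffers()]
        return state

    def set_weights(self, weights: list[np.ndarray]) -> None:
        buffers = [b for layer in self.layers for b in layer.buffers()]
        targets = [p.value for p in self.params()] + buffers
        for t, w in zip(targets, weights, strict=True):
            t[...] = w

    def architecture(self) -> dict:
        return {"task": self.cfg.task, "layers": self.layer_names,
                "n_parameters": self.n_parameters()}


def _as_batch(images: np.ndarray) -> np.ndarray:
    """Normalize uint8 images to a float (B, 1, H, W) batch in [0, 1]."""
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected (H, W) or (B, H, W) grayscale images")
    return (arr / 255.0)[:, None, :, :]


def _softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def build_classifier(cfg: NetConfig) -> Network:
    """The 16-layer / 3-convolution image classifier.

    input -> [conv -> batchnorm -> relu -> maxpool] x3 -> fullyconnected ->
    softmax -> classoutput; forward probabilities live on the 3-class simplex.
    """
    if cfg.task != "classify":
        raise ValueError("cfg.task must be 'classify'")
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    c1, c2, c3 = cfg.conv_channels[:3]
    layers: list[Layer] = [Input()]
    for c_in, c_out in ((1, c1), (c1, c2), (c2, c3)):
        layers += [Conv2D(c_in, c_out, rng), BatchNorm2D(c_out), ReLU(), MaxPool2()]
    layers += [Dense(c3 * (h // 8) * (w // 8), cfg.n_classes, rng),
               Softmax(), ClassOutput()]
    net = Network(layers, cfg)
    assert net.n_layers == 16 and net.n_conv == 3
    return net


def build_segmenter(cfg: NetConfig) -> Network:
    """The 11-layer / 3-convolution pixel classifier.

    input -> conv -> batchnorm -> relu -> maxpool -> conv -> relu -> conv ->
    upsample -> pixelsoftmax -> pixeloutput; the output is a 2-channel
    (non-tumor / tumor) score map on the input grid.
    """
    if cfg.task != "segment":
        raise ValueError("cfg.task must be 'segment'")
    rng = np.random.default_rng(cfg.seed)
    c1, c2 = cfg.conv_channels[:2]
    layers: list[Layer] = [
        Input(),
        Conv2D(1, c1, rng), BatchNorm2D(c1), ReLU(), MaxPool2(),
        Conv2D(c1, c2, rng), ReLU(),
        Conv2D(c2, cfg.n_classes, rng),
        Upsample2(),
        PixelSoftmax(), PixelOutput(),
    ]
    net = Network(layers, cfg)
    assert net.n_layers == 11 and net.n_conv == 3
    return net


def predict_proba(net: Network, images: np.ndarray) -> np.ndarray:
    """Class probabilities: (B, n_classes) for the classifier, a
    (B, n_classes, H, W) map for the segmenter."""
    return _softmax(net.logits(_as_batch(images), train=False), axis=1)


# ---------------------------------------------------------------------------
# training


@dataclasses.dataclass
class TrainTrace:
    """Per-iteration loss/accuracy plus validation checkpoints."""

    loss: list[float] = dataclasses.field(default_factory=list)
    accuracy: list[float] = dataclasses.field(default_factory=list)
    val_iterations: list[int] = dataclasses.field(default_factory=list)
    val_accuracy: list[float] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


class _Adam:
    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batches(n: int, batch_size: int, iterations: int, rng: np.random.Generator):
    """Seeded shuffled epochs, yielding ``iterations`` index batches."""
    produced = 0
    while produced < iterations:
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            if produced == iterations:
                return
            yield order[start:start + batch_size]
            produced += 1


def train_classifier(net: Network, images: np.ndarray, labels: np.ndarray,
                     cfg: NetConfig | None = None,
                     val_images: np.ndarray | None = None,
                     val_labels: np.ndarray | None = None
                     ) -> tuple[Network, TrainTrace]:
    """Train the classifier with softmax cross-entropy and Adam.

    The best checkpoint by validation accuracy (training-batch accuracy if
    no validation data is supplied) is restored before returning.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or net.cfg
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < cfg.n_classes:
        raise ValueError(f"training split must contain all {cfg.n_classes} classes")
    X = _as_batch(images)
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(net.params(), cfg.learning_rate)
    trace = TrainTrace()
    val_interval = cfg.val_interval or max(1, cfg.iterations // 10)
    best_acc, best_weights = -1.0, net.get_weights()

    for it, idx in enumerate(_batches(n, cfg.batch_size, cfg.iterations, rng), start=1):
        xb, yb = X[idx], y[idx]
        logits = net.logits(xb, train=True)
        probs = _softmax(logits)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps)))
        acc = float(np.mean(probs.argmax(axis=1) == yb))
        grad = probs.copy()
        grad[np.arange(len(yb)), yb] -= 1.0
        net.backward(grad / len(yb))
        opt.step()
        trace.loss.append(loss)
        trace.accuracy.append(acc)

        if it % val_interval == 0 or it == cfg.iterations:
            if val_images is not None:
                vprobs = predict_proba(net, val_images)
                vacc = float(np.mean(vprobs.argmax(axis=1) == np.asarray(val_labels)))
            else:
                # no held-out data: score the checkpoint on the full training set
                tprobs = _softmax(net.logits(X, train=False))
                vacc = float(np.mean(tprobs.argmax(axis=1) == y))
            trace.val_iterations.append(it)
            trace.val_accuracy.append(vacc)
            if vacc > best_acc:
                best_acc, best_weights = vacc, net.get_weights()

    net.set_weights(best_weights)
    net.fitted = True
    return net, trace


def _pixel_targets(masks: np.ndarray) -> np.ndarray:
    """Map three-level masks to binary pixel labels (tumor=1)."""
    arr = np.asarray(masks)
    if arr.ndim == 2:
        arr = arr[None]
    return ((arr == 255) | (arr == 225)).astype(np.int64)


def train_segmenter(net: Network, images: np.ndarray, masks: np.ndarray,
                    cfg: NetConfig | None = None) -> tuple[Network, TrainTrace]:
    """Train the pixel classifier with (optionally class-weighted) CE.

    ``masks`` use the 0/127/255 code; tumor pixels (255) are the positive
    class and everything else is negative.  With ``cfg.class_weight=None``
    inverse-frequency weights are estimated from the training masks, which
    matters because tumor pixels are rare.
    """
    cfg = cfg or net.cfg
    X = _as_batch(images)
    T = _pixel_targets(masks)
    if X.shape[0] != T.shape[0] or X.shape[2:] != T.shape[1:]:
        raise ValueError(f"images {X.shape} and masks {T.shape} do not align")
    if cfg.class_weight is None:
        pos = max(T.mean(), 1e-6)
        weights = np.array([0.5 / max(1 - pos, 1e-6), 0.5 / pos])
    else:
        weights = np.asarray(cfg.class_weight, dtype=float)

    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(net.params(), cfg.learning_rate)
    trace = TrainTrace()
    val_interval = cfg.val_interval or max(1, cfg.iterations // 10)
    best_acc, best_weights = -1.0, net.get_weights()

    for it, idx in enumerate(_batches(n, cfg.batch_size, cfg.iterations, rng), start=1):
        xb, tb = X[idx], T[idx]
        logits = net.logits(xb, train=True)          # (B, 2, H, W)
        probs = _softmax(logits, axis=1)
        eps = 1e-12
        p_true = np.take_along_axis(probs, tb[:, None], axis=1)[:, 0]
        w_pix = weights[tb]
        loss = float(-(w_pix * np.log(p_true + eps)).sum() / w_pix.sum())
        acc = float(np.mean(probs.argmax(axis=1) == tb))
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, tb[:, None], 1.0, axis=1)
        grad = w_pix[:, None] * (probs - onehot) / w_pix.sum()
        net.backward(grad)
        opt.step()
        trace.loss.append(loss)
        trace.accuracy.append(acc)
        if it % val_interval == 0 or it == cfg.iterations:
            trace.val_iterations.append(it)
            trace.val_accuracy.append(acc)
            if acc > best_acc:
                best_acc, best_weights = acc, net.get_weights()

    net.set_weights(best_weights)
    net.fitted = True
    return net, trace


def predict_mask(net: Network, img: np.ndarray,
                 threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Tumor-probability map and its thresholded binary {0, 255} mask."""
    if not net.fitted:
        raise RuntimeError("segmenter has not been trained")
    if net.cfg.task != "segment":
        raise ValueError("predict_mask needs a segmentation network")
    probs = predict_proba(net, img)
    prob_map = probs[0, 1] if np.asarray(img).ndim == 2 else probs[:, 1]
    mask = np.where(prob_map >= threshold, 255, 0).astype(np.uint8)
    return prob_map, mask
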