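"""AlexNet-style convolutional network for direct image staging.

The network takes a 224 x 224 x 3 tensor (the processed SHG image resized
and replicated across three channels), passes it through five convolution
layers — filter geometry (11x11x3, 96), (5x5x96, 256), (3x3x256, 384),
(3x3x384, 384), (3x3x384, 256) — with 2x2 max-pooling after the first,
second and fifth convolutions, then two 4096-wide fully connected layers
(plain matrix-vector products) and a 5-way softmax over the Metavir
stages.  The first convolution uses stride 4 with 2 px padding; the 3x3
convolutions pad by 1, giving the shape chain

    224 -> 55 -> 27 -> 27 -> 13 -> 13 -> 13 -> 13 -> 6  (6*6*256 = 9216).

Every layer's declared output shape is verified by propagation at build
time.

The engine is a small self-contained numpy implementation: im2col-based
convolution with analytic backprop, ReLU, 2x2 max-pooling and dense
layers, trained by mini-batch SGD with momentum and weight decay on the
cross-entropy loss.  Pre-trained weights are deliberately not used — the
network trains from scratch — so a *reduced-scale* variant (smaller input,
channel widths divided by 8, 128-wide FC layers) is provided for
experiments on desk-scale synthetic datasets; training the full
60M-parameter geometry is supported but is only sensible with far more
data and compute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from .preprocess import ProcessedImage

__all__ = [
    "CNNArchitecture",
    "CNNTrainConfig",
    "Network",
    "TrainedCNN",
    "resize_duplicate",
    "build_network",
    "train_cnn",
]


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvSpec:
    kernel: int
    out_channels: int
    stride: int
    pad: int
    pool_after: bool  # 2x2 stride-2 max pool after this conv


@dataclass(frozen=True)
class CNNArchitecture:
    """Layer plan: five convolutions, three 2x2 pools, two FC layers."""

    input_size: int = 224
    in_channels: int = 3
    convs: tuple[ConvSpec, ...] = (
        ConvSpec(11, 96, 4, 2, True),
        ConvSpec(5, 256, 1, 2, True),
        ConvSpec(3, 384, 1, 1, False),
        ConvSpec(3, 384, 1, 1, False),
        ConvSpec(3, 256, 1, 1, True),
    )
    fc_sizes: tuple[int, int] = (4096, 4096)
    n_classes: int = 5

    @classmethod
    def reduced(cls, width_divisor: int = 8, input_size: int = 64,
                fc_size: int = 128) -> "CNNArchitecture":
        """Same layer plan at 1/``width_divisor`` channel width and a
        smaller input, for from-scratch training on small datasets."""
        full = cls()
        convs = tuple(replace(c, out_channels=max(c.out_channels
                                                  // width_divisor, 4))
                      for c in full.convs)
        return cls(input_size=input_size, convs=convs,
                   fc_sizes=(fc_size, fc_size))

    def propagate_shapes(self) -> list[tuple[int, int]]:
        """(spatial size, channels) after each conv/pool stage; raises if
        any stage collapses to nothing."""
        s, ch = self.input_size, self.in_channels
        shapes = []
        for i, c in enumerate(self.convs):
            s = (s + 2 * c.pad - c.kernel) // c.stride + 1
            if s < 1:
                raise ValueError(f"conv layer C{i + 1} collapses the "
                                 f"feature map (size {s})")
            ch = c.out_channels
            shapes.append((s, ch))
            if c.pool_after:
                s = (s - 2) // 2 + 1
                if s < 1:
                    raise ValueError(f"pool after C{i + 1} collapses the "
                                     f"feature map")
                shapes.append((s, ch))
        return shapes

    @property
    def flat_size(self) -> int:
        s, ch = self.propagate_shapes()[-1]
        return s * s * ch


@dataclass(frozen=True)
class CNNTrainConfig:
    batch_size: int = 16
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------


def resize_duplicate(proc, size: int = 224) -> np.ndarray:
    """Bilinear-resize a single-channel image to ``size x size``, scale to
    [0, 1] and replicate across 3 channels."""
    if isinstance(proc, ProcessedImage):
        img = proc.enhanced
    else:
        img = np.asarray(proc, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("resize_duplicate expects a non-empty 2-D image")
    x = resize(img, (size, size), order=1, anti_aliasing=True,
               preserve_range=True).astype(float)
    peak = max(float(np.max(np.abs(img))), 1.0)
    x = np.clip(x / (255.0 if peak > 1.0 else 1.0), 0.0, 1.0)
    return np.repeat(x[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# numpy layers (NCHW internally)
# ---------------------------------------------------------------------------


def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    shape = (n, c, kh, kw, oh, ow)
    strides = (xp.strides[0], xp.strides[1],
               xp.strides[2], xp.strides[3],
               xp.strides[2] * stride, xp.strides[3] * stride)
    cols = np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


class _Conv:
    def __init__(self, in_ch, out_ch, kernel, stride, pad, rng):
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (out_ch, in_ch, kernel, kernel))
        self.b = np.zeros(out_ch)
        self.stride, self.pad, self.kernel = stride, pad, kernel

    def forward(self, x):
        self.x_shape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.kernel,
                               self.stride, self.pad)
        self.cols = cols
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = np.einsum("of,nfp->nop", wmat, cols) + self.b[None, :, None]
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, grad):
        n, oc, oh, ow = grad.shape
        g = grad.reshape(n, oc, oh * ow)
        wmat = self.W.reshape(oc, -1)
        self.gW = np.einsum("nop,nfp->of", g, self.cols).reshape(self.W.shape)
        self.gb = g.sum(axis=(0, 2))
        gcols = np.einsum("of,nop->nfp", wmat, g)
        # col2im
        _, c, h, w = self.x_shape
        k, s, p = self.kernel, self.stride, self.pad
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p))
        gcols = gcols.reshape(n, c, k, k, oh, ow)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + s * oh:s, j:j + s * ow:s] += gcols[:, :, i, j]
        return gx[:, :, p:p + h, p:p + w]

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask

    def params(self):
        return []


class _MaxPool2:
    """2x2 max pool, stride 2, floor semantics (trailing row/col dropped)."""

    def forward(self, x):
        n, c, h, w = x.shape
        self.x_shape = x.shape
        oh, ow = (h - 2) // 2 + 1, (w - 2) // 2 + 1
        xv = x[:, :, :oh * 2, :ow * 2].reshape(n, c, oh, 2, ow, 2)
        self.xv = xv
        out = xv.max(axis=(3, 5))
        self.out = out
        return out

    def backward(self, grad):
        n, c, h, w = self.x_shape
        oh, ow = grad.shape[2], grad.shape[3]
        mask = self.xv == self.out[:, :, :, None, :, None]
        # split ties evenly so gradient mass is conserved
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = (mask / counts) * grad[:, :, :, None, :, None]
        gx = np.zeros(self.x_shape)
        gx[:, :, :oh * 2, :ow * 2] = g.reshape(n, c, oh * 2, ow * 2)
        return gx

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.x_shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b  # GEMV per sample

    def backward(self, grad):
        self.gW = self.x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]


class Network:
    """Sequential conv-net with softmax head."""

    def __init__(self, arch: CNNArchitecture, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.layers = []
        in_ch = arch.in_channels
        for c in arch.convs:
            self.layers.append(_Conv(in_ch, c.out_channels, c.kernel,
                                     c.stride, c.pad, rng))
            self.layers.append(_ReLU())
            if c.pool_after:
                self.layers.append(_MaxPool2())
            in_ch = c.out_channels
        self.layers.append(_Flatten())
        n_in = arch.flat_size
        self.fc_indices = []
        for n_out in arch.fc_sizes:
            self.fc_indices.append(len(self.layers))
            self.layers.append(_Dense(n_in, n_out, rng))
            self.layers.append(_ReLU())
            n_in = n_out
        self.layers.append(_Dense(n_in, arch.n_classes, rng))
        self._audit_shapes()

    def _audit_shapes(self) -> None:
        """Forward a zero tensor and confirm each declared stage shape."""
        declared = self.arch.propagate_shapes()
        x = np.zeros((1, self.arch.in_channels, self.arch.input_size,
                      self.arch.input_size))
        seen = []
        for layer in self.layers:
            x = layer.forward(x)
            if isinstance(layer, (_Conv, _MaxPool2)):
                seen.append((x.shape[2], x.shape[1]))
        if seen != declared:
            raise ValueError(f"shape propagation mismatch: declared "
                             f"{declared}, got {seen}")
        if x.shape[1] != self.arch.n_classes:
            raise ValueError("output layer width != n_classes")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a batch (n, h, w, 3)."""
        a = np.transpose(np.asarray(x, dtype=float), (0, 3, 1, 2))
        for layer in self.layers:
            a = layer.forward(a)
        a = a - a.max(axis=1, keepdims=True)
        e = np.exp(a)
        return e / e.sum(axis=1, keepdims=True)

    def train_step(self, x, y_onehot, lr, momentum, weight_decay, velocity):
        probs = self.forward(x)
        n = x.shape[0]
        loss = float(-np.sum(y_onehot * np.log(probs + 1e-12)) / n)
        grad = (probs - y_onehot) / n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        i = 0
        for layer in self.layers:
            for name, p, g in layer.params():
                g = g + weight_decay * p
                if i not in velocity:
                    velocity[i] = np.zeros_like(p)
                velocity[i] = momentum * velocity[i] - lr * g
                p += velocity[i]
                i += 1
        return loss


def build_network(arch: CNNArchitecture | None = None,
                  seed: int = 0) -> Network:
    """Instantiate the network; raises at build time on any layer-shape
    inconsistency."""
    return Network(arch or CNNArchitecture(), seed=seed)


@dataclass
class TrainedCNN:
    network: Network
    classes: np.ndarray
    losses: list[float] = field(default_factory=list)

    def predict_scores(self, tensors: np.ndarray) -> np.ndarray:
        return self.network.forward(tensors)


def train_cnn(tensors: np.ndarray, labels: np.ndarray,
              cfg: CNNTrainConfig | None = None,
              arch: CNNArchitecture | None = None) -> TrainedCNN:
    """Mini-batch SGD with momentum and weight decay on cross-entropy.

    ``tensors``: (n, size, size, 3) in [0, 1]; seeded and deterministic.
    Raises on divergence (non-finite loss), echoing the configuration.
    """
    cfg = cfg or CNNTrainConfig()
    arch = arch or CNNArchitecture.reduced()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    idx = np.searchsorted(classes, labels)
    onehot = np.zeros((len(labels), arch.n_classes))
    onehot[np.arange(len(labels)), idx] = 1.0
    net = Network(arch, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    velocity: dict[int, np.ndarray] = {}
    losses = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(labels))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(labels), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            loss = net.train_step(tensors[sel], onehot[sel],
                                  cfg.learning_rate, cfg.momentum,
                                  cfg.weight_decay, velocity)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"CNN training diverged (non-finite loss) at epoch "
                    f"{epoch}; config: {cfg}")
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    return TrainedCNN(network=net, classes=classes, losses=losses)
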