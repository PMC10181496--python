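"""A 1-D residual network for multivariate time-series classification.

The architecture is the standard time-series ResNet: a convolutional stem,
three residual blocks of three 1-D convolutions each (kernel sizes 8/5/3)
with batch normalization and ReLU, a global-average-pooling head and a
softmax classifier. Each block computes ``x_{l+1} = h(x_l) + F(x_l, W_l)``
where the shortcut ``h`` is the identity when channel counts match and a
1x1 convolution (plus batch norm) otherwise. All convolutions use "same"
padding, so a stride-s layer maps length L to ceil(L / s).

The network, its gradients and the Adam optimizer are implemented directly
on NumPy arrays. Everything is deterministic given the seed: parameter
initialization and batch shuffling are the only random elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResNetSpec",
    "ResNet1D",
    "Adam",
    "same_pad_output_dims",
    "conv_output_dims",
    "residual_block_forward",
    "build_resnet",
]


def conv_output_dims(in_size: int, filter_size: int, padding: int,
                     stride: int) -> int:
    """General convolution output length: (W - F + 2P) / S + 1."""
    if min(in_size, filter_size, stride) < 1 or padding < 0:
        raise ValueError("sizes and stride must be positive, padding >= 0")
    return (in_size - filter_size + 2 * padding) // stride + 1


def same_pad_output_dims(in_w: int, in_h: int, filter_w: int, filter_h: int,
                         stride_w: int, stride_h: int) -> tuple[int, int]:
    """Output (width, height) of a same-padded convolution: ceil(in/stride)."""
    for v in (in_w, in_h, filter_w, filter_h, stride_w, stride_h):
        if v < 1:
            raise ValueError("all dimensions must be positive integers")
    return math.ceil(in_w / stride_w), math.ceil(in_h / stride_h)


def _same_pad_amounts(k: int, s: int, L: int) -> tuple[int, int]:
    """Left/right zero padding realizing out = ceil(L/s)."""
    out = math.ceil(L / s)
    total = max((out - 1) * s + k - L, 0)
    left = total // 2
    return left, total - left


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class Conv1D:
    """Same-padded 1-D convolution on (batch, length, channels) arrays.

    The convolution is evaluated as one batched matmul per kernel tap,
    which avoids materializing im2col tensors.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, dtype=np.float32):
        scale = np.sqrt(2.0 / (kernel * c_in))  # He initialization
        self.W = rng.normal(0.0, scale, size=(kernel, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.kernel, self.stride = kernel, stride
        self.c_in, self.c_out = c_in, c_out
        self.dtype = dtype
        self._cache = None

    def params(self):
        return [("W", self), ("b", self)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, L, C = x.shape
        pl, pr = _same_pad_amounts(self.kernel, self.stride, L)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        Lo = math.ceil(L / self.stride)
        span = (Lo - 1) * self.stride + 1
        y = np.broadcast_to(self.b, (N, Lo, self.c_out)).copy()
        for j in range(self.kernel):
            y += xp[:, j:j + span:self.stride] @ self.W[j]
        self._cache = (xp, x.shape, (pl, pr), Lo, span)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, x_shape, (pl, pr), Lo, span = self._cache
        N, L, C = x_shape
        self.db = dy.sum(axis=(0, 1))
        self.dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            seg = xp[:, j:j + span:self.stride]  # (N, Lo, C)
            self.dW[j] = np.tensordot(seg, dy, axes=([0, 1], [0, 1]))
            dxp[:, j:j + span:self.stride] += dy @ self.W[j].T
        return dxp[:, pl:pl + L]


class BatchNorm1D:
    """Per-channel batch normalization over batch and time."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [("gamma", self), ("beta", self)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[1]
        self.dgamma = (dy * xhat).sum(axis=(0, 1))
        self.dbeta = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        return inv * (dxhat - dxhat.mean(axis=(0, 1))
                      - xhat * (dxhat * xhat).sum(axis=(0, 1)) / m)


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class ResidualBlock:
    """Three conv-BN(-ReLU) stages plus a shortcut; final ReLU after the add."""

    def __init__(self, c_in: int, filters: int, kernels: tuple[int, ...],
                 rng: np.random.Generator, dtype=np.float32):
        self.stages = []
        c = c_in
        for i, k in enumerate(kernels):
            conv = Conv1D(c, filters, k, rng, dtype=dtype)
            bn = BatchNorm1D(filters, dtype=dtype)
            relu = ReLU() if i < len(kernels) - 1 else None
            self.stages.append((conv, bn, relu))
            c = filters
        if c_in != filters:
            self.proj = Conv1D(c_in, filters, 1, rng, dtype=dtype)
            self.proj_bn = BatchNorm1D(filters, dtype=dtype)
        else:
            self.proj = self.proj_bn = None
        self.out_relu = ReLU()

    def layers(self):
        out = []
        for conv, bn, relu in self.stages:
            out += [conv, bn] + ([relu] if relu else [])
        if self.proj is not None:
            out += [self.proj, self.proj_bn]
        return out + [self.out_relu]

    def params(self):
        return [p for lay in self.layers() for p in lay.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for conv, bn, relu in self.stages:
            h = bn.forward(conv.forward(h, training), training)
            if relu is not None:
                h = relu.forward(h, training)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            sc = x
        return self.out_relu.forward(sc + h, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.out_relu.backward(dy)
        dh = dy
        for conv, bn, relu in reversed(self.stages):
            if relu is not None:
                dh = relu.backward(dh)
            dh = conv.backward(bn.backward(dh))
        if self.proj is not None:
            dsc = self.proj.backward(self.proj_bn.backward(dy))
        else:
            dsc = dy
        return dh + dsc


@dataclass
class ResNetSpec:
    """Architecture of the time-series residual network.

    ``block_filters``/``block_kernels`` give the channel width and the three
    kernel sizes of each residual block; a 1x1 projection appears on the
    shortcut automatically whenever the width changes.
    """

    input_channels: int = 6
    n_classes: int = 3
    stem_filters: int = 64
    stem_kernel: int = 7
    block_filters: tuple[int, ...] = (64, 128, 128)
    block_kernels: tuple[int, ...] = (8, 5, 3)

    def __post_init__(self):
        if self.input_channels < 1 or self.n_classes < 2:
            raise ValueError("need >=1 input channel and >=2 classes")
        if len(self.block_filters) < 1:
            raise ValueError("at least one residual block required")

    def scaled(self, width: int) -> "ResNetSpec":
        """Spec with the first block ``width`` channels wide (rest x2)."""
        n = len(self.block_filters)
        return ResNetSpec(
            input_channels=self.input_channels, n_classes=self.n_classes,
            stem_filters=width, stem_kernel=self.stem_kernel,
            block_filters=tuple(width if i == 0 else 2 * width
                                for i in range(n)),
            block_kernels=self.block_kernels)


class Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in),
                            size=(c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)

    def params(self):
        return [("W", self), ("b", self)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class ResNet1D:
    """Stem conv + residual blocks + global average pooling + softmax."""

    def __init__(self, spec: ResNetSpec, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.dtype = dtype
        self.stem = Conv1D(spec.input_channels, spec.stem_filters,
                           spec.stem_kernel, rng, dtype=dtype)
        self.stem_bn = BatchNorm1D(spec.stem_filters, dtype=dtype)
        self.stem_relu = ReLU()
        self.blocks = []
        c = spec.stem_filters
        for f in spec.block_filters:
            self.blocks.append(ResidualBlock(c, f, spec.block_kernels, rng,
                                             dtype=dtype))
            c = f
        self.head = Dense(c, spec.n_classes, rng, dtype=dtype)

    # -- introspection ----------------------------------------------------
    def conv_layers(self) -> list[Conv1D]:
        convs = [self.stem]
        for b in self.blocks:
            convs += [lay for lay in b.layers() if isinstance(lay, Conv1D)]
        return convs

    def n_parameters(self) -> int:
        return sum(getattr(o, n).size for n, o in self._params())

    def _params(self):
        ps = self.stem.params() + self.stem_bn.params()
        for b in self.blocks:
            ps += b.params()
        return ps + self.head.params()

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities for a (batch, length, channels) array."""
        x = np.asarray(x, dtype=self.dtype)
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(x, training), training),
            training)
        for b in self.blocks:
            h = b.forward(h, training)
        self._gap_len = h.shape[1]
        pooled = h.mean(axis=1)
        logits = self.head.forward(pooled, training)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def loss_and_backward(self, labels: np.ndarray) -> float:
        """Cross-entropy of the last forward pass; populates gradients."""
        n = len(labels)
        probs = self._probs
        loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        dpooled = self.head.backward(dlogits)
        dh = np.repeat(dpooled[:, None, :], self._gap_len,
                       axis=1) / self._gap_len
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(dh)))
        return float(loss)

    def predict(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Argmax class labels at inference (running batch-norm stats)."""
        out = []
        for i in range(0, len(x), batch):
            out.append(np.argmax(self.forward(x[i:i + batch],
                                              training=False), axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


class Adam:
    """Adam on every parameter of a ResNet1D (gradients read from .d<name>)."""

    def __init__(self, model: ResNet1D, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model, self.lr, self.betas, self.eps = model, lr, betas, eps
        self.t = 0
        self.state = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for name, obj in self.model._params():
            g = getattr(obj, "d" + name, None)
            if g is None:
                continue
            key = (id(obj), name)
            m, v = self.state.get(key, (np.zeros_like(g), np.zeros_like(g)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.state[key] = (m, v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p = getattr(obj, name)
            setattr(obj, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def residual_block_forward(x: np.ndarray, block: ResidualBlock,
                           training: bool = False) -> np.ndarray:
    """Apply one residual block: ``h(x) + F(x, W)`` then ReLU."""
    return block.forward(x, training)


def build_resnet(spec: ResNetSpec, seed: int = 0, dtype=np.float32) -> ResNet1D:
    """Instantiate the network described by ``spec`` with seeded weights."""
    return ResNet1D(spec, seed=seed, dtype=dtype)
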