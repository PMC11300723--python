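"""Minimal 3D convolutional network engine in numpy.

Layers operate on single samples shaped (channels, D, H, W) in float32 and
implement explicit ``forward``/``backward`` passes; convolution is im2col +
matmul, which keeps the heavy lifting inside BLAS.  Training uses batch
size 1 (volumes are large), so batch normalization normalizes over the
spatial dimensions of each sample and keeps running statistics for
inference.  Everything is deterministic given the seeds of the generators
handed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Dropout",
    "MaxPool2",
    "Upsample2",
    "ConvBlock",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Conv3d:
    """3D convolution with 'same' zero padding.

    Weights are stored as a (in_channels * k^3, out_channels) matrix whose
    row order matches the im2col layout (channel-major, then kernel
    offsets).
    """

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.weight = Param(w)
        self.bias = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
        # (C, D, H, W, k, k, k) -> (D*H*W, C*k^3)
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6)
        return np.ascontiguousarray(cols.reshape(-1, self.cin * k**3), dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        cols = self._im2col(x)
        y = cols @ self.weight.value + self.bias.value
        if train:
            self._cols, self._shape = cols, (d, h, w)
        return np.ascontiguousarray(y.reshape(d, h, w, self.cout).transpose(3, 0, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._shape is not None
        d, h, w = self._shape
        dyf = np.ascontiguousarray(dy.transpose(1, 2, 3, 0).reshape(-1, self.cout))
        self.weight.grad += self._cols.T @ dyf
        self.bias.grad += dyf.sum(axis=0)
        dcols = dyf @ self.weight.value.T
        k, p = self.k, self.k // 2
        dcols = dcols.reshape(d, h, w, self.cin, k, k, k)
        dxp = np.zeros((self.cin, d + 2 * p, h + 2 * p, w + 2 * p), dtype=np.float32)
        for a in range(k):
            for b in range(k):
                for c3 in range(k):
                    dxp[:, a : a + d, b : b + h, c3 : c3 + w] += dcols[
                        :, :, :, :, a, b, c3
                    ].transpose(3, 0, 1, 2)
        self._cols = None
        return dxp[:, p : p + d, p : p + h, p : p + w] if p else dxp


class BatchNorm3d:
    """Per-channel normalization over the spatial dims of one sample.

    With batch size 1 this is instance normalization: the sample's own
    statistics are used at inference as well as in training, so the
    normalization seen by the heads is identical in both modes (running
    averages are still tracked for monitoring and checkpoints).  Scale and
    shift (gamma, beta) are trainable.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    @property
    def n_params(self) -> int:
        return 2 * self.c

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xf = x.reshape(self.c, -1)
        mean = xf.mean(axis=1)
        var = xf.var(axis=1)
        if train:
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mean[:, None]) * inv[:, None]
        if train:
            self._cache = (xhat, inv)
        y = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        return y.reshape(x.shape).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        dyf = dy.reshape(self.c, -1)
        n = dyf.shape[1]
        self.gamma.grad += (dyf * xhat).sum(axis=1)
        self.beta.grad += dyf.sum(axis=1)
        g = self.gamma.value[:, None]
        # standard batch-norm gradient, vectorized per channel
        dxhat = dyf * g
        dx = (
            inv[:, None]
            / n
            * (n * dxhat - dxhat.sum(axis=1, keepdims=True) - xhat * (dxhat * xhat).sum(axis=1, keepdims=True))
        )
        self._cache = None
        return dx.reshape(dy.shape).astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Dropout:
    """Inverted dropout; identity when rate is 0 or in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2x2 max pooling (spatial dims must be even)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        r = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        r = r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        idx = np.argmax(r, axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        c, d, h, w = shape
        scat = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(scat, idx[..., None], dy[..., None], axis=-1)
        dx = (
            scat.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )
        self._cache = None
        return dx


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = dy.shape
        return (
            dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .sum(axis=(2, 4, 6))
            .astype(np.float32)
        )


class ConvBlock:
    """An intermediate layer: (conv -> BN -> ReLU) x n, then dropout."""

    def __init__(
        self,
        cin: int,
        cout: int,
        n_convs: int,
        k: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        self.layers = []
        c = cin
        for _ in range(n_convs):
            self.layers += [Conv3d(c, cout, k, rng), BatchNorm3d(cout), ReLU()]
            c = cout
        self.layers.append(Dropout(dropout, rng))

    def params(self) -> list[Param]:
        out = []
        for lay in self.layers:
            out += lay.params()
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
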