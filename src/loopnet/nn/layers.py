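"""Elementary differentiable layers (NCHW tensor convention, float32).

Every layer exposes ``forward(x, train)`` and ``backward(dy)``; gradients
accumulate into ``Parameter.grad``. Backward assumes the immediately
preceding forward was called with ``train=True`` (caches are only kept
then).
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name", "trainable")

    def __init__(self, data: np.ndarray, name: str = "", trainable: bool = True):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {f"{prefix}{p.name}": p.data for p in self.params()}
        out.update({f"{prefix}{k}": v for k, v in self.buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for p in self.params():
            p.data[...] = state[f"{prefix}{p.name}"]
        for k, v in self.buffers().items():
            v[...] = state[f"{prefix}{k}"]


def _pair(v) -> tuple[int, int]:
    return (v, v) if np.isscalar(v) else tuple(v)


class Conv2D(Layer):
    """2-D convolution (cross-correlation) with stride, dilation and either
    'valid' or stride-1 'same' padding, via an explicit im2col lowering."""

    def __init__(self, in_channels, out_channels, kernel, stride=(1, 1),
                 dilation=(1, 1), padding="valid", rng=None):
        rng = rng or np.random.default_rng()
        self.kernel = _pair(kernel)
        self.stride = _pair(stride)
        self.dilation = _pair(dilation)
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and self.stride != (1, 1):
            raise ValueError("'same' padding is only supported with stride 1")
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels
        kh, kw = self.kernel
        fan_in = in_channels * kh * kw
        self.W = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kh, kw)),
            name="W",
        )
        self.b = Parameter(np.zeros(out_channels), name="b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape: tuple[int, int]) -> tuple[int, int]:
        H, W = in_shape
        kh, kw = self.kernel
        dh, dw = self.dilation
        sh, sw = self.stride
        if self.padding == "same":
            return (H, W)
        eh, ew = dh * (kh - 1) + 1, dw * (kw - 1) + 1
        return ((H - eh) // sh + 1, (W - ew) // sw + 1)

    def _pad(self):
        kh, kw = self.kernel
        dh, dw = self.dilation
        if self.padding == "same":
            ph, pw = dh * (kh - 1), dw * (kw - 1)
        else:
            ph = pw = 0
        return ph, pw

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        kh, kw = self.kernel
        sh, sw = self.stride
        dh, dw = self.dilation
        ph, pw = self._pad()
        ph0, pw0 = ph // 2, pw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph0, ph - ph0), (pw0, pw - pw0))) if (ph or pw) else x
        Hp, Wp = xp.shape[2:]
        OH = (Hp - (dh * (kh - 1) + 1)) // sh + 1
        OW = (Wp - (dw * (kw - 1) + 1)) // sw + 1
        if OH < 1 or OW < 1:
            raise ValueError(f"input {H}x{W} too small for kernel {self.kernel} "
                             f"dilation {self.dilation}")
        cols = np.empty((N, C, kh, kw, OH, OW), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i * dh: i * dh + sh * OH: sh,
                                      j * dw: j * dw + sw * OW: sw]
        y = np.tensordot(cols, self.W.data, axes=([1, 2, 3], [1, 2, 3]))  # (N,OH,OW,F)
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + self.b.data[None, :, None, None]
        if train:
            self._cache = (cols, xp.shape, (ph0, ph - ph0, pw0, pw - pw0), (OH, OW))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (pt, pb, pl, pr), (OH, OW) = self._cache
        kh, kw = self.kernel
        sh, sw = self.stride
        dh, dw = self.dilation
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dyt = dy.transpose(0, 2, 3, 1)  # (N,OH,OW,F)
        self.W.grad += np.tensordot(dyt, cols, axes=([0, 1, 2], [0, 4, 5]))
        dcols = np.tensordot(dyt, self.W.data, axes=([3], [0]))  # (N,OH,OW,C,kh,kw)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N,C,kh,kw,OH,OW)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i * dh: i * dh + sh * OH: sh,
                    j * dw: j * dw + sw * OW: sw] += dcols[:, :, i, j]
        self._cache = None
        H, W = xp_shape[2] - pt - pb, xp_shape[3] - pl - pr
        return dxp[:, :, pt: pt + H, pl: pl + W]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels), name="gamma")
        self.beta = Parameter(np.zeros(channels), name="beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std, x.shape[0] * x.shape[2] * x.shape[3])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class PReLU(Layer):
    """Per-channel parametric ReLU, slope initialized at 0.25."""

    def __init__(self, channels: int, init: float = 0.25):
        self.a = Parameter(np.full(channels, init), name="a")
        self._cache = None

    def params(self):
        return [self.a]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.a.data[None, :, None, None]
        neg = np.minimum(x, 0.0)
        y = np.maximum(x, 0.0) + a * neg
        if train:
            self._cache = (x > 0, neg)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pos, neg = self._cache
        self._cache = None
        self.a.grad += (dy * neg).sum(axis=(0, 2, 3))
        return dy * np.where(pos, 1.0, self.a.data[None, :, None, None]).astype(dy.dtype)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dy = dy * self._mask.astype(dy.dtype)
        self._mask = None
        return dy


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None):
        rng = rng or np.random.default_rng()
        self.in_features = in_features
        self.out_features = out_features
        self.W = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / max(in_features, 1)), size=(in_features, out_features)),
            name="W",
        )
        self.b = Parameter(np.zeros(out_features), name="b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = x @ self.W.data + self.b.data
        if train:
            self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.data.T
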