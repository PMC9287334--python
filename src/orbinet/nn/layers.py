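"""NumPy building blocks for the multi-plane network: forward and backward.

All feature maps are channels-first ``(batch, channels, height, width)``
float32.  Convolutions are cross-correlations (no kernel flip), 'same'
zero padding, computed by im2col + one BLAS matmul; gradients w.r.t. the
input are computed as a correlation with the spatially flipped, transposed
kernel so no scatter-add is needed.  Each layer caches what its backward
pass needs; ``backward`` returns the input gradient (or ``None`` for
layers at the bottom of the graph) and accumulates parameter gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _windows3(x: np.ndarray) -> np.ndarray:
    """3x3 sliding windows of a zero-padded map -> (B, C, H, W, 3, 3)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    return sliding_window_view(xp, (3, 3), axis=(2, 3))


class Layer:
    def params(self) -> list[Param]:
        return []


_SHIFTS = [(di, dj) for di in range(3) for dj in range(3)]


class Conv3x3(Layer):
    """Standard 3x3 'same' convolution mixing channels, weights (F, C, 3, 3).

    Implemented as one large channels-last matmul on the zero-padded input
    followed by nine shifted-view accumulations, which keeps all heavy
    arithmetic inside a single contiguous BLAS call:

        Ybig[b, hp, wp, f, k] = sum_c  xpad[b, hp, wp, c] * W[f, c, k]
        out[b, f, h, w]       = sum_k  Ybig[b, h+di_k, w+dj_k, f, k] + bias
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        fan_in = in_channels * 9
        fan_out = out_channels * 9
        self.w = Param(xavier_uniform(rng, (out_channels, in_channels, 3, 3), fan_in, fan_out))
        self.b = Param(np.zeros(out_channels, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def _wmat(self) -> np.ndarray:
        # (C, F*9): column (f, k) holds W[f, :, di_k, dj_k]
        f, c = self.w.value.shape[:2]
        return self.w.value.reshape(f, c, 9).transpose(1, 0, 2).reshape(c, f * 9)

    def forward(self, x: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        f = self.w.value.shape[0]
        xp = np.pad(x.transpose(0, 2, 3, 1), ((0, 0), (1, 1), (1, 1), (0, 0)))
        xp = np.ascontiguousarray(xp)  # (B, H+2, W+2, C)
        self._xp = xp
        self._need_input_grad = need_input_grad
        ybig = (xp.reshape(-1, c) @ self._wmat()).reshape(b, h + 2, w + 2, f, 9)
        out = np.zeros((b, h, w, f), dtype=np.float32)
        for k, (di, dj) in enumerate(_SHIFTS):
            out += ybig[:, di : di + h, dj : dj + w, :, k]
        return out.transpose(0, 3, 1, 2) + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        b, f, h, w = dout.shape
        c = self.w.value.shape[1]
        dout_l = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))
        dybig = np.zeros((b, h + 2, w + 2, f, 9), dtype=np.float32)
        for k, (di, dj) in enumerate(_SHIFTS):
            dybig[:, di : di + h, dj : dj + w, :, k] = dout_l
        dybig_mat = dybig.reshape(-1, f * 9)
        dwmat = self._xp.reshape(-1, c).T @ dybig_mat  # (C, F*9)
        self.w.grad += dwmat.reshape(c, f, 9).transpose(1, 0, 2).reshape(f, c, 3, 3)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        self._xp = None
        if not self._need_input_grad:
            return None
        dxp = (dybig_mat @ self._wmat().T).reshape(b, h + 2, w + 2, c)
        return np.ascontiguousarray(dxp[:, 1 : 1 + h, 1 : 1 + w, :].transpose(0, 3, 1, 2))


class DepthwiseConv3x3(Layer):
    """Depthwise 3x3 'same' convolution: one filter per channel, no mixing."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.w = Param(xavier_uniform(rng, (channels, 3, 3), 9, 9))
        self.b = Param(np.zeros(channels, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        self._x = x
        self._need_input_grad = need_input_grad
        win = _windows3(x)
        out = np.einsum("bchwij,cij->bchw", win, self.w.value, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        win = _windows3(self._x)
        self.w.grad += np.einsum("bchwij,bchw->cij", win, dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        self._x = None
        if not self._need_input_grad:
            return None
        w_rot = self.w.value[:, ::-1, ::-1]
        dwin = _windows3(dout)
        return np.einsum("bchwij,cij->bchw", dwin, np.ascontiguousarray(w_rot),
                         optimize=True)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; input height/width must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2x2 needs even spatial dims, got {(h, w)}")
        tiles = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        tiles = tiles.reshape(b, c, h // 2, w // 2, 4)
        self._argmax = tiles.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(tiles, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        tiles = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(tiles, self._argmax[..., None], dout[..., None], axis=-1)
        return (tiles.reshape(b, c, h // 2, w // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w))


class Dense(Layer):
    """Fully connected layer, weights (out, in)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(xavier_uniform(rng, (n_out, n_in), n_in, n_out))
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Adam:
    """Adaptive-moment gradient descent over a list of Params."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60))),
                    np.exp(np.clip(z, -60, 60)) / (1.0 + np.exp(np.clip(z, -60, 60))))


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)
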