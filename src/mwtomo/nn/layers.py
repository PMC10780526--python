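"""Minimal NumPy CNN layers with analytic backprop.

Only what the encoder-decoder reconstruction network needs: same-padded
k x k convolutions, ReLU, 2x2 max pooling, 2x2-stride-2 transposed
convolutions and channel concatenation. Convolutions use a
shift-and-accumulate scheme (k^2 BLAS matmuls via tensordot) instead of
im2col to keep peak memory low on 1-CPU boxes. All layers operate on
(N, C, H, W) arrays; gradients are exact and verified against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: layers expose params/grads lists aligned by index."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded convolution, stride 1, He-initialized."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.kernel = kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.w = rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p, k = self.pad, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.zeros((n, h, w, self.w.shape[0]), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + h, j : j + w]
                out += np.tensordot(xs, self.w[:, :, i, j], axes=([1], [1]))
        out += self.b
        self._xp = xp
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, f, h, w = dy.shape
        p, k = self.pad, self.kernel
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))  # (N,H,W,F)
        self.grads[1][...] = dyt.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + h, j : j + w]
                self.grads[0][:, :, i, j] = np.tensordot(
                    dyt, xs, axes=([0, 1, 2], [0, 2, 3])
                )
                dxp[:, :, i : i + h, j : j + w] += np.tensordot(
                    dyt, self.w[:, :, i, j], axes=([3], [0])
                ).transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to one winner."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        xr = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(n, c, h, w)


class ConvTranspose2(Layer):
    """2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(
        self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32
    ) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * 4))
        self.w = rng.normal(0.0, scale, (c_in, c_out, 2, 2)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        y4 = np.tensordot(x, self.w, axes=([1], [0]))  # (N,H,W,Cout,2,2)
        y4 += self.b[:, None, None]
        out = y4.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.w.shape[1], 2 * h, 2 * w)
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, f, hh, ww = dy.shape
        h, w = hh // 2, ww // 2
        dyr = dy.reshape(n, f, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,H,W,F,2,2)
        self.grads[0][...] = np.tensordot(x, dyr, axes=([0, 2, 3], [0, 1, 2]))
        self.grads[1][...] = dyr.sum(axis=(0, 1, 2, 4, 5))
        dx = np.tensordot(dyr, self.w, axes=([3, 4, 5], [1, 2, 3]))  # (N,H,W,Cin)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class Concat(Layer):
    """Channel concatenation of (up-path, skip) used by the decoder."""

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:  # type: ignore[override]
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:  # type: ignore[override]
        return dy[:, : self._split], dy[:, self._split :]


class Adam:
    """Adaptive moment estimation over a flat list of parameter arrays."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
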