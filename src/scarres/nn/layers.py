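"""Layers with explicit forward/backward passes, NHWC layout.

Convolutions are computed as a sum of kernel-offset channel matmuls
(no im2col patch matrix), which keeps the working set small enough for
CPU training on 128x128 slices.  Default dtype is float32; float64 is
supported for gradient checking.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "BatchNorm2d", "MaxPool2", "Upsample2", "Adam"]


class Layer:
    """Base: trainable arrays in .params, matching gradients in .grads."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 'same' k x k convolution, He-initialized.

    Weights are stored as (k, k, c_in, c_out); the forward pass is
    y = sum_ij x_padded[shifted by ij] @ W[i, j].
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        self.dtype = dtype
        std = np.sqrt(2.0 / (c_in * k * k))
        self.params["W"] = rng.normal(0.0, std, (k, k, c_in, c_out)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        p = self.pad
        self._xp = (
            np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        )
        n, h, w, _ = x.shape
        W = self.params["W"]
        y = np.zeros((n, h, w, self.c_out), dtype=self.dtype)
        for i in range(self.k):
            for j in range(self.k):
                y += self._xp[:, i : i + h, j : j + w, :] @ W[i, j]
        y += self.params["b"]
        self._out_hw = (n, h, w)
        return y

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=self.dtype)
        n, h, w = self._out_hw
        W = self.params["W"]
        dW = np.empty_like(W)
        dyf = dy.reshape(-1, self.c_out)
        dxp = np.zeros_like(self._xp)
        for i in range(self.k):
            for j in range(self.k):
                xs = self._xp[:, i : i + h, j : j + w, :].reshape(-1, self.c_in)
                dW[i, j] = xs.T @ dyf
                dxp[:, i : i + h, j : j + w, :] += dy @ W[i, j].T
        self.grads["W"] = dW
        self.grads["b"] = dyf.sum(axis=0)
        p = self.pad
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) in NHWC layout."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.dtype = dtype

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2), dtype=self.dtype)
            var = x.var(axis=(0, 1, 2), dtype=self.dtype)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat = self._xhat
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dy.sum(axis=(0, 1, 2))
        g = self.params["gamma"]
        if not self._train:
            return dy * g / self._std
        dxhat = dy * g
        return (
            dxhat
            - dxhat.mean(axis=(0, 1, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 1, 2), keepdims=True)
        ) / self._std


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even input sizes only)."""

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(n, h, w, c)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= (self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)).astype(p.dtype)
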