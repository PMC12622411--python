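"""Layer primitives with cached forward passes and explicit gradients.

Every layer exposes ``forward(x, train)`` and ``backward(grad)``; parameters
and their gradient buffers are reachable through ``params()`` as
``(array, grad)`` pairs shared with the optimizer. Convolutions use im2col
so the heavy lifting is BLAS matmul; tensors are NCHW float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm2d", "ReLU", "Linear", "Dropout",
    "Flatten", "GlobalAvgPool", "Sequential", "ResidualBlock",
]


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []

    def __call__(self, x, train=True):
        return self.forward(x, train)


class Conv2d(Layer):
    """3x3 / 1x1 convolution with 'same'-style padding and stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = kernel
        self.stride = stride
        self.pad = kernel // 2
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _im2col(self, xp: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(
            xp.shape[0], h_out, w_out, self.c_in * k * k)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        h_out = (h + 2 * p - k) // s + 1
        w_out = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, h_out, w_out)
        out = cols.reshape(-1, cols.shape[-1]) @ self.w + self.b
        self._cache = (cols, x.shape, xp.shape)
        return out.reshape(n, h_out, w_out, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, x_shape, xp_shape = self._cache
        n, _, h_out, w_out = grad.shape
        k, s, p = self.k, self.stride, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        flat = cols.reshape(-1, cols.shape[-1])
        self.dw += flat.T @ g
        self.db += g.sum(axis=0)
        dcols = (g @ self.w.T).reshape(n, h_out, w_out, self.c_in, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * h_out:s, kj:kj + s * w_out:s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.dgamma += (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (g - sum_g / n_eff - xhat * sum_gx / n_eff)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.w.T


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=True):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn plus a (projected) skip, then relu."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(c_in, c_out, 3, stride, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride, rng)
            self.bn_proj = BatchNorm2d(c_out)
        else:
            self.proj = None
        self.relu_out = ReLU()

    def params(self):
        layers = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            layers += [self.proj, self.bn_proj]
        return [p for l in layers for p in l.params()]

    def forward(self, x, train=True):
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.proj is not None:
            skip = self.bn_proj.forward(self.proj.forward(x, train), train)
        else:
            skip = x
        return self.relu_out.forward(out + skip, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        g_main = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(grad)))))
        if self.proj is not None:
            g_skip = self.proj.backward(self.bn_proj.backward(grad))
        else:
            g_skip = grad
        return g_main + g_skip
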