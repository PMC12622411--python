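"""Stacked LSTM sequence classifier with hand-written BPTT."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Linear

__all__ = ["LSTMLayer", "LSTMClassifier"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class LSTMLayer(Layer):
    """Single LSTM layer over (N, T, D) -> (N, T, H); gates ordered i,f,g,o."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(d_in + hidden)
        self.wx = rng.uniform(-scale, scale, (d_in, 4 * hidden)).astype(np.float32)
        self.wh = rng.uniform(-scale, scale, (hidden, 4 * hidden)).astype(np.float32)
        self.b = np.zeros(4 * hidden, dtype=np.float32)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)
        self.h = hidden

    def params(self):
        return [(self.wx, self.dwx), (self.wh, self.dwh), (self.b, self.db)]

    def forward(self, x, train=True):
        n, t, _ = x.shape
        hdim = self.h
        h = np.zeros((n, hdim), dtype=np.float32)
        c = np.zeros((n, hdim), dtype=np.float32)
        hs = np.empty((n, t, hdim), dtype=np.float32)
        self._cache = []
        self._x = x
        for step in range(t):
            z = x[:, step] @ self.wx + h @ self.wh + self.b
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim:2 * hdim])
            g = np.tanh(z[:, 2 * hdim:3 * hdim])
            o = _sigmoid(z[:, 3 * hdim:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, step] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return hs

    def backward(self, grad):
        x = self._x
        n, t, d = x.shape
        hdim = self.h
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, hdim), dtype=np.float32)
        dc_next = np.zeros((n, hdim), dtype=np.float32)
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[step]
            dh = grad[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.dwx += x[:, step].T @ dz
            self.dwh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
        return dx


class LSTMClassifier:
    """Stacked LSTM -> dropout -> linear head on the final hidden state."""

    def __init__(self, d_in: int, n_classes: int, hidden: int = 128,
                 n_layers: int = 3, dropout: float = 0.3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers = [LSTMLayer(d_in if i == 0 else hidden, hidden, rng)
                       for i in range(n_layers)]
        self.fc = Linear(hidden, n_classes, rng)
        self.dropout = dropout
        self._rng = rng

    def params(self):
        return [p for l in self.layers for p in l.params()] + self.fc.params()

    def forward(self, x, train=True):
        self._masks = []
        h = x.astype(np.float32)
        for li, layer in enumerate(self.layers):
            h = layer.forward(h, train)
            if train and self.dropout > 0 and li < len(self.layers) - 1:
                mask = (self._rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * mask
                self._masks.append(mask)
            else:
                self._masks.append(None)
        self._last_h = h
        return self.fc.forward(h[:, -1], train)

    def backward(self, dlogits):
        dlast = self.fc.backward(dlogits)
        grad = np.zeros_like(self._last_h)
        grad[:, -1] = dlast
        for li in range(len(self.layers) - 1, -1, -1):
            if self._masks[li] is not None:
                grad = grad * self._masks[li]
            grad = self.layers[li].backward(grad)
        return grad

    def predict(self, x, batch: int = 512):
        out = []
        for i in range(0, len(x), batch):
            out.append(self.forward(x[i:i + batch], train=False).argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)
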