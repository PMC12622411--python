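"""Optimizers operating on shared (param, grad) buffer pairs."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam"]


class SGD:
    """Stochastic gradient descent with momentum and L2 weight penalty."""

    def __init__(self, params, lr: float = 0.001, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p, _ in self.params]

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0

    def step(self):
        for (p, g), v in zip(self.params, self.velocity):
            upd = g + self.weight_decay * p
            v *= self.momentum
            v += upd
            p -= self.lr * v


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            grad = g + self.weight_decay * p
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
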