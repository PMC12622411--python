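"""Model architectures: reduced residual classifier and Siamese encoder.

``SmallResNet`` is a desk-scale residual classifier (stem conv + four
residual blocks by default + global average pooling + linear head); the
block plan is configurable up to deeper variants. Separating ``features``
from ``head`` keeps the last convolutional activation addressable, which is
what Grad-CAM differentiates against.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d, Conv2d, GlobalAvgPool, Linear, ReLU, ResidualBlock, Sequential,
)

__all__ = ["SmallResNet", "SiameseEncoder"]

#: channel/stride plan of the default 4-block backbone (input 1 channel).
#: The final block keeps stride 1 so the last conv activation retains enough
#: spatial resolution for gradient-weighted saliency maps.
_DEFAULT_PLAN = ((8, 8, 1), (8, 16, 2), (16, 32, 2), (32, 32, 1))


class SmallResNet:
    """Residual image classifier with an addressable last conv activation."""

    def __init__(self, n_classes: int = 5, stem_channels: int = 8,
                 plan=_DEFAULT_PLAN, stem_stride: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        blocks = [ResidualBlock(cin, cout, s, rng) for cin, cout, s in plan]
        self.features = Sequential(
            Conv2d(1, stem_channels, 3, stem_stride, rng), BatchNorm2d(stem_channels), ReLU(),
            *blocks)
        self.pool = GlobalAvgPool()
        self.fc = Linear(plan[-1][1], n_classes, rng)
        self.n_classes = n_classes

    def params(self):
        return self.features.params() + self.pool.params() + self.fc.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, 1, H, W) float32 -> logits (N, n_classes).

        The last conv activation is cached on ``self.last_conv`` for
        saliency analyses.
        """
        a = self.features.forward(x, train)
        self.last_conv = a
        return self.fc.forward(self.pool.forward(a, train), train)

    def backward(self, dlogits: np.ndarray, through_features: bool = True):
        """Backpropagate; returns (grad at last conv, grad at input or None)."""
        g = self.pool.backward(self.fc.backward(dlogits))
        self.last_conv_grad = g
        if through_features:
            return g, self.features.backward(g)
        return g, None

    def predict(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch):
            out.append(self.forward(x[i:i + batch], train=False).argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


class SiameseEncoder:
    """Shared-weight twin encoder mapping images to an embedding space.

    The two branch passes are realized as one batched pass through the same
    layers, which is exactly weight sharing. ``embed`` returns L2-unnormalized
    embeddings; pair distances are plain Euclidean.
    """

    def __init__(self, embed_dim: int = 16, stem_channels: int = 8,
                 plan=_DEFAULT_PLAN, stem_stride: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        blocks = [ResidualBlock(cin, cout, s, rng) for cin, cout, s in plan]
        self.features = Sequential(
            Conv2d(1, stem_channels, 3, stem_stride, rng), BatchNorm2d(stem_channels), ReLU(),
            *blocks)
        self.pool = GlobalAvgPool()
        self.fc = Linear(plan[-1][1], embed_dim, rng)
        self.embed_dim = embed_dim

    def params(self):
        return self.features.params() + self.fc.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        a = self.features.forward(x, train)
        self.last_conv = a
        return self.fc.forward(self.pool.forward(a, train), train)

    def backward(self, dembed: np.ndarray, through_features: bool = True):
        g = self.pool.backward(self.fc.backward(dembed))
        self.last_conv_grad = g
        if through_features:
            return g, self.features.backward(g)
        return g, None

    def embed(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch):
            out.append(self.forward(x[i:i + batch], train=False))
        return np.vstack(out)


def save_checkpoint(path, model) -> None:
    """Persist model parameters (and batch-norm running stats) as .npz."""
    arrays = {}
    for i, (p, _) in enumerate(model.params()):
        arrays[f"p{i}"] = p
    j = 0
    def walk(obj):
        nonlocal j
        from .layers import BatchNorm2d, Sequential, ResidualBlock
        if isinstance(obj, BatchNorm2d):
            arrays[f"bn{j}_mean"] = obj.run_mean
            arrays[f"bn{j}_var"] = obj.run_var
            j += 1
        elif isinstance(obj, Sequential):
            for l in obj.layers:
                walk(l)
        elif isinstance(obj, ResidualBlock):
            for l in (obj.conv1, obj.bn1, obj.conv2, obj.bn2):
                walk(l)
            if obj.proj is not None:
                walk(obj.proj)
                walk(obj.bn_proj)
    for attr in ("features", "pool", "fc"):
        if hasattr(model, attr):
            walk(getattr(model, attr))
    np.savez(path, **arrays)


def load_checkpoint(path, model) -> None:
    """Load parameters saved by :func:`save_checkpoint` into ``model`` in place."""
    data = np.load(path)
    for i, (p, _) in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    j = 0
    def walk(obj):
        nonlocal j
        from .layers import BatchNorm2d, Sequential, ResidualBlock
        if isinstance(obj, BatchNorm2d):
            obj.run_mean = data[f"bn{j}_mean"]
            obj.run_var = data[f"bn{j}_var"]
            j += 1
        elif isinstance(obj, Sequential):
            for l in obj.layers:
                walk(l)
        elif isinstance(obj, ResidualBlock):
            for l in (obj.conv1, obj.bn1, obj.conv2, obj.bn2):
                walk(l)
            if obj.proj is not None:
                walk(obj.proj)
                walk(obj.bn_proj)
    for attr in ("features", "pool", "fc"):
        if hasattr(model, attr):
            walk(getattr(model, attr))
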