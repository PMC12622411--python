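"""Gradient-weighted class activation maps for the classifier and the twin encoder.

Class Grad-CAM: channel importance = spatially averaged gradient of the
target-class logit at the last convolutional layer; the map is the rectified
importance-weighted sum of activations, upsampled to the input and
normalized to [0, 1].

Similarity Grad-CAM: the scalar backpropagated through each branch is the
*negative* embedding distance for same-valence pairs (what makes the images
alike) and the *positive* distance for different-valence pairs (what drives
them apart).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from ..nn import SiameseEncoder, SmallResNet

__all__ = ["SaliencyMap", "gradcam", "similarity_gradcam"]


@dataclass
class SaliencyMap:
    values: np.ndarray  # (H, W) in [0, 1]
    target: str
    flagged: bool = False  # zero-gradient degenerate case


def _cam_from(acts: np.ndarray, grads: np.ndarray, out_shape) -> tuple[np.ndarray, bool]:
    weights = grads.mean(axis=(1, 2))  # (C,)
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    top = cam.max()
    if top == 0.0:
        return np.zeros(out_shape), True
    cam = cam / top
    return resize(cam, out_shape, order=1, anti_aliasing=False), False


def gradcam(model: SmallResNet, image: np.ndarray, target: int) -> SaliencyMap:
    """Class-discriminative saliency map for one image."""
    if not 0 <= target < model.n_classes:
        raise ValueError(f"target class {target} out of range")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    logits = model.forward(x, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target] = 1.0
    model.backward(dlogits, through_features=False)
    cam, flagged = _cam_from(model.last_conv[0], model.last_conv_grad[0], x.shape[-2:])
    return SaliencyMap(values=cam, target=str(target), flagged=flagged)


def similarity_gradcam(model: SiameseEncoder, image1: np.ndarray, image2: np.ndarray,
                       pair_label: int) -> tuple[SaliencyMap, SaliencyMap]:
    """Per-branch saliency for a pair; ``pair_label`` 1 = same valence.

    Identical images (d = 0) yield flagged zero maps — the distance has no
    gradient direction there.
    """
    x = np.stack([np.asarray(image1, dtype=np.float32).squeeze(),
                  np.asarray(image2, dtype=np.float32).squeeze()])[:, None]
    emb = model.forward(x, train=False)
    e1, e2 = emb[0], emb[1]
    d = float(np.linalg.norm(e1 - e2))
    shape = x.shape[-2:]
    if d == 0.0:
        z = np.zeros(shape)
        return (SaliencyMap(z, "similarity", True), SaliencyMap(z, "similarity", True))
    sign = -1.0 if pair_label == 1 else 1.0
    # d(target)/de1 = sign * (e1 - e2)/d ; branch 2 gets the mirror image
    de1 = sign * (e1 - e2) / d
    model.backward(np.stack([de1, -de1]), through_features=False)
    cam1, f1 = _cam_from(model.last_conv[0], model.last_conv_grad[0], shape)
    cam2, f2 = _cam_from(model.last_conv[1], model.last_conv_grad[1], shape)
    tgt = "similarity" if pair_label == 1 else "dissimilarity"
    return SaliencyMap(cam1, tgt, f1), SaliencyMap(cam2, tgt, f2)
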