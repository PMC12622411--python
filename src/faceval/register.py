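"""Landmark-based coregistration of face frames across mice.

Six manually identified landmarks (nose tip, inner/outer eye corners,
anterior lower-lip edge, cheek, posterior pinna edge) anchor each session to
a template mouse: a least-squares affine fit gives the initial alignment,
refined by a restricted similarity transform (translation + rotation +
uniform scale). Frames are warped by inverse mapping with bilinear
interpolation; a red/cyan overlay provides the alignment QC image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet",
    "PlanarTransform",
    "fit_affine",
    "refine_similarity",
    "apply_transform",
    "transform_points",
    "alignment_overlay",
]

LANDMARK_NAMES = (
    "nose_tip",
    "inner_eye_corner",
    "outer_eye_corner",
    "lower_lip_anterior",
    "cheek",
    "pinna_posterior_edge",
)


@dataclass(frozen=True)
class LandmarkSet:
    """Six named 2-D points in image coordinates."""

    points: np.ndarray  # (6, 2), ordered as LANDMARK_NAMES

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (6, 2):
            raise ValueError("expected six 2-D landmarks")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmarks must be finite")
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() == 0.0:
            raise ValueError("two landmarks coincide")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_keypoints(cls, kp: np.ndarray, names: list[str]) -> "LandmarkSet":
        """Extract the six landmarks from a 37-keypoint frame.

        The cheek has no dedicated keypoint; the mouth corner stands in for
        it (it sits on the cheek margin of the schematic face).
        """
        idx = {n: i for i, n in enumerate(names)}
        mapping = {
            "nose_tip": "nose_tip",
            "inner_eye_corner": "eye_inner_corner",
            "outer_eye_corner": "eye_outer_corner",
            "lower_lip_anterior": "lower_lip_anterior",
            "cheek": "mouth_corner",
            "pinna_posterior_edge": "pinna_posterior_edge",
        }
        return cls(np.array([kp[idx[mapping[n]]] for n in LANDMARK_NAMES], dtype=float))


@dataclass(frozen=True)
class PlanarTransform:
    """2x3 affine matrix mapping source -> destination coordinates."""

    matrix: np.ndarray  # (2, 3)
    warning: str | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("expected a 2x3 affine matrix")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("linear part is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def decompose(self) -> dict:
        """Translation, rotation (deg) and scale of the closest similarity."""
        a = self.linear
        u, s, vt = np.linalg.svd(a)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        angle = np.degrees(np.arctan2(r[1, 0], r[0, 0]))
        return {"translation": self.translation.copy(), "rotation_deg": float(angle),
                "scale": float(s.mean())}

    def inverse(self) -> "PlanarTransform":
        a_inv = np.linalg.inv(self.linear)
        return PlanarTransform(np.hstack([a_inv, (-a_inv @ self.translation)[:, None]]))

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """Return self o other (apply ``other`` first)."""
        a = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return PlanarTransform(np.hstack([a, t[:, None]]))

    @classmethod
    def identity(cls) -> "PlanarTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


def transform_points(points: np.ndarray, t: PlanarTransform) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return pts @ t.linear.T + t.translation


def fit_affine(src: LandmarkSet, dst: LandmarkSet) -> tuple[PlanarTransform, np.ndarray]:
    """Least-squares affine minimizing sum ||T(src_i) - dst_i||^2.

    Returns the transform and the (6, 2) residual vectors. Collinear source
    landmarks make the normal equations rank-deficient and raise.
    """
    s, d = src.points, dst.points
    design = np.hstack([s, np.ones((6, 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise np.linalg.LinAlgError("source landmarks are collinear; affine fit is rank-deficient")
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)
    t = PlanarTransform(np.hstack([coef[:2].T, coef[2][:, None]]))
    residuals = transform_points(s, t) - d
    return t, residuals


def refine_similarity(src: LandmarkSet, dst: LandmarkSet,
                      init: PlanarTransform | None = None) -> PlanarTransform:
    """Restricted similarity transform (translation, rotation, uniform scale).

    Solved in closed form (orthogonal-Procrustes with scaling), which is the
    global least-squares optimum, so the objective can never exceed that of
    the restriction of ``init``. ``init`` is accepted for interface
    compatibility with the affine pre-alignment stage.
    """
    s, d = src.points, dst.points
    sc, dc = s.mean(axis=0), d.mean(axis=0)
    s0, d0 = s - sc, d - dc
    cov = d0.T @ s0
    u, sig, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, sign])
    r = u @ corr @ vt
    denom = (s0 ** 2).sum()
    if denom == 0:
        raise ValueError("degenerate source landmarks")
    scale = (sig * np.diag(corr)).sum() / denom
    a = scale * r
    t = dc - a @ sc
    return PlanarTransform(np.hstack([a, t[:, None]]))


def apply_transform(frames: np.ndarray, t: PlanarTransform,
                    out_canvas: tuple[int, int] | None = None,
                    order: int = 1) -> np.ndarray:
    """Warp frames into the template space of ``t`` (src -> dst mapping).

    Inverse mapping with bilinear interpolation (``order=1``); out-of-bounds
    pixels are filled with the frame median. Accepts (H, W) or (T, H, W).
    """
    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 2
    stack = frames[None] if single else frames
    shape = out_canvas if out_canvas is not None else stack.shape[1:]
    # skimage transforms operate on (x, y) = (col, row) coordinates.
    m = np.eye(3)
    m[:2, :2] = t.linear
    m[:2, 2] = t.translation
    tf = AffineTransform(matrix=m)
    out = np.empty((stack.shape[0],) + tuple(shape), dtype=float)
    for i, frame in enumerate(stack):
        out[i] = warp(frame, tf.inverse, output_shape=shape, order=order,
                      mode="constant", cval=float(np.median(frame)),
                      preserve_range=True)
    return out[0] if single else out


def alignment_overlay(unaligned: np.ndarray, aligned: np.ndarray) -> np.ndarray:
    """RGB QC image: red = unaligned, green = blue = aligned.

    Gray pixels mean overlap; red/cyan fringes localize misalignment.
    """
    u = np.asarray(unaligned, dtype=float)
    a = np.asarray(aligned, dtype=float)
    if u.shape != a.shape:
        raise ValueError("frames must share a canvas")
    rgb = np.stack([u, a, a], axis=-1)
    return np.clip(rgb, 0.0, 1.0)
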