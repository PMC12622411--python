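"""Vector-schematic rendering of a side-view mouse face with keypoint ground truth.

The face is drawn from geometric primitives (head ellipse, ear quadrilateral,
whisker polylines, mouth/nose line work, eye + pupil) whose construction
points double as the 37 tracked keypoints, so angle/distance oracles applied
to the returned keypoints recover the generating phenotype exactly. The
schematic look is deliberate: HOG descriptors, keypoint geometry and saliency
maps depend on edges and configuration, not photorealism.

Construction happens in a y-up mathematical frame; keypoints are returned in
image coordinates (x right, y down), the convention of pose-estimation
exports.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk, ellipse, line_aa, polygon

from .phenotype import FacePhenotype

__all__ = ["RenderError", "render_face", "KEYPOINT_NAMES", "KEYPOINT_REGIONS", "REGION_COUNTS"]


class RenderError(ValueError):
    """Raised when a phenotype cannot be drawn inside the canvas."""


#: Keypoints per facial region (sums to 37).
REGION_COUNTS = {"pupil": 8, "eye": 4, "ear": 5, "nose": 5, "mouth": 3, "whisker": 12}

_PUPIL = ["pupil_top", "pupil_right", "pupil_bottom", "pupil_left",
          "pupil_topright", "pupil_bottomright", "pupil_bottomleft", "pupil_topleft"]
_EYE = ["eye_inner_corner", "eye_outer_corner", "eye_top", "eye_bottom"]
_EAR = ["ear_root", "pinna_posterior_edge", "mid_ear_a", "mid_ear_b", "pinna_anterior_edge"]
_NOSE = ["nose_tip", "nose_bridge", "nostril_left", "nostril_right", "nostril_bottom"]
_MOUTH = ["lower_lip_anterior", "mouth_center", "mouth_corner"]
_WHISK = [f"whisker{w}_{i}" for w in (1, 2, 3) for i in range(4)]

#: Canonical keypoint order: pupil, eye, ear, nose, mouth, whiskers.
KEYPOINT_NAMES = _PUPIL + _EYE + _EAR + _NOSE + _MOUTH + _WHISK

#: name -> region lookup.
KEYPOINT_REGIONS = (
    {n: "pupil" for n in _PUPIL} | {n: "eye" for n in _EYE} | {n: "ear" for n in _EAR}
    | {n: "nose" for n in _NOSE} | {n: "mouth" for n in _MOUTH} | {n: "whisker" for n in _WHISK}
)

assert len(KEYPOINT_NAMES) == sum(REGION_COUNTS.values()) == 37


def _rot(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise RenderError("degenerate zero-length construction vector")
    return v / n


def _construct_keypoints(p: FacePhenotype, s: float) -> dict[str, np.ndarray]:
    """Place all 37 keypoints in the y-up frame at canvas scale ``s``."""
    pts: dict[str, np.ndarray] = {}

    eye_c = np.array([143.0, 141.0]) * s
    # Pupil: 4 cardinal then 4 diagonal points on a circle of the given diameter.
    r = p.pupil_diameter / 2.0
    for name, ang in zip(_PUPIL, (90, 0, -90, 180, 45, -45, -135, 135)):
        pts[name] = eye_c + r * np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
    # Eyelid: vertical extent = eye_opening; horizontal extent proportional.
    pts["eye_inner_corner"] = eye_c + np.array([-0.8 * p.eye_opening, 0.0])
    pts["eye_outer_corner"] = eye_c + np.array([0.8 * p.eye_opening, 0.0])
    pts["eye_top"] = eye_c + np.array([0.0, p.eye_opening / 2.0])
    pts["eye_bottom"] = eye_c - np.array([0.0, p.eye_opening / 2.0])

    # Ear: pinna vector from the root at ear_angle to the +x axis; the fold
    # point (mid_ear_a) makes the ear_fold interior angle at the posterior
    # edge; the two mid-ear points are ear_width apart.
    root = np.array([172.0, 158.0]) * s
    u = np.array([np.cos(np.deg2rad(p.ear_angle)), np.sin(np.deg2rad(p.ear_angle))])
    post = root + p.ear_length * u
    u_back = _unit(root - post)
    a = post + 0.5 * p.ear_length * (_rot(p.ear_fold) @ u_back)
    n_perp = _rot(90.0) @ _unit(a - post)
    b = a + p.ear_width * n_perp
    pts["ear_root"] = root
    pts["pinna_posterior_edge"] = post
    pts["mid_ear_a"] = a
    pts["mid_ear_b"] = b
    pts["pinna_anterior_edge"] = root + 0.55 * p.ear_length * (_rot(35.0) @ u)

    # Nostril triangle is anchored to the snout (fixed); the lower lip sits on
    # the ray from the inner eye corner rotated mouth_inclination degrees from
    # the nostril ray, and the nose tip sits snout_mouth_length from the lip.
    nostril_c = np.array([50.0, 106.0]) * s
    pts["nostril_left"] = nostril_c + np.array([-4.0, 2.0]) * s
    pts["nostril_right"] = nostril_c + np.array([4.0, 2.0]) * s
    pts["nostril_bottom"] = nostril_c + np.array([0.0, -4.0]) * s

    e_in = pts["eye_inner_corner"]
    d_lip = _rot(p.mouth_inclination) @ _unit(pts["nostril_bottom"] - e_in)
    lip = e_in + 89.0 * s * d_lip
    pts["lower_lip_anterior"] = lip
    pts["mouth_center"] = lip + np.array([14.0, 2.0]) * s
    pts["mouth_corner"] = lip + np.array([26.0, 6.0]) * s

    u_snout = _unit(np.array([-0.625, 0.781]))
    tip = lip + p.snout_mouth_length * u_snout
    pts["nose_tip"] = tip
    u_nose = np.array([np.cos(np.deg2rad(52.0)), np.sin(np.deg2rad(52.0))])
    pts["nose_bridge"] = tip + p.nose_extension * u_nose

    # Three whiskers of four points each, angled from the -x axis
    # (protraction = smaller angle); y-up, so positive angles droop downward.
    d_w = np.array([-np.cos(np.deg2rad(p.whisker_angle)),
                    -np.sin(np.deg2rad(p.whisker_angle))])
    w_len = 55.0 * s
    for w, base in zip((1, 2, 3), (np.array([88.0, 118.0]), np.array([84.0, 106.0]),
                                   np.array([88.0, 94.0]))):
        b0 = base * s
        for i in range(4):
            pts[f"whisker{w}_{i}"] = b0 + (i / 3.0) * w_len * d_w
    return pts


def _draw(img, rr, cc, value, alpha=None):
    h, w = img.shape
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    if alpha is None:
        img[rr[ok], cc[ok]] = value
    else:
        a = alpha[ok]
        img[rr[ok], cc[ok]] = (1 - a) * img[rr[ok], cc[ok]] + a * value


def _poly(img, pts_yup, value, canvas):
    arr = np.asarray(pts_yup, dtype=float)
    rr, cc = polygon((canvas - 1) - arr[:, 1], arr[:, 0], shape=img.shape)
    img[rr, cc] = value


def _segment(img, p0, p1, value, canvas):
    r0, c0 = int(round((canvas - 1) - p0[1])), int(round(p0[0]))
    r1, c1 = int(round((canvas - 1) - p1[1])), int(round(p1[0]))
    rr, cc, aa = line_aa(r0, c0, r1, c1)
    _draw(img, rr, cc, value, aa)


def render_face(phenotype: FacePhenotype, canvas: int = 256):
    """Render one schematic face.

    Parameters
    ----------
    phenotype
        Geometry of the face, in pixels/degrees at this canvas size (use
        :meth:`FacePhenotype.scaled` when changing canvas).
    canvas
        Side length of the square grayscale canvas, >= 128.

    Returns
    -------
    image : (canvas, canvas) float32 array in [0, 1].
    keypoints : (37, 2) float array of (x, y) image coordinates (y down),
        ordered as :data:`KEYPOINT_NAMES`.

    Raises
    ------
    RenderError
        If any keypoint would fall outside the canvas.
    """
    if canvas < 128:
        raise ValueError("canvas must be >= 128 px")
    phenotype.validate()
    s = canvas / 256.0
    pts = _construct_keypoints(phenotype, s)

    margin = 2.0
    for name, xy in pts.items():
        if not (margin <= xy[0] <= canvas - 1 - margin and margin <= xy[1] <= canvas - 1 - margin):
            raise RenderError(
                f"keypoint {name} at ({xy[0]:.1f}, {xy[1]:.1f}) falls outside the "
                f"{canvas}-px canvas; phenotype not renderable"
            )

    img = np.full((canvas, canvas), 0.08, dtype=np.float32)

    # Head and snout.
    rr, cc = ellipse((canvas - 1) - 105.0 * s, 150.0 * s, 66.0 * s, 86.0 * s, shape=img.shape)
    img[rr, cc] = 0.52
    tip = pts["nose_tip"]
    _poly(img, [tip, np.array([100.0, 142.0]) * s, np.array([100.0, 72.0]) * s], 0.52, canvas)

    # Ear: filled outer pinna with a darker inner fold.
    quad = [pts["ear_root"], pts["pinna_anterior_edge"], pts["pinna_posterior_edge"],
            pts["mid_ear_b"]]
    _poly(img, quad, 0.60, canvas)
    _poly(img, [pts["ear_root"], pts["pinna_posterior_edge"], pts["mid_ear_a"]], 0.33, canvas)

    # Whiskers (bright), mouth and nose line work (dark).
    for w in (1, 2, 3):
        for i in range(3):
            _segment(img, pts[f"whisker{w}_{i}"], pts[f"whisker{w}_{i + 1}"], 0.92, canvas)
    _segment(img, pts["lower_lip_anterior"], pts["mouth_center"], 0.12, canvas)
    _segment(img, pts["mouth_center"], pts["mouth_corner"], 0.12, canvas)
    _segment(img, pts["nose_tip"], pts["nose_bridge"], 0.30, canvas)
    _poly(img, [pts["nostril_left"], pts["nostril_right"], pts["nostril_bottom"]], 0.15, canvas)

    # Eye: bright sclera ellipse, dark pupil disk.
    eye_c = 0.5 * (pts["eye_inner_corner"] + pts["eye_outer_corner"])
    rr, cc = ellipse((canvas - 1) - eye_c[1], eye_c[0],
                     phenotype.eye_opening / 2.0, 0.8 * phenotype.eye_opening, shape=img.shape)
    img[rr, cc] = 0.80
    rr, cc = disk(((canvas - 1) - eye_c[1], eye_c[0]), phenotype.pupil_diameter / 2.0,
                  shape=img.shape)
    img[rr, cc] = 0.05

    kp = np.array([[pts[n][0], (canvas - 1) - pts[n][1]] for n in KEYPOINT_NAMES])
    return img, kp
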