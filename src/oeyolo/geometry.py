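"""Oriented-box algebra, Gaussian conversion, ProbIoU, polygon IoU and rotated NMS.

An oriented bounding box (OBB) is a rotated rectangle ``(cx, cy, w, h, theta)``
in image coordinates (origin top-left, x right, y down, theta in radians
measured from the +x axis toward +y).  The canonical form keeps ``w >= h`` and
``theta in [-pi/2, pi/2)``; every rectangle has exactly one canonical
parameterization, which makes equality and regression targets well defined for
slender objects such as rice panicles.

The probabilistic overlap measure used as detection loss replaces a box by the
2-D Gaussian with the rectangle's uniform-density second moments,

    mu = (cx, cy),   Sigma = R(theta) diag(w^2/12, h^2/12) R(theta)^T,

and scores a pair of boxes by one minus the Hellinger distance between their
Gaussians,

    ProbIoU(a, b) = 1 - sqrt(1 - BC(p, q)),

where BC is the Bhattacharyya coefficient, available in closed form for
Gaussians.  Unlike the area IoU, this is smooth in all five box parameters and
stays informative for non-overlapping boxes, which is what makes it usable as
a regression loss for arbitrarily oriented targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

__all__ = [
    "OrientedBox",
    "Gaussian2D",
    "Detection",
    "InvalidBoxError",
    "InvalidQuadError",
    "canonicalize_box",
    "box_to_vertices",
    "vertices_to_box",
    "min_area_rect",
    "box_to_gaussian",
    "bhattacharyya_coefficient",
    "prob_iou",
    "polygon_iou",
    "polygon_area",
    "clip_polygon",
    "rotated_nms",
]


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive side lengths."""


class InvalidQuadError(ValueError):
    """Raised for degenerate (collinear) quadrilaterals."""


@dataclass(frozen=True)
class OrientedBox:
    """A rotated rectangle: center (cx, cy), sides (w, h), angle theta [rad]."""

    cx: float
    cy: float
    w: float
    h: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box sides must be positive, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def canonical(self) -> "OrientedBox":
        return canonicalize_box(self)

    def vertices(self) -> np.ndarray:
        return box_to_vertices(self)

    def translated(self, dx: float, dy: float) -> "OrientedBox":
        return OrientedBox(self.cx + dx, self.cy + dy, self.w, self.h, self.theta)


@dataclass(frozen=True)
class Gaussian2D:
    """2-D Gaussian surrogate of a box: mean (pixels), covariance (pixels^2)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float).reshape(2)
        sigma = np.asarray(self.sigma, dtype=float).reshape(2, 2)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class Detection:
    """A scored oriented-box prediction."""

    box: OrientedBox
    score: float
    class_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


def canonicalize_box(box: OrientedBox) -> OrientedBox:
    """Return the canonical representation (w >= h, theta in [-pi/2, pi/2)).

    Swapping the two side lengths corresponds to a pi/2 rotation; rectangles
    are invariant under rotations by pi, so theta is wrapped modulo pi.
    """
    w, h, theta = box.w, box.h, box.theta
    if w < h:
        w, h = h, w
        theta += math.pi / 2.0
    theta = (theta + math.pi / 2.0) % math.pi - math.pi / 2.0
    return OrientedBox(box.cx, box.cy, w, h, theta)


def _rotation(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def box_to_vertices(box: OrientedBox) -> np.ndarray:
    """Corners of the box as a (4, 2) array.

    Winding starts at the rotated image of the (-w/2, -h/2) corner and
    proceeds consistently; for theta = 0 the order is top-left, top-right,
    bottom-right, bottom-left in image coordinates.
    """
    half = np.array(
        [
            [-box.w / 2.0, -box.h / 2.0],
            [box.w / 2.0, -box.h / 2.0],
            [box.w / 2.0, box.h / 2.0],
            [-box.w / 2.0, box.h / 2.0],
        ]
    )
    return half @ _rotation(box.theta).T + np.array([box.cx, box.cy])


def min_area_rect(points: Sequence[Sequence[float]]) -> OrientedBox:
    """Minimum-area enclosing rotated rectangle of a point set.

    Delegates to shapely's oriented envelope (rotating calipers over the
    convex hull).  Degenerate inputs whose hull has no area raise
    :class:`InvalidQuadError`.
    """
    import shapely

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InvalidQuadError("need at least three 2-D points")
    env = shapely.oriented_envelope(shapely.multipoints(pts))
    if env.geom_type != "Polygon" or env.area <= 0:
        raise InvalidQuadError("points are collinear; no enclosing rectangle exists")
    corners = np.asarray(env.exterior.coords)[:4]
    cx, cy = corners.mean(axis=0)
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    w = float(np.hypot(*e1))
    h = float(np.hypot(*e2))
    theta = math.atan2(e1[1], e1[0])
    return canonicalize_box(OrientedBox(float(cx), float(cy), w, h, theta))


def vertices_to_box(quad: Sequence[Sequence[float]]) -> OrientedBox:
    """Fit an OrientedBox to four vertices.

    For (near-)rectangular input this inverts :func:`box_to_vertices`; for a
    general convex quadrilateral it returns the minimum-area enclosing rotated
    rectangle.  Collinear vertices raise :class:`InvalidQuadError`.
    """
    pts = np.asarray(quad, dtype=float).reshape(4, 2)
    e1 = pts[1] - pts[0]
    e2 = pts[2] - pts[1]
    e3 = pts[2] - pts[3]
    e4 = pts[3] - pts[0]
    l1, l2, l3, l4 = (float(np.hypot(*e)) for e in (e1, e2, e3, e4))
    if min(l1, l2, l3, l4) == 0.0:
        raise InvalidQuadError("repeated vertex")
    # opposite sides equal within 1% -> treat as a rectangle directly
    if abs(l1 - l3) <= 0.01 * max(l1, l3) and abs(l2 - l4) <= 0.01 * max(l2, l4):
        cross = e1[0] * e2[1] - e1[1] * e2[0]
        if abs(cross) < 1e-12 * max(l1, l2) ** 2:
            raise InvalidQuadError("collinear vertices")
        cx, cy = pts.mean(axis=0)
        theta = math.atan2(e1[1], e1[0])
        w = (l1 + l3) / 2.0
        h = (l2 + l4) / 2.0
        return canonicalize_box(OrientedBox(float(cx), float(cy), w, h, theta))
    return min_area_rect(pts)


def box_to_gaussian(box: OrientedBox) -> Gaussian2D:
    """Gaussian surrogate: mean at the center, covariance from the uniform
    rectangle's second moments rotated by theta.

    det(Sigma) = (w^2/12)(h^2/12) independent of theta.
    """
    a = box.w * box.w / 12.0
    b = box.h * box.h / 12.0
    c, s = math.cos(box.theta), math.sin(box.theta)
    sigma = np.array(
        [
            [a * c * c + b * s * s, (a - b) * c * s],
            [(a - b) * c * s, a * s * s + b * c * c],
        ]
    )
    return Gaussian2D(np.array([box.cx, box.cy]), sigma)


def bhattacharyya_coefficient(g1: Gaussian2D, g2: Gaussian2D) -> float:
    """Closed-form Bhattacharyya coefficient BC = ∫ sqrt(p q) dx of two
    Gaussians.

    BC = exp(-B_D) with the Bhattacharyya distance
    B_D = 1/8 (mu1-mu2)^T S^-1 (mu1-mu2) + 1/2 ln(det S / sqrt(det S1 det S2)),
    S = (S1 + S2)/2.  Equals 1 iff the distributions coincide.
    """
    s1, s2 = g1.sigma, g2.sigma
    sbar = 0.5 * (s1 + s2)
    det1 = s1[0, 0] * s1[1, 1] - s1[0, 1] * s1[1, 0]
    det2 = s2[0, 0] * s2[1, 1] - s2[0, 1] * s2[1, 0]
    detbar = sbar[0, 0] * sbar[1, 1] - sbar[0, 1] * sbar[1, 0]
    if detbar <= 0 or det1 <= 0 or det2 <= 0:
        raise np.linalg.LinAlgError("degenerate covariance in Bhattacharyya coefficient")
    d = g1.mu - g2.mu
    # 2x2 inverse applied to d, written out to avoid a solve() call
    inv_d = np.array(
        [sbar[1, 1] * d[0] - sbar[0, 1] * d[1], -sbar[1, 0] * d[0] + sbar[0, 0] * d[1]]
    ) / detbar
    b_d = 0.125 * float(d @ inv_d) + 0.5 * math.log(detbar / math.sqrt(det1 * det2))
    return float(math.exp(-b_d))


def prob_iou(a: OrientedBox, b: OrientedBox, hellinger_sqrt: bool = True) -> float:
    """Probabilistic IoU of two oriented boxes via their Gaussian surrogates.

    ``ProbIoU = 1 - HD`` with the Hellinger distance ``HD = sqrt(1 - BC)``.
    ``hellinger_sqrt=False`` drops the radical (``HD = 1 - BC``), an
    alternative sometimes written in the OBB-detection literature; the square
    root form keeps HD a metric and is the default.
    """
    bc = bhattacharyya_coefficient(box_to_gaussian(a), box_to_gaussian(b))
    bc = min(max(bc, 0.0), 1.0)
    hd = math.sqrt(1.0 - bc) if hellinger_sqrt else 1.0 - bc
    return float(min(max(1.0 - hd, 0.0), 1.0))


def polygon_area(poly: np.ndarray) -> float:
    """Unsigned shoelace area of a polygon given as an (n, 2) vertex array."""
    p = np.asarray(poly, dtype=float)
    if len(p) < 3:
        return 0.0
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def clip_polygon(subject: np.ndarray, clip: np.ndarray) -> np.ndarray:
    """Sutherland–Hodgman clipping of polygon ``subject`` by convex ``clip``.

    Returns the (possibly empty) intersection polygon.  ``clip`` may wind
    either way; the inside half-plane is chosen per polygon orientation.
    """
    clip = np.asarray(clip, dtype=float)
    # signed area > 0 means counter-clockwise in a y-up frame; use it to
    # orient the inside test consistently for either winding
    x, y = clip[:, 0], clip[:, 1]
    signed = 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    sign = 1.0 if signed >= 0 else -1.0

    output = [tuple(p) for p in np.asarray(subject, dtype=float)]
    n = len(clip)
    for i in range(n):
        if not output:
            return np.zeros((0, 2))
        a = clip[i]
        b = clip[(i + 1) % n]
        ex, ey = b[0] - a[0], b[1] - a[1]
        input_pts = output
        output = []
        prev = input_pts[-1]
        prev_side = sign * (ex * (prev[1] - a[1]) - ey * (prev[0] - a[0]))
        for cur in input_pts:
            cur_side = sign * (ex * (cur[1] - a[1]) - ey * (cur[0] - a[0]))
            if cur_side >= 0:
                if prev_side < 0:
                    t = prev_side / (prev_side - cur_side)
                    output.append(
                        (prev[0] + t * (cur[0] - prev[0]), prev[1] + t * (cur[1] - prev[1]))
                    )
                output.append(cur)
            elif prev_side >= 0:
                t = prev_side / (prev_side - cur_side)
                output.append(
                    (prev[0] + t * (cur[0] - prev[0]), prev[1] + t * (cur[1] - prev[1]))
                )
            prev, prev_side = cur, cur_side
    return np.asarray(output) if output else np.zeros((0, 2))


def polygon_iou(a: OrientedBox, b: OrientedBox) -> float:
    """Exact area IoU of two oriented boxes via convex polygon clipping."""
    va, vb = box_to_vertices(a), box_to_vertices(b)
    inter = polygon_area(clip_polygon(va, vb))
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    return float(min(max(inter / union, 0.0), 1.0))


def rotated_nms(dets: Sequence[Detection], iou_threshold: float) -> List[Detection]:
    """Greedy non-maximum suppression with exact rotated-box IoU.

    Detections are visited in descending score order (ties broken by lower
    class id, then original input order); a detection is suppressed when its
    IoU with an already kept detection exceeds the threshold, so every
    surviving pair overlaps by at most the threshold.  Survivors come back
    sorted by descending score.
    """
    order = sorted(
        range(len(dets)), key=lambda i: (-dets[i].score, dets[i].class_id, i)
    )
    # axis-aligned bounds give a cheap certificate of non-overlap before the
    # exact polygon clip
    bounds = np.empty((len(dets), 4))
    for i, d in enumerate(dets):
        v = box_to_vertices(d.box)
        bounds[i] = (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())
    kept: List[int] = []
    for i in order:
        suppressed = False
        for j in kept:
            if (
                bounds[i, 0] > bounds[j, 2]
                or bounds[j, 0] > bounds[i, 2]
                or bounds[i, 1] > bounds[j, 3]
                or bounds[j, 1] > bounds[i, 3]
            ):
                continue
            if polygon_iou(dets[j].box, dets[i].box) > iou_threshold:
                suppressed = True
                break
        if not suppressed:
            kept.append(i)
    return [dets[i] for i in kept]
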