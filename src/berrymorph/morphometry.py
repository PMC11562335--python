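"""Size and shape metrics for a single berry mask.

Implements the caliper-style oriented-bounding-box length/width, mask area
and arc length, convex-hull solidity, ISO roundness (largest inscribed over
smallest enclosing circle), and the solid-of-revolution estimators: volume as
a stack of 1-px-high cylinders and surface area as a stack of 1-px-high
truncated cones, both driven by the per-row width profile of the mask taken
along its major axis. Closed-form prolate-spheroid references are provided to
verify the two estimators.

All metrics are in pixel units; unit conversion lives in layout_calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from .segmentation import extract_contour, polygon_perimeter

logger = logging.getLogger(__name__)

#: Eigenvalue anisotropy below which a mask is treated as isotropic and its
#: orientation pinned to 0 for determinism.
ISOTROPY_EPS = 1e-6


@dataclass
class WidthProfile:
    """Mask widths sampled every pixel step along the major axis.

    ``widths[i]`` is the extent of the mask orthogonal to the major axis at
    unit step ``i``; ``h`` is the total extent along the major axis.
    """

    angle: float
    h: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.h < 1 or len(self.widths) != self.h:
            raise ValueError("profile length must equal h >= 1")
        if (self.widths < 0).any() or not (self.widths > 0).any():
            raise ValueError("widths must be >= 0 with at least one positive")


@dataclass
class ShapeMetrics:
    """All per-berry size/shape measurements (pixel units)."""

    length: float
    width: float
    area: float
    perimeter: float
    surface_area: float
    volume: float
    roundness: float
    solidity: float
    orientation: float = 0.0  # radians, major-axis direction in [0, pi)


@dataclass
class EllipsoidReference:
    """Semi-axes of the prolate spheroid matching a berry's length/width."""

    a: float  # 0.5 * length (semi-major)
    b: float  # 0.5 * width (semi-minor)

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got ({self.a}, {self.b})")


def principal_orientation(mask):
    """Major-axis direction from second central moments, in [0, pi).

    The angle is measured from the +x axis toward the +y axis of the image.
    Near-isotropic masks (relative eigenvalue split below ISOTROPY_EPS)
    return 0 so downstream metrics are deterministic.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size < 5:
        raise ValueError("mask area must be >= 5 px for a stable orientation")
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    split = np.hypot(mu20 - mu02, 2 * mu11)
    if split / (mu20 + mu02) < ISOTROPY_EPS:
        return 0.0
    theta = float(np.mod(0.5 * np.arctan2(2 * mu11, mu20 - mu02), np.pi))
    if np.pi - theta < 1e-3:  # fold directions a hair below pi onto ~0
        theta -= np.pi
    return theta


def _rotate_points(points, angle, origin):
    """Rotate points by ``angle`` (from +x toward +y) about ``origin``."""
    c, s = np.cos(angle), np.sin(angle)
    p = np.asarray(points, dtype=float) - origin
    return p @ np.array([[c, -s], [s, c]]).T


def oriented_bbox(mask, angle, contour=None):
    """Oriented bounding box aligned to the major axis.

    Returns ``(length, width, corners)`` where length is the extent along the
    axis direction, width the orthogonal extent, and corners the four box
    vertices in original image coordinates. If the extent along the given
    axis is smaller than the orthogonal one the two are swapped (and logged)
    so that length >= width always holds.
    """
    if contour is None:
        contour = extract_contour(mask)
    if len(contour) == 0:
        raise ValueError("empty contour")
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    origin = np.array([xs.mean(), ys.mean()])
    rot = _rotate_points(contour, -angle, origin)
    (x0, y0), (x1, y1) = rot.min(axis=0), rot.max(axis=0)
    length, width = x1 - x0, y1 - y0
    if length < width:
        logger.info("moment axis shorter than orthogonal extent "
                    "(%.2f < %.2f); swapping length/width", length, width)
        length, width = width, length
    box = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    c, s = np.cos(angle), np.sin(angle)
    corners = box @ np.array([[c, s], [-s, c]]) + origin
    return float(length), float(width), corners


def mask_area(mask):
    """Foreground pixel count."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return int(mask.sum())


def mask_perimeter(contour):
    """Arc length of the mask: edge-length sum of its contour polygon."""
    return polygon_perimeter(contour)


def solidity(mask, contour=None):
    """Mask area over the area of the convex hull of its contour.

    May exceed 1 by a rasterization tolerance (< ~1%) for convex masks whose
    pixel count slightly outruns the sub-pixel hull area.
    """
    area = mask_area(mask)
    if contour is None:
        contour = extract_contour(mask)
    if len(contour) < 4:
        return 1.0
    hull = ConvexHull(contour[:-1])
    return float(area / hull.volume)  # 2-D "volume" is the polygon area


def _smallest_enclosing_circle(points):
    """Exact minimum enclosing circle (Welzl, move-to-front), deterministic."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) > 16:
        pts = pts[ConvexHull(pts).vertices]
    order = np.random.default_rng(1905).permutation(len(pts))
    pts = [tuple(p) for p in pts[order]]

    def circle_two(p, q):
        cx, cy = (p[0] + q[0]) / 2, (p[1] + q[1]) / 2
        return cx, cy, np.hypot(p[0] - cx, p[1] - cy)

    def circle_three(p, q, r):
        ax, ay = p; bx, by = q; cx, cy = r
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        return ux, uy, np.hypot(ax - ux, ay - uy)

    def inside(c, p, eps=1e-9):
        return c is not None and np.hypot(p[0] - c[0], p[1] - c[1]) <= c[2] + eps

    c = None
    for i, p in enumerate(pts):
        if inside(c, p):
            continue
        c = (p[0], p[1], 0.0)
        for j, q in enumerate(pts[: i + 1]):
            if inside(c, q):
                continue
            c = circle_two(p, q)
            for r in pts[: j + 1]:
                if not inside(c, r):
                    c3 = circle_three(p, q, r)
                    if c3 is not None:
                        c = c3
    return c


def roundness_iso(mask, contour=None):
    """ISO roundness: largest inscribed circle over smallest enclosing circle.

    The inscribed radius is the maximum of the Euclidean distance transform
    (taken to the mask boundary, i.e. half a pixel beyond the outermost
    foreground centers); the enclosing radius comes from the minimum
    enclosing circle of the contour. Clipped to (0, 1].
    """
    mask = np.asarray(mask, dtype=bool)
    if contour is None:
        contour = extract_contour(mask)
    if len(contour) < 4:
        return 1.0
    r_in = float(ndi.distance_transform_edt(np.pad(mask, 1)).max()) - 0.5
    r_enc = _smallest_enclosing_circle(contour[:-1])[2]
    return float(min(r_in / r_enc, 1.0))


def _profile_from_rows(aligned):
    """Per-row orthogonal extents (rightmost - leftmost + 1) of a mask."""
    rows = np.nonzero(aligned.any(axis=1))[0]
    if rows.size == 0:
        raise ValueError("mask is empty")
    widths = []
    for r in range(rows[0], rows[-1] + 1):
        cols = np.nonzero(aligned[r])[0]
        widths.append(float(cols[-1] - cols[0] + 1) if cols.size else 0.0)
    return widths


def _profile_from_contour(contour, angle, origin):
    """Widths from unit-spaced slices of the exactly-rotated contour.

    The contour is rotated by ``-angle`` about the centroid; at every integer
    offset along the rotated x-axis the width is the orthogonal extent of the
    polygon's intersection with that slice line. Rotating the sub-pixel
    polygon is exact, so the profile carries no resampling artifacts.
    """
    p = _rotate_points(contour, -angle, origin)
    xs, ys = p[:, 0], p[:, 1]
    ks = np.arange(np.ceil(xs.min()), np.floor(xs.max()) + 1.0)
    if ks.size == 0:
        raise ValueError("mask too thin to profile")
    xa, xb = xs, np.roll(xs, -1)
    ya, yb = ys, np.roll(ys, -1)
    keep = xa != xb
    xa, xb, ya, yb = xa[keep], xb[keep], ya[keep], yb[keep]
    A = xa[:, None] - ks[None, :]
    B = xb[:, None] - ks[None, :]
    hit = A * B <= 0
    t = A / (xa - xb)[:, None]
    y = ya[:, None] + t * (yb - ya)[:, None]
    ymax = np.where(hit, y, -np.inf).max(axis=0)
    ymin = np.where(hit, y, np.inf).min(axis=0)
    ok = hit.sum(axis=0) >= 2
    widths = np.where(ok, ymax - ymin, 0.0)
    inner = np.nonzero(ok)[0]
    return list(widths[inner[0]: inner[-1] + 1])


def width_profile(mask, angle, contour=None):
    """Per-pixel-step mask widths along the major axis.

    Axis-aligned masks (angle ~ 0 or ~ pi/2) are profiled directly row by
    row: each step's width is the mask extent orthogonal to the major axis
    (rightmost - leftmost + 1), which interior holes cannot deflate. Oblique
    masks are profiled by slicing their sub-pixel contour in the exactly
    rotated frame (see :func:`_profile_from_contour`); raster rotation with
    nearest-neighbor resampling was rejected because its jagged widths
    inflate the frustum surface estimator by several percent.
    """
    mask = np.asarray(mask, dtype=bool)
    if abs(np.sin(angle)) < 1e-9:
        widths = _profile_from_rows(mask.T)  # major axis along x
    elif abs(np.cos(angle)) < 1e-9:
        widths = _profile_from_rows(mask)  # major axis already along y
    else:
        if contour is None:
            contour = extract_contour(mask)
        if len(contour) < 4:
            widths = _profile_from_rows(mask.T)
        else:
            ys, xs = np.nonzero(mask)
            origin = np.array([xs.mean(), ys.mean()])
            widths = _profile_from_contour(contour[:-1], angle, origin)
    return WidthProfile(angle=float(angle), h=len(widths),
                        widths=np.asarray(widths))


def volume_stacked_cylinders(profile: WidthProfile):
    """Volume as a stack of 1-px-high cylinders: V = pi * sum (w_i / 2)^2."""
    r = profile.widths / 2.0
    return float(np.pi * np.sum(r * r))


def surface_area_frustums(profile: WidthProfile):
    """Surface area as stacked 1-px-high truncated cones plus end caps.

    S = pi * [ (w_1/2)^2 + (w_h/2)^2
               + sum_{i=1}^{h-1} (w_i/2 + w_{i+1}/2) * sqrt((w_i/2 - w_{i+1}/2)^2 + 1) ]

    Base and top disks are added only for the first and last slice.
    """
    r = profile.widths / 2.0
    caps = r[0] ** 2 + r[-1] ** 2
    if len(r) > 1:
        lateral = np.sum((r[:-1] + r[1:]) * np.sqrt((r[:-1] - r[1:]) ** 2 + 1.0))
    else:
        lateral = 0.0
    return float(np.pi * (caps + lateral))


def spheroid_reference(ref: EllipsoidReference):
    """Closed-form volume and surface area of the prolate spheroid (a, b, b).

    Volume is (4/3) pi b^2 a. Surface area uses the prolate closed form
    2 pi b^2 (1 + (a / (b e)) * arcsin(e)), e = sqrt(1 - b^2/a^2), which is
    exact for spheroids (the sphere formula is its a -> b limit).
    """
    a, b = ref.a, ref.b
    volume = 4.0 / 3.0 * np.pi * b * b * a
    if np.isclose(a, b):
        surface = 4.0 * np.pi * a * a
    else:
        e = np.sqrt(1.0 - (b * b) / (a * a))
        surface = 2.0 * np.pi * b * b * (1.0 + (a / (b * e)) * np.arcsin(e))
    return float(volume), float(surface)


def compute_shape_metrics(mask, contour=None):
    """All shape metrics for one mask; length >= width is enforced."""
    mask = np.asarray(mask, dtype=bool)
    if contour is None:
        contour = extract_contour(mask)
    angle = principal_orientation(mask)
    length, width, _ = oriented_bbox(mask, angle, contour)
    profile = width_profile(mask, angle, contour)
    return ShapeMetrics(
        length=length,
        width=width,
        area=float(mask_area(mask)),
        perimeter=mask_perimeter(contour),
        surface_area=surface_area_frustums(profile),
        volume=volume_stacked_cylinders(profile),
        roundness=roundness_iso(mask, contour),
        solidity=solidity(mask, contour),
        orientation=angle,
    )


def metrics_to_cm(metrics: ShapeMetrics, px_per_cm: float):
    """Scale pixel metrics to cm (lengths /s, areas /s^2, volumes /s^3)."""
    s = px_per_cm
    if s <= 0:
        raise ValueError("px_per_cm must be > 0")
    return replace(
        metrics,
        length=metrics.length / s,
        width=metrics.width / s,
        perimeter=metrics.perimeter / s,
        area=metrics.area / s**2,
        surface_area=metrics.surface_area / s**2,
        volume=metrics.volume / s**3,
    )
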