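"""Synthetic stage-photograph generator with exact ground truth.

Emulates the imaging setup used for postharvest fruit phenotyping: separated
fruit arranged in rows and columns on a uniform stage, photographed from above
together with black circular scale markers of known physical diameter. Berries
are rendered as shaded filled ellipses (optionally with a wedge notch to mimic
a segmentation failure), markers as near-black disks. Every rendered object is
reported in a ground-truth table so downstream stages can be tested without
external data.

The rasterizer here also serves as the oracle fixture for the geometric
estimators: it draws ideal ellipse masks under a pixel-center inclusion rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: Sub-pixel grid phase used when the caller does not pin an object center.
#: Placing an ellipse center exactly on a pixel row/column (or exactly between
#: two) aligns the rasterization error coherently along the ellipse's flat
#: sides, which inflates the error of the solid-of-revolution estimators
#: severalfold. A generic (golden-ratio) phase avoids that lattice resonance.
GOLDEN_PHASE = (0.6180339887498949, 0.3819660112501051)

#: Default rendered color of scale markers (near-black, as on a real stage).
MARKER_COLOR = (20, 20, 20)

GROUND_TRUTH_COLUMNS = [
    "class", "row", "col", "cx", "cy",
    "length_px", "width_px", "rotation_deg", "area_px", "R", "G", "B",
]


class SceneOverlapError(ValueError):
    """Raised when two object footprints in a scene overlap."""


@dataclass
class BerrySpec:
    """Geometry and appearance of a single synthetic berry.

    rotation is measured in degrees from the +x axis toward the +y axis of the
    image (origin top-left), matching the orientation convention used by the
    morphometry module.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    rotation: float = 0.0
    base_color: tuple[int, int, int] = (150, 40, 45)
    shading: float = 0.0
    notch_depth: float = 0.0

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                f"require semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        if not (0.0 <= self.shading < 1.0):
            raise ValueError(f"shading must be in [0, 1), got {self.shading}")
        if any(not (0 <= c <= 255) for c in self.base_color):
            raise ValueError(f"colors must be in [0, 255], got {self.base_color}")
        if self.notch_depth < 0:
            raise ValueError("notch_depth must be >= 0")


@dataclass
class SceneSpec:
    """Full description of one synthetic stage photograph."""

    image_size: tuple[int, int]  # (W, H)
    background_color: tuple[int, int, int] = (255, 255, 255)
    berries: list[BerrySpec] = field(default_factory=list)
    markers: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    grid: tuple[int, int, float] | None = None  # (n_rows, n_cols, spacing px)
    seed: int = 0


def _ellipse_field(shape_hw, center, a, b, rotation_deg):
    """Squared normalized elliptical radius at every pixel center."""
    H, W = shape_hw
    cx, cy = center
    theta = np.deg2rad(rotation_deg)
    x = np.arange(W, dtype=float) - cx
    y = np.arange(H, dtype=float) - cy
    X, Y = np.meshgrid(x, y)
    u = np.cos(theta) * X + np.sin(theta) * Y
    v = -np.sin(theta) * X + np.cos(theta) * Y
    return (u / a) ** 2 + (v / b) ** 2


def _ellipse_extent(a, b, rotation_deg):
    """Half-extents (ex, ey) of a rotated ellipse along the image axes."""
    theta = np.deg2rad(rotation_deg)
    ex = np.hypot(a * np.cos(theta), b * np.sin(theta))
    ey = np.hypot(a * np.sin(theta), b * np.cos(theta))
    return ex, ey


def rasterize_ellipse_mask(semi_major, semi_minor, rotation=0.0, canvas=None,
                           center=None):
    """Rasterize an ideal ellipse under the pixel-center inclusion rule.

    A pixel belongs to the mask iff its center lies inside (or on) the
    ellipse. When ``center`` is not given the ellipse is placed at the canvas
    center offset by :data:`GOLDEN_PHASE`, a generic sub-pixel phase.

    Parameters
    ----------
    semi_major, semi_minor : float
        Semi-axes in pixels; each must be >= 2.
    rotation : float
        Degrees from the +x axis toward the +y axis.
    canvas : (W, H) tuple, optional
        Canvas size. Default: tight canvas with a 4-pixel pad.
    center : (cx, cy) tuple, optional
        Sub-pixel ellipse center in image coordinates.

    Returns
    -------
    numpy.ndarray of bool, shape (H, W)
    """
    if semi_major < semi_minor:
        raise ValueError("semi_major must be >= semi_minor")
    if semi_minor < 2:
        raise ValueError("semi-axes must be >= 2 px")
    ex, ey = _ellipse_extent(semi_major, semi_minor, rotation)
    if canvas is None:
        W = int(np.ceil(2 * ex)) + 9
        H = int(np.ceil(2 * ey)) + 9
    else:
        W, H = canvas
    if center is None:
        center = (W // 2 + GOLDEN_PHASE[0], H // 2 + GOLDEN_PHASE[1])
    cx, cy = center
    if cx - ex < -0.5 or cx + ex > W - 0.5 or cy - ey < -0.5 or cy + ey > H - 0.5:
        raise ValueError(
            f"ellipse (a={semi_major}, b={semi_minor}, rot={rotation}) at "
            f"center ({cx:.2f}, {cy:.2f}) exceeds canvas {W}x{H}: needs "
            f"x in [{cx - ex:.1f}, {cx + ex:.1f}], y in [{cy - ey:.1f}, {cy + ey:.1f}]"
        )
    return _ellipse_field((H, W), (cx, cy), semi_major, semi_minor, rotation) <= 1.0


def _notch_triangle(spec: BerrySpec):
    """Vertices of the wedge carved out of a berry, in image coordinates.

    The wedge points from the tip of the major axis toward the centroid; its
    base sits on the boundary with half-width 0.75 * depth. Depth is chosen by
    the caller to push solidity below (or keep it above) a QC threshold.
    """
    theta = np.deg2rad(spec.rotation)
    axis = np.array([np.cos(theta), np.sin(theta)])
    tangent = np.array([-np.sin(theta), np.cos(theta)])
    c = np.asarray(spec.center, dtype=float)
    tip = c + spec.semi_major * axis
    apex = tip - spec.notch_depth * axis
    half_w = 0.75 * spec.notch_depth
    # base corners pushed slightly outside the boundary so the carve is clean
    base1 = tip + 2.0 * axis + half_w * tangent
    base2 = tip + 2.0 * axis - half_w * tangent
    return np.array([apex, base1, base2])


def _point_in_triangle(X, Y, tri):
    """Vectorized inclusion test for pixel centers against a triangle."""
    def sign(p1, p2):
        return (X - p2[0]) * (p1[1] - p2[1]) - (p1[0] - p2[0]) * (Y - p2[1])

    d1 = sign(tri[0], tri[1])
    d2 = sign(tri[1], tri[2])
    d3 = sign(tri[2], tri[0])
    neg = (d1 < 0) | (d2 < 0) | (d3 < 0)
    pos = (d1 > 0) | (d2 > 0) | (d3 > 0)
    return ~(neg & pos)


def _berry_mask(spec: BerrySpec, shape_hw):
    q = _ellipse_field(shape_hw, spec.center, spec.semi_major, spec.semi_minor,
                       spec.rotation)
    mask = q <= 1.0
    if spec.notch_depth > 0:
        H, W = shape_hw
        X, Y = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
        mask &= ~_point_in_triangle(X, Y, _notch_triangle(spec))
    return mask, q


def render_scene(spec: SceneSpec):
    """Render a scene to an 8-bit RGB image plus its ground-truth table.

    Berries are shaded filled ellipses: the color interpolates linearly from
    ``base_color`` at the center to ``(1 - shading) * base_color`` at the rim.
    Markers are filled near-black disks. Rendering is pure: the output depends
    only on ``spec``.

    Returns
    -------
    (image, ground_truth) : (numpy.ndarray uint8 (H, W, 3), pandas.DataFrame)

    Raises
    ------
    SceneOverlapError
        If two object footprints overlap.
    """
    W, H = spec.image_size
    image = np.empty((H, W, 3), dtype=np.uint8)
    image[:] = np.asarray(spec.background_color, dtype=np.uint8)

    occupancy = np.full((H, W), -1, dtype=np.int32)
    records = []
    n_cols = spec.grid[1] if spec.grid else None

    def _claim(mask, idx, name):
        clash = occupancy[mask]
        clash = clash[clash >= 0]
        if clash.size:
            other = records[int(clash[0])]
            raise SceneOverlapError(
                f"object footprints overlap: {name} collides with "
                f"{other['class']} at ({other['cx']:.0f}, {other['cy']:.0f})"
            )
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            raise ValueError(f"{name} is not fully inside the frame")
        occupancy[mask] = idx

    for i, b in enumerate(spec.berries):
        mask, q = _berry_mask(b, (H, W))
        _claim(mask, len(records), f"berry {i}")
        r_norm = np.sqrt(np.clip(q[mask], 0.0, 1.0))
        base = np.asarray(b.base_color, dtype=float)
        shade = 1.0 - b.shading * r_norm
        image[mask] = np.clip(np.round(shade[:, None] * base), 0, 255).astype(np.uint8)
        row = col = None
        if n_cols is not None:
            row, col = i // n_cols + 1, i % n_cols + 1
        records.append({
            "class": "berry", "row": row, "col": col,
            "cx": b.center[0], "cy": b.center[1],
            "length_px": 2 * b.semi_major, "width_px": 2 * b.semi_minor,
            "rotation_deg": b.rotation, "area_px": int(mask.sum()),
            "R": b.base_color[0], "G": b.base_color[1], "B": b.base_color[2],
        })

    for j, (center, diameter) in enumerate(spec.markers):
        r = diameter / 2.0
        mask = _ellipse_field((H, W), center, r, r, 0.0) <= 1.0
        _claim(mask, len(records), f"marker {j}")
        image[mask] = np.asarray(MARKER_COLOR, dtype=np.uint8)
        records.append({
            "class": "marker", "row": None, "col": None,
            "cx": center[0], "cy": center[1],
            "length_px": diameter, "width_px": diameter,
            "rotation_deg": 0.0, "area_px": int(mask.sum()),
            "R": MARKER_COLOR[0], "G": MARKER_COLOR[1], "B": MARKER_COLOR[2],
        })

    truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    return image, truth


# Cranberry-like palette: dark reds through pink, roughly spanning the color
# range reported for real fruit populations.
DEFAULT_PALETTE = (
    (96, 30, 28),
    (118, 30, 34),
    (140, 42, 40),
    (160, 56, 52),
    (175, 72, 70),
    (105, 26, 30),
)


def make_grid_spec(n_rows=5, n_cols=6, axes_ranges=((34.0, 46.0), (28.0, 38.0)),
                   color_palette=DEFAULT_PALETTE, seed=0, spacing=None,
                   shading=0.25, marker_diameter=100.0, n_markers=6,
                   jitter_frac=0.08, background_color=(255, 255, 255)):
    """Build a :class:`SceneSpec` for a gridded stage layout.

    Defaults emulate the study layout scaled for fast tests: a 5 x 6 grid of
    berries (semi-axes drawn uniformly from ``axes_ranges``) flanked by six
    black markers of 100 px diameter, so that a 2.54 cm marker gives
    ~39.4 px/cm and a typical berry measures ~2 cm long. Jitter is kept small
    enough (``jitter_frac`` of the spacing) to preserve row and column order.

    Axes, rotations, colors and jitter are drawn reproducibly from ``seed``.
    """
    if n_rows * n_cols < 1:
        raise ValueError("grid must contain at least one cell")
    rng = np.random.default_rng(seed)
    (maj_lo, maj_hi), (min_lo, min_hi) = axes_ranges
    if spacing is None:
        spacing = 2.6 * maj_hi
    max_extent = maj_hi + jitter_frac * spacing
    if spacing < 2 * max_extent:
        raise ValueError(
            f"grid too dense: spacing {spacing:.1f} px cannot separate berries "
            f"with extent up to {max_extent:.1f} px"
        )

    side = marker_diameter + 60.0  # lateral band holding the markers
    W = int(np.ceil(n_cols * spacing + 2 * side))
    H = int(np.ceil(max(n_rows * spacing,
                        (n_markers / 2) * (marker_diameter + 30.0)) + 60.0))
    x0 = side + spacing / 2.0
    y0 = (H - (n_rows - 1) * spacing) / 2.0

    berries = []
    palette = np.asarray(color_palette, dtype=int)
    for r in range(n_rows):
        for c in range(n_cols):
            a = rng.uniform(maj_lo, maj_hi)
            b = rng.uniform(min_lo, min(min_hi, a))
            jx, jy = rng.uniform(-jitter_frac, jitter_frac, size=2) * spacing
            color = palette[rng.integers(len(palette))]
            berries.append(BerrySpec(
                center=(x0 + c * spacing + jx, y0 + r * spacing + jy),
                semi_major=a, semi_minor=b,
                rotation=float(rng.uniform(0.0, 180.0)),
                base_color=tuple(int(v) for v in color),
                shading=shading,
            ))

    markers = []
    per_side = n_markers - n_markers // 2
    for k in range(n_markers):
        on_left = k < per_side
        count = per_side if on_left else n_markers // 2
        slot = k if on_left else k - per_side
        mx = side / 2.0 if on_left else W - side / 2.0
        my = (slot + 1) * H / (count + 1)
        markers.append(((mx + GOLDEN_PHASE[0], my + GOLDEN_PHASE[1]),
                        marker_diameter))

    return SceneSpec(image_size=(W, H), background_color=background_color,
                     berries=berries, markers=markers,
                     grid=(n_rows, n_cols, spacing), seed=seed)


def save_scene(image, truth, image_path, truth_path=None, jpeg_quality=None):
    """Write the rendered image (PNG by default, JPG on request) and truth CSV."""
    img = Image.fromarray(image)
    if jpeg_quality is not None:
        img.save(image_path, format="JPEG", quality=jpeg_quality)
    else:
        img.save(image_path, format="PNG")
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
    logger.info("wrote scene image to %s", image_path)
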