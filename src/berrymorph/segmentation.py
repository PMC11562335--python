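"""Classical berry / scale-marker segmentation.

Detects and segments fruit and circular size markers from an RGB stage
photograph using static thresholding on the hue, saturation and value
channels, followed by morphological cleanup, hole filling and small-object
removal. This is the traditional computer-vision path: fast and reliable on
clean, consistently laid-out stages, and deliberately pluggable — any callable
mapping an image to a list of :class:`LabeledMask` can replace it (e.g. a
neural instance segmenter).

Classical pipelines of this kind are hand-tuned per imaging setup; the
defaults here are documented and were chosen on synthetic fixtures only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)


@dataclass
class ThresholdConfig:
    """HSV thresholding parameters.

    Foreground is the union of two rules:

    * colored-object rule: saturation >= ``sat_min`` AND value inside
      ``value_window`` AND (if ``hue_windows`` is given) hue inside one of the
      windows (degrees, wrap-around allowed);
    * dark-object rule: value <= ``dark_value_max`` (catches near-black
      markers, which have no saturation to threshold on).

    ``background_mode='dark'`` swaps the dark-object rule for a bright-object
    rule (value >= 1 - dark_value_max). ``'auto'`` infers light/dark from the
    border pixels and sets the value cut by Otsu's method.
    """

    background_mode: str = "light"  # light | dark | auto
    hue_windows: list[tuple[float, float]] | None = None
    sat_min: float = 0.25
    value_window: tuple[float, float] = (0.0, 1.0)
    dark_value_max: float = 0.35
    min_object_area: int = 256
    morphology_radius: int = 1

    def __post_init__(self) -> None:
        if self.background_mode not in ("light", "dark", "auto"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if not (0 <= self.sat_min <= 1) or not (0 <= self.dark_value_max <= 1):
            raise ValueError("channel thresholds must lie in [0, 1]")
        if self.min_object_area <= 0:
            raise ValueError("min_object_area must be > 0")


@dataclass
class LabeledMask:
    """One segmented object: full-frame mask, outer contour, class, location."""

    mask: np.ndarray
    contour: np.ndarray  # (N, 2) float, (x, y), closed (first == last)
    label: str  # "berry" | "marker"
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int] = field(default=None)  # (x0, y0, x1, y1)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _hue_in_windows(hue_deg, windows):
    keep = np.zeros_like(hue_deg, dtype=bool)
    for lo, hi in windows:
        if lo <= hi:
            keep |= (hue_deg >= lo) & (hue_deg <= hi)
        else:  # wrap-around window such as (330, 30)
            keep |= (hue_deg >= lo) | (hue_deg <= hi)
    return keep


def hsv_threshold_segment(image, config: ThresholdConfig | None = None):
    """Segment foreground objects by static HSV thresholding.

    Returns full-frame boolean masks, one per connected component, sorted
    largest-first. Components are cleaned by morphological opening and
    closing, hole-filled, and filtered by ``min_object_area``; components
    touching the image border are dropped (they cannot be measured fully)
    and logged.
    """
    if config is None:
        config = ThresholdConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB image of shape (H, W, 3)")

    hsv = rgb2hsv(image)
    hue_deg, sat, val = hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]

    mode = config.background_mode
    dark_cut = config.dark_value_max
    if mode == "auto":
        border = np.concatenate([val[0, :], val[-1, :], val[:, 0], val[:, -1]])
        mode = "light" if np.median(border) >= 0.5 else "dark"
        try:
            dark_cut = float(threshold_otsu(val))
        except ValueError:  # constant image
            dark_cut = config.dark_value_max
        logger.info("auto background mode -> %s (value cut %.3f)", mode, dark_cut)

    colored = (sat >= config.sat_min) \
        & (val >= config.value_window[0]) & (val <= config.value_window[1])
    if config.hue_windows:
        colored &= _hue_in_windows(hue_deg, config.hue_windows)
    if mode == "light":
        fg = colored | (val <= dark_cut)
    else:
        fg = colored | (val >= 1.0 - dark_cut)

    r = config.morphology_radius
    if r > 0:
        selem = morphology.disk(r)
        fg = ndi.binary_opening(fg, structure=selem)
        fg = ndi.binary_closing(fg, structure=selem)

    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    # opening erodes border-touching objects inward by the morphology radius,
    # so "touching" is judged against a band of that width along the border
    band = r + 1
    components = []
    for i in range(1, n + 1):
        comp = labels == i
        if comp[:band, :].any() or comp[-band:, :].any() \
                or comp[:, :band].any() or comp[:, -band:].any():
            logger.info("dropping component %d: touches the image border", i)
            continue
        comp = ndi.binary_fill_holes(comp)
        if comp.sum() < config.min_object_area:
            continue
        components.append(comp)
    components.sort(key=lambda m: int(m.sum()), reverse=True)
    return components


def extract_contour(mask):
    """Outer boundary of a single connected component as a closed polygon.

    The contour is the sub-pixel 0.5-level iso-contour of the mask (marching
    squares), in (x, y) image coordinates, oriented counter-clockwise in the
    mathematical sense of the axes (x right, y down; signed shoelace area
    positive), starting at the vertex nearest the topmost-then-leftmost
    boundary point, with the first vertex repeated at the end. A single-pixel
    mask yields a degenerate one-vertex polygon.
    """
    mask = np.asarray(mask, dtype=bool)
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValueError("cannot extract a contour from an empty mask")
    if n_fg == 1:
        y, x = (int(v[0]) for v in np.nonzero(mask))
        return np.array([[float(x), float(y)]])

    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    rc = max(contours, key=len)  # outer boundary is the longest loop
    poly = np.column_stack([rc[:, 1] - 1.0, rc[:, 0] - 1.0])  # (x, y)
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])

    ring = poly[:-1]
    signed = 0.5 * np.sum(ring[:, 0] * np.roll(ring[:, 1], -1)
                          - np.roll(ring[:, 0], -1) * ring[:, 1])
    if signed < 0:
        ring = ring[::-1]
    start = np.lexsort((ring[:, 0], ring[:, 1]))[0]
    ring = np.roll(ring, -start, axis=0)
    return np.vstack([ring, ring[0]])


def polygon_perimeter(contour, smooth_window=5):
    """Arc length of a closed contour polygon.

    The iso-contour of a binary mask is a staircase whose raw edge-length sum
    overestimates a smooth boundary by ~5%, so the vertices are first passed
    through a short circular moving average (``smooth_window`` vertices,
    about 2.5 px of boundary) before the Euclidean edge lengths are summed.
    This brings a digital circle's arc length within ~0.5% of its true
    circumference while leaving the polygon itself (used for extents, hulls
    and enclosing circles) untouched. ``smooth_window=1`` disables smoothing.
    """
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 2:
        return 0.0
    ring = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    n = len(ring)
    if smooth_window > 1 and n > smooth_window:
        half = smooth_window // 2
        idx = (np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :]) % n
        ring = ring[idx].mean(axis=1)
    closed = np.vstack([ring, ring[0]])
    return float(np.hypot(*np.diff(closed, axis=0).T).sum())


def classify_components(image, components, darkness_max=0.20,
                        circularity_min=0.85, marker_area_band=(0.25, 4.0)):
    """Label each component as a size marker or a berry.

    A component is a marker iff its circularity 4*pi*A/P**2 is at least
    ``circularity_min``, its mean value channel is below ``darkness_max``
    (markers are near-black), and its area lies within ``marker_area_band``
    times the median area of the candidate markers. Everything else —
    including ambiguous components, which are logged — defaults to berry.
    """
    image = np.asarray(image)
    val = image.max(axis=2).astype(float) / 255.0
    masks = []
    candidate_idx = []
    for i, comp in enumerate(components):
        contour = extract_contour(comp)
        area = int(comp.sum())
        per = polygon_perimeter(contour)
        circ = 4.0 * np.pi * area / per**2 if per > 0 else 0.0
        dark = float(val[comp].mean()) <= darkness_max
        ys, xs = np.nonzero(comp)
        lm = LabeledMask(
            mask=comp, contour=contour, label="berry",
            centroid=(float(xs.mean()), float(ys.mean())),
            bbox=(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())),
        )
        if circ >= circularity_min and dark:
            candidate_idx.append(i)
        elif dark and circ >= circularity_min - 0.05:
            logger.info("component %d is dark but borderline-round "
                        "(circularity %.3f); keeping as berry", i, circ)
        masks.append(lm)

    if candidate_idx:
        med = float(np.median([masks[i].area for i in candidate_idx]))
        lo, hi = marker_area_band
        for i in candidate_idx:
            if lo * med <= masks[i].area <= hi * med:
                masks[i].label = "marker"
            else:
                logger.info("component %d: round and dark but area %d outside "
                            "[%.0f, %.0f]; keeping as berry",
                            i, masks[i].area, lo * med, hi * med)
    return masks


def segment_image(image, config: ThresholdConfig | None = None):
    """Convenience wrapper: threshold then classify. The default segmenter."""
    comps = hsv_threshold_segment(image, config)
    return classify_components(image, comps)
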