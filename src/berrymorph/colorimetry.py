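"""Per-berry color statistics in RGB, grayscale, HSV and CIELAB.

Waxy fruit reflect the stage surface along their rim, so a 10-pixel border is
eroded off each berry mask before any color statistic is computed (size and
shape metrics always use the full mask). Grayscale follows the Rec.601 luma
weights applied to the channel *medians*: R*0.299 + G*0.587 + B*0.114.
CIELAB conversion is the standard sRGB decoding under the D65 reference
white, applied per pixel before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv, rgb2lab

logger = logging.getLogger(__name__)

GRAY_WEIGHTS = {"R": 0.299, "G": 0.587, "B": 0.114}


@dataclass
class ColorMetrics:
    """Color statistics over the (eroded) berry region, 0-255 RGB scale."""

    red_mean: float
    green_mean: float
    blue_mean: float
    red_median: int
    green_median: int
    blue_median: int
    red_var: float
    green_var: float
    blue_var: float
    gray: float          # Rec.601 luma of the channel medians
    gray_var: float      # variance of the per-pixel Rec.601 gray value
    hue_mean_deg: float  # circular mean, degrees in [0, 360)
    sat_mean: float
    val_mean: float
    L_mean: float
    L_sd: float
    astar_mean: float
    astar_sd: float
    bstar_mean: float
    bstar_sd: float
    n_pixels_used: int
    eroded: bool


def erode_interior(mask, radius=10):
    """Erode the mask with a Euclidean disk of the given radius.

    Returns ``(eroded_mask, eroded_flag)``. If erosion would empty the mask
    (the object is thinner than 2*radius) the original mask is returned with
    ``eroded_flag=False`` and a log message, so small objects still get color
    statistics rather than NaNs.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if radius <= 0:
        return mask, True
    inner = ndi.distance_transform_edt(mask) > radius
    if not inner.any():
        logger.info("erosion by %d px would empty the mask (area %d); "
                    "using the un-eroded mask", radius, int(mask.sum()))
        return mask, False
    return inner, True


def _lower_median(values):
    """Median with the lower-of-two tie rule, preserving integer inputs."""
    v = np.sort(np.asarray(values).ravel())
    return v[(len(v) - 1) // 2]


def rgb_stats(image, mask):
    """Per-channel mean, (lower-)median and population variance over the mask."""
    pixels = np.asarray(image)[np.asarray(mask, dtype=bool)]
    if pixels.size == 0:
        raise ValueError("mask selects no pixels")
    out = {}
    for i, ch in enumerate("RGB"):
        v = pixels[:, i].astype(float)
        out[ch] = {
            "mean": float(v.mean()),
            "median": int(_lower_median(pixels[:, i])),
            "variance": float(v.var()),
        }
    return out


def grayscale_from_medians(r_med, g_med, b_med):
    """Rec.601 luma of the channel medians."""
    for v in (r_med, g_med, b_med):
        if not (0 <= v <= 255):
            raise ValueError("channel medians must lie in [0, 255]")
    return (GRAY_WEIGHTS["R"] * r_med + GRAY_WEIGHTS["G"] * g_med
            + GRAY_WEIGHTS["B"] * b_med)


def srgb_to_cielab(r, g, b):
    """Convert one 8-bit sRGB triple to CIELAB (D65 reference white)."""
    rgb = np.asarray([[[r, g, b]]], dtype=float) / 255.0
    lab = rgb2lab(rgb)[0, 0]
    return tuple(float(v) for v in lab)


def lab_stats(image, mask):
    """Per-pixel CIELAB conversion, then mean and population SD per channel."""
    pixels = np.asarray(image)[np.asarray(mask, dtype=bool)]
    if pixels.size == 0:
        raise ValueError("mask selects no pixels")
    lab = rgb2lab(pixels.reshape(-1, 1, 3).astype(float) / 255.0).reshape(-1, 3)
    return {
        "L": {"mean": float(lab[:, 0].mean()), "sd": float(lab[:, 0].std())},
        "a": {"mean": float(lab[:, 1].mean()), "sd": float(lab[:, 1].std())},
        "b": {"mean": float(lab[:, 2].mean()), "sd": float(lab[:, 2].std())},
    }


def hsv_stats(image, mask):
    """Channel means in HSV; hue is averaged circularly, in degrees."""
    pixels = np.asarray(image)[np.asarray(mask, dtype=bool)]
    if pixels.size == 0:
        raise ValueError("mask selects no pixels")
    hsv = rgb2hsv(pixels.reshape(-1, 1, 3)).reshape(-1, 3)
    ang = hsv[:, 0] * 2.0 * np.pi
    hue = np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()))
    return {
        "hue_deg": float(np.mod(hue, 360.0)),
        "saturation": float(hsv[:, 1].mean()),
        "value": float(hsv[:, 2].mean()),
    }


def compute_color_metrics(image, mask, erosion_radius=10):
    """All color statistics for one berry, after rim erosion."""
    region, eroded = erode_interior(mask, erosion_radius)
    rgb = rgb_stats(image, region)
    lab = lab_stats(image, region)
    hsv = hsv_stats(image, region)
    pixels = np.asarray(image)[region].astype(float)
    gray_pp = (GRAY_WEIGHTS["R"] * pixels[:, 0] + GRAY_WEIGHTS["G"] * pixels[:, 1]
               + GRAY_WEIGHTS["B"] * pixels[:, 2])
    return ColorMetrics(
        red_mean=rgb["R"]["mean"], green_mean=rgb["G"]["mean"],
        blue_mean=rgb["B"]["mean"],
        red_median=rgb["R"]["median"], green_median=rgb["G"]["median"],
        blue_median=rgb["B"]["median"],
        red_var=rgb["R"]["variance"], green_var=rgb["G"]["variance"],
        blue_var=rgb["B"]["variance"],
        gray=grayscale_from_medians(rgb["R"]["median"], rgb["G"]["median"],
                                    rgb["B"]["median"]),
        gray_var=float(gray_pp.var()),
        hue_mean_deg=hsv["hue_deg"], sat_mean=hsv["saturation"],
        val_mean=hsv["value"],
        L_mean=lab["L"]["mean"], L_sd=lab["L"]["sd"],
        astar_mean=lab["a"]["mean"], astar_sd=lab["a"]["sd"],
        bstar_mean=lab["b"]["mean"], bstar_sd=lab["b"]["sd"],
        n_pixels_used=int(region.sum()),
        eroded=eroded,
    )
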