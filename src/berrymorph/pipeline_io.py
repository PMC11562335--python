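"""End-to-end per-image pipeline: segment, measure, calibrate, QC, write.

The core output is a CSV with one row per detected berry carrying all size,
shape and color metrics in pixels and (when markers are present) in cm,
plus quality-control flags. Optionally an annotated copy of each image is
written showing berry and marker contours, oriented bounding boxes, berry
indices, and flagged berries.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

from . import colorimetry, morphometry
from .layout_calibration import ScaleCalibration, assign_grid, estimate_scale, to_cm
from .segmentation import LabeledMask, ThresholdConfig, segment_image

logger = logging.getLogger(__name__)

QC_LOW_SOLIDITY = "LOW_SOLIDITY"
QC_AREA_OUTLIER = "AREA_OUTLIER"
QC_BORDER_TOUCH = "BORDER_TOUCH"
QC_EROSION_FALLBACK = "EROSION_FALLBACK"


@dataclass
class PipelineConfig:
    """All pipeline knobs, serializable to/from YAML."""

    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    marker_diameter_cm: float = 2.54
    grid_mode: bool = True
    solidity_qc_threshold: float = 0.95
    area_sd_threshold: float = 3.0
    erosion_radius: int = 10
    annotate: bool = False

    def __post_init__(self) -> None:
        if self.solidity_qc_threshold <= 0 or self.area_sd_threshold <= 0 \
                or self.marker_diameter_cm <= 0 or self.erosion_radius < 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        thr = data.pop("threshold", {})
        if thr.get("hue_windows"):
            thr["hue_windows"] = [tuple(w) for w in thr["hue_windows"]]
        if "value_window" in thr:
            thr["value_window"] = tuple(thr["value_window"])
        return cls(threshold=ThresholdConfig(**thr), **data)

    def to_yaml(self, path):
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class BerryRecord:
    """One output row: identity, position, all metrics, QC flags."""

    image_id: str
    berry_index: int
    row: int | None
    col: int | None
    centroid_x: float
    centroid_y: float
    length_px: float
    width_px: float
    perimeter_px: float
    area_px2: float
    surface_area_px2: float
    volume_px3: float
    length_cm: float | None
    width_cm: float | None
    perimeter_cm: float | None
    area_cm2: float | None
    surface_area_cm2: float | None
    volume_cm3: float | None
    roundness: float
    solidity: float
    red_mean: float
    green_mean: float
    blue_mean: float
    red_median: int
    green_median: int
    blue_median: int
    red_var: float
    green_var: float
    blue_var: float
    gray: float
    gray_var: float
    hue_mean_deg: float
    sat_mean: float
    val_mean: float
    L_mean: float
    L_sd: float
    astar_mean: float
    astar_sd: float
    bstar_mean: float
    bstar_sd: float
    n_pixels_used: int
    qc_flags: str = ""


CSV_HEADER = [f.name for f in fields(BerryRecord)]


def _load_image(source):
    if isinstance(source, (str, Path)):
        with Image.open(source) as img:
            return np.asarray(img.convert("RGB")), Path(source).stem
    arr = np.asarray(source)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image array or a readable path")
    return arr.astype(np.uint8, copy=False), "image"


def qc_flags(records, solidity_threshold=0.95, area_sd_threshold=3.0):
    """Apply per-image runtime QC to a list of records (in place).

    LOW_SOLIDITY marks berries whose solidity falls below the threshold
    (typically mis-segmented fruit). AREA_OUTLIER marks berries whose mask
    area lies more than ``area_sd_threshold`` standard deviations from the
    mean area of the berries in the same image (never triggered for a
    single-berry image). Flags set during measurement (border contact,
    erosion fallback) are preserved.
    """
    if not records:
        raise ValueError("need at least one record")
    by_image: dict[str, list[BerryRecord]] = {}
    for rec in records:
        by_image.setdefault(rec.image_id, []).append(rec)
    for recs in by_image.values():
        areas = np.array([r.area_px2 for r in recs], dtype=float)
        mean, sd = areas.mean(), areas.std()
        for rec in recs:
            flags = set(rec.qc_flags.split(";")) - {""}
            flags.discard(QC_LOW_SOLIDITY)
            flags.discard(QC_AREA_OUTLIER)
            if rec.solidity < solidity_threshold:
                flags.add(QC_LOW_SOLIDITY)
            if len(recs) > 1 and sd > 0 \
                    and abs(rec.area_px2 - mean) > area_sd_threshold * sd:
                flags.add(QC_AREA_OUTLIER)
            rec.qc_flags = ";".join(sorted(flags))
    return records


def analyze_image(source, config: PipelineConfig | None = None, image_id=None):
    """Full pipeline on one image; returns records plus the segmentation.

    Returns
    -------
    (records, berries, markers, cal, image)
        records: list of BerryRecord ordered by (row, col) in grid mode;
        berries/markers: LabeledMask lists aligned with the records;
        cal: ScaleCalibration; image: the RGB array analyzed.
    """
    if config is None:
        config = PipelineConfig()
    image, default_id = _load_image(source)
    image_id = image_id or default_id

    labeled = segment_image(image, config.threshold)
    berries = [m for m in labeled if m.label == "berry"]
    markers = [m for m in labeled if m.label == "marker"]
    logger.info("%s: %d berries, %d markers detected", image_id,
                len(berries), len(markers))
    if not berries:
        logger.warning("%s: no berries detected", image_id)
        return [], [], markers, estimate_scale(markers, config.marker_diameter_cm), image

    cal = estimate_scale(markers, config.marker_diameter_cm)
    if cal.calibrated:
        logger.info("%s: calibrated at %.2f px/cm from %d markers", image_id,
                    cal.px_per_cm, cal.n_markers_used)

    positions = [None] * len(berries)
    if config.grid_mode:
        heights = [b.bbox[3] - b.bbox[1] + 1 for b in berries]
        grid = assign_grid([b.centroid for b in berries], heights)
        positions = grid.positions

    H, W = image.shape[:2]
    entries = []
    for b, pos in zip(berries, positions):
        metrics = morphometry.compute_shape_metrics(b.mask, b.contour)
        color = colorimetry.compute_color_metrics(image, b.mask,
                                                  config.erosion_radius)
        cm = to_cm(metrics, cal) if cal.calibrated else None
        flags = set()
        if not color.eroded:
            flags.add(QC_EROSION_FALLBACK)
        x0, y0, x1, y1 = b.bbox
        if x0 == 0 or y0 == 0 or x1 == W - 1 or y1 == H - 1:
            flags.add(QC_BORDER_TOUCH)
        entries.append((b, pos, metrics, cm, color, flags))

    entries.sort(key=lambda e: (e[1] if e[1] is not None else (0, 0)))
    records, ordered_berries = [], []
    for idx, (b, pos, m, cm, c, flags) in enumerate(entries, start=1):
        records.append(BerryRecord(
            image_id=image_id, berry_index=idx,
            row=pos[0] if pos else None, col=pos[1] if pos else None,
            centroid_x=b.centroid[0], centroid_y=b.centroid[1],
            length_px=m.length, width_px=m.width, perimeter_px=m.perimeter,
            area_px2=m.area, surface_area_px2=m.surface_area,
            volume_px3=m.volume,
            length_cm=cm.length if cm else None,
            width_cm=cm.width if cm else None,
            perimeter_cm=cm.perimeter if cm else None,
            area_cm2=cm.area if cm else None,
            surface_area_cm2=cm.surface_area if cm else None,
            volume_cm3=cm.volume if cm else None,
            roundness=m.roundness, solidity=m.solidity,
            red_mean=c.red_mean, green_mean=c.green_mean, blue_mean=c.blue_mean,
            red_median=c.red_median, green_median=c.green_median,
            blue_median=c.blue_median,
            red_var=c.red_var, green_var=c.green_var, blue_var=c.blue_var,
            gray=c.gray, gray_var=c.gray_var,
            hue_mean_deg=c.hue_mean_deg, sat_mean=c.sat_mean, val_mean=c.val_mean,
            L_mean=c.L_mean, L_sd=c.L_sd,
            astar_mean=c.astar_mean, astar_sd=c.astar_sd,
            bstar_mean=c.bstar_mean, bstar_sd=c.bstar_sd,
            n_pixels_used=c.n_pixels_used,
            qc_flags=";".join(sorted(flags)),
        ))
        ordered_berries.append(b)

    qc_flags(records, config.solidity_qc_threshold, config.area_sd_threshold)
    n_flagged = sum(1 for r in records if r.qc_flags)
    logger.info("%s: %d records, %d flagged", image_id, len(records), n_flagged)
    return records, ordered_berries, markers, cal, image


def process_image(source, config: PipelineConfig | None = None, image_id=None):
    """Run the pipeline on one image and return the berry records."""
    return analyze_image(source, config, image_id)[0]


def write_csv(records, path):
    """Write records as an RFC 4180 CSV with a fixed header.

    Floats are written at 4 decimals; rows are sorted by
    (image_id, row, col, berry_index); cm columns are empty when the image
    was not calibrated. Byte-identical for identical inputs.
    """
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=CSV_HEADER)
    if len(df):
        big = 10**9
        df = df.sort_values(
            by=["image_id", "row", "col", "berry_index"],
            key=lambda s: s.fillna(big) if s.dtype != object else s,
            kind="stable",
        ).reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.4f", lineterminator="\r\n")
    return path


def read_csv(path):
    """Read a pipeline CSV back into a DataFrame."""
    return pd.read_csv(path)


def write_annotated(image, records, masks, path, markers=()):
    """Write a PNG overlay of contours, OBBs, indices and QC highlights.

    ``masks`` must be the LabeledMask list aligned with ``records``. Flagged
    berries are outlined in red, clean berries in green, markers in blue;
    oriented bounding boxes are drawn in yellow with the berry index at the
    centroid.
    """
    img = Image.fromarray(np.asarray(image)).convert("RGB")
    draw = ImageDraw.Draw(img)
    for m in markers:
        draw.line([tuple(p) for p in m.contour], fill=(60, 120, 255), width=2)
    for rec, m in zip(records, masks):
        color = (255, 60, 60) if rec.qc_flags else (60, 200, 60)
        draw.line([tuple(p) for p in m.contour], fill=color, width=2)
        angle = morphometry.principal_orientation(m.mask)
        _, _, corners = morphometry.oriented_bbox(m.mask, angle, m.contour)
        box = [tuple(p) for p in corners] + [tuple(corners[0])]
        draw.line(box, fill=(240, 200, 40), width=1)
        draw.text(m.centroid, str(rec.berry_index), fill=(255, 255, 255))
    img.save(path, format="PNG")
    return path
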