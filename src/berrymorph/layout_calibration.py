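"""Scale calibration, grid assignment and cross-platform berry matching.

Pixel metrics are converted to cm via the detected circular scale markers of
known physical diameter (2.54 cm on the reference stages). Berries are
auto-assigned grid rows and columns from their centroids, and two measurement
sets over the same image frame are matched 1-to-1 by reciprocal nearest
centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .morphometry import _smallest_enclosing_circle, metrics_to_cm  # noqa: F401
from .segmentation import LabeledMask

logger = logging.getLogger(__name__)

DEFAULT_MARKER_DIAMETER_CM = 2.54


@dataclass
class ScaleCalibration:
    """px-per-cm factor derived from detected markers of known diameter."""

    px_per_cm: float | None
    marker_diameters_px: list[float]
    marker_diameter_cm: float = DEFAULT_MARKER_DIAMETER_CM
    n_markers_used: int = 0

    @property
    def calibrated(self) -> bool:
        return self.px_per_cm is not None


@dataclass
class GridAssignment:
    """1-based (row, col) per berry; rows top-to-bottom, cols left-to-right."""

    positions: list[tuple[int, int]]
    n_rows: int
    n_cols: int


def estimate_scale(marker_masks, marker_diameter_cm=DEFAULT_MARKER_DIAMETER_CM,
                   outlier_frac=0.20):
    """Calibrate px/cm from marker masks.

    Each marker's pixel diameter is that of the minimum enclosing circle of
    its contour (robust to small segmentation nicks), minus 1 px because the
    iso-contour sits half a pixel outside the outermost pixel centers on each
    side. Markers deviating more
    than ``outlier_frac`` from the median diameter are excluded and logged;
    px_per_cm is the median of the remaining diameters over the known
    physical diameter. With no markers the result is uncalibrated and
    metrics stay in pixels.
    """
    diameters = []
    for m in marker_masks:
        contour = m.contour if isinstance(m, LabeledMask) else np.asarray(m)
        pts = contour[:-1] if len(contour) > 1 else contour
        diameters.append(max(2.0 * _smallest_enclosing_circle(pts)[2] - 1.0, 0.0))
    if not diameters:
        logger.warning("no markers detected; metrics will stay in pixels")
        return ScaleCalibration(None, [], marker_diameter_cm, 0)
    med = float(np.median(diameters))
    kept = [d for d in diameters if abs(d - med) <= outlier_frac * med]
    for d in diameters:
        if abs(d - med) > outlier_frac * med:
            logger.info("excluding marker with diameter %.1f px "
                        "(>%.0f%% from median %.1f px)", d, 100 * outlier_frac, med)
    px_per_cm = float(np.median(kept)) / marker_diameter_cm
    return ScaleCalibration(px_per_cm, diameters, marker_diameter_cm, len(kept))


def to_cm(metrics, cal: ScaleCalibration):
    """Convert ShapeMetrics from px to cm; dimensionless fields unchanged."""
    if not cal.calibrated:
        raise ValueError("cannot convert to cm: calibration has no markers")
    return metrics_to_cm(metrics, cal.px_per_cm)


def assign_grid(centroids, mask_heights):
    """Assign 1-based (row, col) positions from centroid coordinates.

    Centroids are sorted by y; a new row starts whenever the y-gap between
    consecutive centroids exceeds half the median mask height. Within each
    row, columns follow ascending x. Invariant to the input order of berries
    within a row. Ambiguous row splits (gap within 20% of the threshold) are
    logged.
    """
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) == 0:
        raise ValueError("need at least one centroid")
    threshold = 0.5 * float(np.median(mask_heights))
    order = np.argsort(centroids[:, 1], kind="stable")
    rows: list[list[int]] = [[order[0]]]
    for prev, cur in zip(order[:-1], order[1:]):
        gap = centroids[cur, 1] - centroids[prev, 1]
        if gap > threshold:
            rows.append([cur])
        elif gap > 0.8 * threshold:
            logger.warning("ambiguous row break: y-gap %.1f px is close to "
                           "the threshold %.1f px", gap, threshold)
            rows[-1].append(cur)
        else:
            rows[-1].append(cur)
    positions = [None] * len(centroids)
    n_cols = 0
    for r, members in enumerate(rows, start=1):
        members = sorted(members, key=lambda i: centroids[i, 0])
        n_cols = max(n_cols, len(members))
        for c, i in enumerate(members, start=1):
            positions[i] = (r, c)
    return GridAssignment(positions=positions, n_rows=len(rows), n_cols=n_cols)


def reciprocal_match(centroids_a, centroids_b):
    """Match two centroid sets by reciprocal nearest neighbors.

    Pair (i, j) is reported iff b_j is the closest B-point to a_i AND a_i is
    the closest A-point to b_j (ties broken by lowest index). There is no
    maximum-distance cutoff; distances are returned so callers can filter.

    Returns
    -------
    (pairs, unmatched_a, unmatched_b, distances)
        pairs: list of (i, j); distances: matching Euclidean distances.
    """
    A = np.atleast_2d(np.asarray(centroids_a, dtype=float))
    B = np.atleast_2d(np.asarray(centroids_b, dtype=float))
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both centroid sets must be nonempty")
    d = cdist(A, B)
    a_best = d.argmin(axis=1)
    b_best = d.argmin(axis=0)
    pairs, dists = [], []
    for i, j in enumerate(a_best):
        if b_best[j] == i:
            pairs.append((i, int(j)))
            dists.append(float(d[i, j]))
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    unmatched_a = [i for i in range(len(A)) if i not in matched_a]
    unmatched_b = [j for j in range(len(B)) if j not in matched_b]
    return pairs, unmatched_a, unmatched_b, dists
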