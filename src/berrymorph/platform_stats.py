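"""Platform-agreement statistics for paired berry measurements.

When the same fruit are measured by two platforms (e.g. this pipeline and an
older tool), matched 1-to-1 by reciprocal nearest centroids, per-trait
agreement is summarized by the mean paired difference, the range-normalized
mean difference (rmd), the Pearson correlation, and a paired t-test.

rmd_t = mean(x_i - y_i) / min(max(x) - min(x), max(y) - min(y))

normalizes the mean difference by the smaller within-platform trait range,
placing traits of different scales on a comparable footing. The sign
convention is x (this implementation) minus y (the reference platform).
p values are reported unadjusted; with many matched berries even trivially
small differences reach significance, so effect size (rmd) is the quantity
to read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layout_calibration import reciprocal_match


@dataclass
class TraitComparison:
    """Agreement statistics for one trait across two platforms."""

    trait: str
    n: int
    mean_x: float
    mean_y: float
    min_x: float
    max_x: float
    min_y: float
    max_y: float
    mean_diff: float
    rmd: float
    pearson_r: float
    t_stat: float
    p_value: float
    ci_x: tuple[float, float]
    ci_y: tuple[float, float]


def rmd(x, y):
    """Range-normalized mean difference of paired samples.

    Mean of (x_i - y_i) divided by the smaller of the two within-platform
    ranges. Undefined (raises) when either range is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be paired 1-D samples of length >= 2")
    rx = x.max() - x.min()
    ry = y.max() - y.min()
    if rx <= 0 or ry <= 0:
        raise ValueError("rmd is undefined when a platform's range is zero")
    return float(np.mean(x - y) / min(rx, ry))


def _mean_ci(v, level=0.95):
    n = len(v)
    se = v.std(ddof=1) / np.sqrt(n)
    if se == 0:
        return float(v.mean()), float(v.mean())
    half = stats.t.ppf(0.5 + level / 2, n - 1) * se
    return float(v.mean() - half), float(v.mean() + half)


def compare_traits(matched: pd.DataFrame, traits,
                   suffixes=("_x", "_y")) -> list[TraitComparison]:
    """Per-trait agreement statistics over a matched table.

    ``matched`` must contain ``<trait><suffix>`` columns for each trait and
    platform (the output of :func:`match_tables`). The paired t-test is run
    on the per-berry differences; confidence intervals are t-based 95%
    intervals of each platform's mean.
    """
    out = []
    for trait in traits:
        x = matched[f"{trait}{suffixes[0]}"].to_numpy(dtype=float)
        y = matched[f"{trait}{suffixes[1]}"].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if len(x) < 2:
            raise ValueError(f"trait {trait!r}: need >= 2 matched pairs")
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        d = x - y
        if np.allclose(d, d[0]):
            t_stat, p = (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
        else:
            res = stats.ttest_rel(x, y)
            t_stat, p = float(res.statistic), float(res.pvalue)
        out.append(TraitComparison(
            trait=trait, n=len(x),
            mean_x=float(x.mean()), mean_y=float(y.mean()),
            min_x=float(x.min()), max_x=float(x.max()),
            min_y=float(y.min()), max_y=float(y.max()),
            mean_diff=float(d.mean()), rmd=rmd(x, y), pearson_r=r,
            t_stat=t_stat, p_value=p,
            ci_x=_mean_ci(x), ci_y=_mean_ci(y),
        ))
    return out


def match_tables(df_x: pd.DataFrame, df_y: pd.DataFrame, image_col="image_id",
                 cx_col="centroid_x", cy_col="centroid_y"):
    """Join two measurement tables by reciprocal-nearest centroids per image.

    Both tables need at least an image identifier and centroid x/y columns;
    shared numeric columns are suffixed ``_x`` / ``_y`` in the result.
    """
    chunks = []
    for image_id in sorted(set(df_x[image_col]) & set(df_y[image_col])):
        a = df_x[df_x[image_col] == image_id].reset_index(drop=True)
        b = df_y[df_y[image_col] == image_id].reset_index(drop=True)
        pairs, _, _, dists = reciprocal_match(
            a[[cx_col, cy_col]].to_numpy(), b[[cx_col, cy_col]].to_numpy())
        ia = [i for i, _ in pairs]
        ib = [j for _, j in pairs]
        joined = a.loc[ia].reset_index(drop=True).add_suffix("_x").join(
            b.loc[ib].reset_index(drop=True).add_suffix("_y"))
        joined.insert(0, image_col, image_id)
        joined["match_distance_px"] = dists
        chunks.append(joined)
    if not chunks:
        raise ValueError("no shared images between the two tables")
    return pd.concat(chunks, ignore_index=True)


def comparison_report(comparisons, path=None):
    """Tabulate comparisons as two rows per trait (platforms x and y).

    Columns: trait, platform, mean, min, max, LCI, UCI, md, rmd, r; the
    agreement statistics (md, rmd, r) are printed on the first platform's
    row. Returns the DataFrame; writes CSV when ``path`` is given.
    """
    rows = []
    for c in comparisons:
        rows.append({
            "trait": c.trait, "platform": "x", "mean": c.mean_x,
            "min": c.min_x, "max": c.max_x,
            "LCI": c.ci_x[0], "UCI": c.ci_x[1],
            "md": c.mean_diff, "rmd": c.rmd, "r": c.pearson_r,
        })
        rows.append({
            "trait": c.trait, "platform": "y", "mean": c.mean_y,
            "min": c.min_y, "max": c.max_y,
            "LCI": c.ci_y[0], "UCI": c.ci_y[1],
            "md": None, "rmd": None, "r": None,
        })
    df = pd.DataFrame(rows, columns=["trait", "platform", "mean", "min", "max",
                                     "LCI", "UCI", "md", "rmd", "r"])
    if path is not None:
        df.to_csv(path, index=False, float_format="%.6g", lineterminator="\r\n")
    return df
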