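"""Buffer-based validation of CHM heights against field-measured heights.

Each field point is paired with the maximum CHM value over pixels whose
centres lie within a buffer radius (1 m by default) of the recorded stem
position — the buffer absorbs GNSS error without requiring tree-identity
matching.  The paired heights then go through a Pearson correlation test:

    r = sum (x_i - xbar)(y_i - ybar) / sqrt(sum (x_i - xbar)^2 sum (y_i - ybar)^2)
    t = r sqrt((n - 2) / (1 - r^2)),  p two-sided from Student t, n - 2 dof

with ordinary-least-squares slope/intercept of field height on CHM height,
the fit's residual RMSE, and the mean bias (chm - field) as diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .raster import Grid
from .scene import FieldPoint


@dataclass
class PairedHeights:
    point_id: int
    field_height: float
    chm_height: float
    n_buffer_pixels: int


@dataclass
class ValidationResult:
    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    rmse: float
    bias: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r out of [-1, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0, 1]")


def buffer_max_height(chm: Grid, points: list[FieldPoint], radius_m: float = 1.0
                      ) -> tuple[list[PairedHeights], int]:
    """Pair each field point with the CHM maximum within ``radius_m``.

    Membership is by pixel-centre Euclidean distance (<= radius_m), the
    same convention as the zonal statistics.  Points with no valid pixel
    in the buffer are excluded; the exclusion count is returned.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be > 0")
    t = chm.transform
    nrows, ncols = chm.shape
    pairs: list[PairedHeights] = []
    n_excluded = 0
    for p in points:
        c0 = max(0, int(np.floor((p.x - radius_m - t.x_origin) / t.pixel_width - 0.5)))
        c1 = min(ncols - 1, int(np.ceil((p.x + radius_m - t.x_origin) / t.pixel_width - 0.5)))
        r0 = max(0, int(np.floor((p.y + radius_m - t.y_origin) / t.pixel_height - 0.5)))
        r1 = min(nrows - 1, int(np.ceil((p.y - radius_m - t.y_origin) / t.pixel_height - 0.5)))
        if c0 > c1 or r0 > r1:
            n_excluded += 1
            continue
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        xc = t.x_origin + (cols + 0.5) * t.pixel_width
        yc = t.y_origin + (rows + 0.5) * t.pixel_height
        X, Y = np.meshgrid(xc, yc)
        inside = (X - p.x) ** 2 + (Y - p.y) ** 2 <= radius_m ** 2
        vals = chm.values[rows[:, None], cols[None, :]][inside]
        if chm.nodata is not None:
            vals = vals[vals != chm.nodata]
        if vals.size == 0:
            n_excluded += 1
            continue
        pairs.append(PairedHeights(point_id=p.id, field_height=p.height_m,
                                   chm_height=float(vals.max()), n_buffer_pixels=int(vals.size)))
    return pairs, n_excluded


def pearson_test(pairs: list[PairedHeights]) -> ValidationResult:
    """Pearson correlation test between CHM and field heights.

    x = CHM buffer-max height, y = field-measured height; requires n >= 3
    and both variables non-constant.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError("need >= 3 pairs for a correlation test")
    x = np.array([p.chm_height for p in pairs], dtype=np.float64)
    y = np.array([p.field_height for p in pairs], dtype=np.float64)
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise ValueError("Pearson r undefined: a variable is constant")
    sxy = float(dx @ dy)
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = float(2 * sps.t.sf(abs(tstat), df=n - 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    bias = float(np.mean(x - y))
    return ValidationResult(n=n, pearson_r=r, p_value=p, slope=float(slope),
                            intercept=intercept, rmse=rmse, bias=bias)


def validation_report(result: ValidationResult, pairs: list[PairedHeights]
                      ) -> tuple[dict, pd.DataFrame]:
    """Machine-readable summary plus the per-pair table for plotting."""
    table = pd.DataFrame([{
        "point_id": p.point_id, "field_height_m": p.field_height,
        "chm_height_m": p.chm_height, "n_buffer_pixels": p.n_buffer_pixels,
    } for p in pairs])
    report = {
        "n": result.n,
        "pearson_r": result.pearson_r,
        "p_value": result.p_value,
        "slope": result.slope,
        "intercept": result.intercept,
        "rmse_m": result.rmse,
        "bias_m": result.bias,
        "n_excluded": result.n_excluded,
    }
    return report, table


def scatter_plot(pairs: list[PairedHeights], result: ValidationResult, path) -> str:
    """Write a field-vs-CHM scatter with the fitted line annotated."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.chm_height for p in pairs])
    y = np.array([p.field_height for p in pairs])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=14, alpha=0.7)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.slope * xs + result.intercept, "r-", lw=1)
    ax.set_xlabel("CHM buffer-max height (m)")
    ax.set_ylabel("Field-measured height (m)")
    p_txt = "< 0.0001" if result.p_value < 1e-4 else f"= {result.p_value:.3g}"
    ax.set_title(f"r = {result.pearson_r:.3f}, p {p_txt}, n = {result.n}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
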