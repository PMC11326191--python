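"""Puncta SNR, per-cell signal totals, and population statistics.

Per-cell QDF puncta signal follows the threshold-mask definition: a mask at
4x the 99th percentile of the image's background selects puncta pixels, and
the signal of a cell is the QDF sum over (cell label ∩ mask).  Noise is the
standard deviation of the background outside masked cells, and SNR is the
masked mean divided by that noise.  Population relationships (signal per
mass vs mass per area) are summarised by Pearson correlation and a
least-squares linear fit tested against the intercept-only model with an
F-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = ["RegressionReport", "puncta_mask", "cell_snr", "per_cell_totals",
           "pearson", "linreg_ftest", "binned_scatter", "background_pixels_mask"]


@dataclass(frozen=True)
class RegressionReport:
    """Least-squares line vs intercept-only null, with correlation."""

    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    pearson_r: float
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value must lie in [0, 1]")
        if abs(self.pearson_r) > 1.0 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def background_pixels_mask(labels: np.ndarray, dilation_px: int = 5) -> np.ndarray:
    """Background = complement of the union of cell labels dilated by a margin."""
    structure = ndimage.generate_binary_structure(2, 2)
    fg = np.asarray(labels) > 0
    if fg.any() and dilation_px > 0:
        fg = ndimage.binary_dilation(fg, structure, iterations=dilation_px)
    return ~fg


def puncta_mask(
    qdf: np.ndarray,
    background_pixels: np.ndarray,
    k: float = 4.0,
    q: float = 99.0,
    min_background: int = 1000,
) -> np.ndarray:
    """Threshold mask at ``k`` times the ``q``-th percentile of the background.

    The threshold is recomputed per image from the pixels flagged as
    background; percentiles use linear interpolation between order statistics.
    """
    qdf = np.asarray(qdf, dtype=float)
    background_pixels = np.asarray(background_pixels, dtype=bool)
    if qdf.shape != background_pixels.shape:
        raise ValueError("qdf and background_pixels must share a shape")
    bg = qdf[background_pixels]
    if bg.size < min_background:
        raise ValueError(f"need >= {min_background} background pixels, got {bg.size}")
    threshold = k * np.percentile(bg, q)
    return qdf > threshold


def cell_snr(
    qdf: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    background_pixels: np.ndarray,
) -> tuple[pd.Series, float, float]:
    """Per-cell puncta SNR plus the population mean ± std.

    SNR of a cell is the mean QDF over (label ∩ mask) divided by the standard
    deviation of the background; cells whose intersection with the mask is
    empty get NaN.  Returns ``(per_cell_series, mean, std)`` over cells with
    defined SNR.
    """
    qdf = np.asarray(qdf, dtype=float)
    labels = np.asarray(labels)
    noise = float(np.std(qdf[np.asarray(background_pixels, dtype=bool)]))
    if noise == 0:
        raise ValueError("degenerate image: zero background standard deviation")
    ids = range(1, int(labels.max()) + 1)
    values = {}
    for i in ids:
        sel = (labels == i) & mask
        values[i] = float(qdf[sel].mean()) / noise if sel.any() else np.nan
    series = pd.Series(values, name="snr", dtype=float)
    series.index.name = "label"
    defined = series.dropna()
    if defined.empty:
        raise ValueError("no cell intersects the puncta mask")
    return series, float(defined.mean()), float(defined.std(ddof=1)) if len(defined) > 1 else 0.0


def per_cell_totals(
    qdf: np.ndarray,
    df: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell integrated signals: plain label sums and mask-intersected sums.

    ``total_df``/``total_qdf`` are pixel sums over each label (background
    excluded).  When a puncta ``mask`` is given, ``puncta_df``/``puncta_qdf``
    sum only over (label ∩ mask) — the threshold-mask definition of a cell's
    puncta signal.
    """
    qdf = np.asarray(qdf, dtype=float)
    df = np.asarray(df, dtype=float)
    labels = np.asarray(labels)
    if not (qdf.shape == df.shape == labels.shape):
        raise ValueError("qdf, df and labels must be co-registered (same shape)")
    nmax = int(labels.max())
    ids = np.arange(1, nmax + 1)
    if nmax == 0:
        return pd.DataFrame(columns=["total_df", "total_qdf", "puncta_df", "puncta_qdf"],
                            index=pd.Index([], name="label"))
    out = pd.DataFrame(index=pd.Index(ids, name="label"))
    out["total_df"] = ndimage.sum_labels(df, labels, ids)
    out["total_qdf"] = ndimage.sum_labels(qdf, labels, ids)
    if mask is not None:
        masked_labels = np.where(np.asarray(mask, dtype=bool), labels, 0)
        out["puncta_df"] = ndimage.sum_labels(df, masked_labels, ids)
        out["puncta_qdf"] = ndimage.sum_labels(qdf, masked_labels, ids)
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def linreg_ftest(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> RegressionReport:
    """Least-squares line y = a + b*x tested against the constant model.

    F = (RSS0 - RSS1) / (RSS1 / (n - 2)) with RSS0 the residual sum of squares
    of the intercept-only fit and RSS1 that of the line; p from F(1, n-2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    sx = float(np.sum((x - x.mean()) ** 2))
    if sx == 0:
        raise ValueError("degenerate x: all values equal")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sx)
    intercept = float(y.mean() - slope * x.mean())
    rss1 = float(np.sum((y - intercept - slope * x) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    dof = n - 2
    if rss1 == 0:
        f = np.inf
        p = 0.0
    else:
        f = (rss0 - rss1) / (rss1 / dof)
        p = float(stats.f.sf(f, 1, dof))
    r = float(stats.pearsonr(x, y).statistic) if np.std(y) > 0 else 0.0
    return RegressionReport(slope=slope, intercept=intercept, f_statistic=float(f),
                            p_value=p, pearson_r=r, n=n, alpha=alpha)


def binned_scatter(
    x: np.ndarray,
    y: np.ndarray,
    bin_width: float,
    origin: float = 0.0,
) -> pd.DataFrame:
    """Per-bin mean and standard deviation of y over half-open x bins.

    Bins are ``[lo, lo + bin_width)`` anchored at ``origin``; a point exactly
    on an edge belongs to the upper bin.  Empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    idx = np.floor((x - origin) / bin_width).astype(int)
    frame = pd.DataFrame({"bin": idx, "y": y})
    grouped = frame.groupby("bin")["y"]
    out = pd.DataFrame({
        "bin_lo": grouped.mean().index * bin_width + origin,
        "mean": grouped.mean().to_numpy(),
        "std": grouped.std(ddof=1).to_numpy(),
        "n": grouped.size().to_numpy(),
    }).reset_index(drop=True)
    out["bin_hi"] = out["bin_lo"] + bin_width
    return out[["bin_lo", "bin_hi", "mean", "std", "n"]]
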