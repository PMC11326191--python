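"""Single-cell segmentation, time-lapse track linking, and debris filtering.

Segmentation is watershed-based: Otsu foreground on the smoothed phase image,
markers from h-maxima seed suppression, watershed on the inverted phase
restricted to the foreground.  Tracking realises Crocker–Grier linking as a
per-frame-pair optimal assignment: the matching minimises total squared
displacement, with a hard displacement gate and a fixed cost for starting or
ending a track, solved exactly by the Hungarian algorithm on an augmented
cost matrix.  Debris removal applies per-metric min/max thresholds to the
cell table and logs a per-criterion report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage import filters, measure, morphology, segmentation

logger = logging.getLogger(__name__)

__all__ = ["CellLabelMap", "CellTrack", "segment_cells", "link_tracks", "filter_debris"]


@dataclass
class CellLabelMap:
    """Labelled segmentation of one frame; label 0 is background."""

    labels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def foreground(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class CellTrack:
    """One tracked object: (frame, object index, x_um, y_um) observations."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    indices: list[int] = field(default_factory=list)  # object index within each frame
    centroids_um: list[tuple[float, float]] = field(default_factory=list)

    def add(self, frame: int, index: int, centroid: tuple[float, float]) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("track observations must be strictly increasing in frame")
        self.frames.append(frame)
        self.indices.append(index)
        self.centroids_um.append((float(centroid[0]), float(centroid[1])))

    def __len__(self) -> int:
        return len(self.frames)


def segment_cells(
    phase: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 20.0,
    h_depth: float = 0.3,
    smooth_sigma_um: float = 1.0,
    min_phase: float = 0.1,
    frame_index: int = 0,
    threshold_mode: str = "floor",
) -> CellLabelMap:
    """Watershed segmentation of cells from a background-corrected phase image.

    Foreground thresholding has two modes.  ``"floor"`` (default) keeps every
    pixel above ``min_phase`` radians — appropriate for background-corrected
    phase, where ``min_phase`` sits a few sigma above the noise floor and the
    dim skirt of tall rounded cells is retained (an Otsu split between a
    bright apex and the background would truncate it and bias dry mass low).
    ``"otsu"`` uses ``max(Otsu, min_phase)``, useful on uncorrected phase
    where a smooth background would defeat a fixed floor.  Seeds are h-maxima
    of the smoothed phase with suppression depth ``h_depth`` (radians);
    touching cells are split by a watershed on the inverted smoothed phase;
    components smaller than ``min_area_um2`` are dropped.
    """
    phase = np.asarray(phase, dtype=float)
    smoothed = filters.gaussian(phase, sigma=smooth_sigma_um / pixel_size_um,
                                preserve_range=True)
    if smoothed.max() - smoothed.min() < min_phase:
        logger.warning("segment_cells: no signal above %.3g rad; returning empty map", min_phase)
        return CellLabelMap(np.zeros(phase.shape, dtype=np.int32), frame_index)
    if threshold_mode == "otsu":
        thresh = max(float(filters.threshold_otsu(smoothed)), min_phase)
    elif threshold_mode == "floor":
        thresh = min_phase
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    fg = smoothed > thresh
    if not fg.any():
        logger.warning("segment_cells: empty foreground")
        return CellLabelMap(np.zeros(phase.shape, dtype=np.int32), frame_index)

    seeds = morphology.h_maxima(smoothed, h_depth)
    seeds &= fg
    if not seeds.any():
        seeds = fg  # degenerate: one basin
    markers = measure.label(seeds, connectivity=2)
    labels = segmentation.watershed(-smoothed, markers=markers, mask=fg, connectivity=1)

    min_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    counts = np.bincount(labels.ravel())
    too_small = counts < min_px
    too_small[0] = False
    labels[too_small[labels]] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return CellLabelMap(labels.astype(np.int32), frame_index)


def _assignment(prev: np.ndarray, cur: np.ndarray, max_disp: float) -> list[tuple[int, int]]:
    """Optimal gated matching between two point sets (Crocker–Grier cost).

    Cost of a link is the squared displacement; leaving a point unmatched
    costs ``max_disp**2``; links longer than ``max_disp`` are infeasible.
    Returns (prev_index, cur_index) pairs of the optimal matching.
    """
    n, m = len(prev), len(cur)
    if n == 0 or m == 0:
        return []
    big = 1e30
    l2 = max_disp**2
    d2 = np.sum((prev[:, None, :] - cur[None, :, :]) ** 2, axis=-1)
    cost = np.full((n + m, m + n), 0.0)
    cost[:n, :m] = np.where(d2 <= l2, d2, big)
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), l2, big)  # track ends
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), l2, big)  # track starts
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if r < n and c < m and d2[r, c] <= l2]


def link_tracks(
    centroids_per_frame: list[np.ndarray],
    max_disp: float,
    memory: int = 0,
) -> list[CellTrack]:
    """Link per-frame centroids into tracks (Crocker–Grier linking).

    Each consecutive assignment is the global minimiser of total squared
    displacement over feasible one-to-one matchings with a ``max_disp`` gate;
    unmatched objects end or start tracks.  With ``memory > 0`` a track that
    misses up to that many frames may be resumed.  Results are independent of
    the input ordering of objects within a frame (points are canonically
    sorted internally; ties in position are broken by input index).
    """
    if len(centroids_per_frame) < 1:
        raise ValueError("need at least one frame")
    if memory < 0:
        raise ValueError("memory must be nonnegative")

    tracks: list[CellTrack] = []
    # active: list of (track, last_frame, last_position)
    active: list[list] = []

    for t, pts in enumerate(centroids_per_frame):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        order = np.lexsort((np.arange(len(pts)), pts[:, 1], pts[:, 0]))
        pts_sorted = pts[order]

        candidates = [a for a in active if t - a[1] <= memory + 1]
        prev_pos = np.array([a[2] for a in candidates]).reshape(-1, 2)
        links = _assignment(prev_pos, pts_sorted, max_disp)
        matched_prev = {r for r, _ in links}
        matched_cur = {c for _, c in links}

        for r, c in sorted(links, key=lambda rc: rc[1]):
            track = candidates[r][0]
            idx = int(order[c])
            track.add(t, idx, tuple(pts_sorted[c]))
            candidates[r][1] = t
            candidates[r][2] = pts_sorted[c]
        for c in range(len(pts_sorted)):
            if c not in matched_cur:
                track = CellTrack(track_id=len(tracks))
                idx = int(order[c])
                track.add(t, idx, tuple(pts_sorted[c]))
                tracks.append(track)
                active.append([track, t, pts_sorted[c]])
        active = [a for a in active if t - a[1] <= memory]
        _ = matched_prev  # candidates not matched simply age out of `active`
    return tracks


def filter_debris(
    table: pd.DataFrame,
    thresholds: dict[str, tuple[float | None, float | None]],
    return_report: bool = False,
):
    """Remove debris rows by per-metric (min, max) bounds.

    ``thresholds`` maps a column name of the cell table (e.g. ``area_um2``,
    ``track_length``, ``mean_phase``, ``mean_df``, ``mean_qdf``) to a
    ``(min, max)`` pair; either bound may be ``None``.  Rows must satisfy every
    bound to survive.  A per-criterion rejection count is logged (and returned
    when ``return_report`` is set).
    """
    unknown = [k for k in thresholds if k not in table.columns]
    if unknown:
        raise ValueError(f"unknown debris-filter metrics: {unknown}; available: {list(table.columns)}")
    keep = pd.Series(True, index=table.index)
    report = {}
    for metric, (lo, hi) in thresholds.items():
        ok = pd.Series(True, index=table.index)
        if lo is not None:
            ok &= table[metric] >= lo
        if hi is not None:
            ok &= table[metric] <= hi
        report[metric] = int((~ok).sum())
        keep &= ok
    logger.info("filter_debris: kept %d/%d rows; rejections per criterion: %s",
                int(keep.sum()), len(table), report)
    filtered = table[keep].copy()
    if return_report:
        return filtered, report
    return filtered
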