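"""Aggregate size-distribution and coarsening statistics.

Per-cell complementary cumulative distribution functions (CCDF, the
empirical survival function of object size) averaged across cells with a
standard error; aggregation propensity versus concentration; the
condensation/dissolution cycle analysis (mean small-aggregate area at the
first frame of each condensation cycle); and the bulk-intensity
conservation trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CellROI, ConfigurationError, ImageStack, PipelineConfig
from .segment import (
    auto_background_region,
    compute_threshold,
    estimate_background,
    measure_objects,
    segment_2d,
    select_reference_frame,
)


@dataclass
class CCDFCurve:
    """Cross-cell-averaged survival function of aggregate size."""

    size_um2: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_cells: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size_um2": self.size_um2, "mean_survival": self.mean,
            "se": self.se, "n_cells": self.n_cells,
        })


def _survival(sorted_sizes: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """P(S >= s) for each grid point; exact empirical survival function."""
    n = sorted_sizes.size
    # count of sizes >= s  ==  n - (number strictly below s)
    below = np.searchsorted(sorted_sizes, grid, side="left")
    return (n - below) / n


def ccdf_per_cell(sizes) -> pd.DataFrame:
    """Empirical survival function of one cell's aggregate sizes.

    Evaluated at the sorted unique sizes: P(S >= s) = #{sizes >= s} / n.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("cell has no aggregates; it contributes nothing")
    s = np.sort(sizes)
    grid = np.unique(s)
    return pd.DataFrame({"size_um2": grid, "survival": _survival(s, grid)})


def ccdf_average(cells: list) -> CCDFCurve:
    """Average per-cell CCDFs on the union grid of observed sizes.

    Each cell's empirical survival function is evaluated exactly at every
    union-grid point (the right-continuous step rule: a cell with all sizes
    above s contributes 1, all below contributes 0).  SE = SD / sqrt(n_cells)
    pointwise.
    """
    if len(cells) < 2:
        raise ValueError("need >= 2 cells for an SE")
    sorted_cells = [np.sort(np.asarray(c, dtype=float)) for c in cells]
    for c in sorted_cells:
        if c.size == 0:
            raise ValueError("every contributing cell needs >= 1 aggregate")
    grid = np.unique(np.concatenate(sorted_cells))
    surv = np.vstack([_survival(c, grid) for c in sorted_cells])
    mean = surv.mean(axis=0)
    se = surv.std(axis=0, ddof=1) / np.sqrt(len(cells))
    return CCDFCurve(size_um2=grid, mean=mean, se=se, n_cells=len(cells))


def aggregation_propensity(cells: pd.DataFrame, bin_edges) -> pd.DataFrame:
    """Fraction of cells showing >= 1 aggregate, binned by concentration.

    ``cells`` needs columns ``concentration_uM`` and ``n_aggregates``.
    Empty bins are reported with fraction NaN (undefined), not 0.
    """
    edges = np.asarray(bin_edges, dtype=float)
    conc = cells["concentration_uM"].to_numpy()
    if conc.min() < edges[0] or conc.max() > edges[-1]:
        raise ValueError("bin edges do not cover the data")
    has_agg = cells["n_aggregates"].to_numpy() >= 1
    idx = np.clip(np.digitize(conc, edges) - 1, 0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = idx == b
        n = int(sel.sum())
        rows.append({
            "bin_left_uM": edges[b],
            "bin_right_uM": edges[b + 1],
            "fraction_aggregating": float(has_agg[sel].mean()) if n else np.nan,
            "n_cells": n,
        })
    return pd.DataFrame(rows)


def cycle_first_frames(stack: ImageStack) -> list[int]:
    """First frame index of each condensation (light-on) interval."""
    return [a for a, _ in stack.light_schedule]


def cycle_coarsening(
    stack: ImageStack,
    roi: CellROI,
    config: PipelineConfig | None = None,
    channel: str | int = "polyQ",
) -> pd.DataFrame:
    """Mean small-aggregate area at the first frame of each condensation cycle.

    The aggregate channel is thresholded at background mean + k SD measured
    once on the reference frame (the same threshold applied to every cycle
    frame) and objects below ``small_agg_cutoff_um2`` are averaged.  One row
    per cycle, indexed from 1.
    """
    config = config or PipelineConfig()
    if len(stack.light_schedule) < 2:
        raise ConfigurationError("need >= 2 condensation intervals for a cycle analysis")
    firsts = cycle_first_frames(stack)
    if max(firsts) >= stack.n_frames:
        raise ConfigurationError("light schedule exceeds stack length")
    ref = select_reference_frame(stack, roi, channel)
    ref_frame = stack.frame(ref, channel)
    bg = auto_background_region(ref_frame, roi, stack.pixel_size_um)
    mean, sd = estimate_background(ref_frame, bg)
    thr = compute_threshold(mean, sd, config.threshold_k)
    rows = []
    for i, t in enumerate(firsts, start=1):
        labeled = segment_2d(stack.frame(t, channel), roi, thr, config.min_area_px)
        rec = measure_objects(labeled, stack.pixel_size_um)
        areas = rec["area_um2"].to_numpy()
        small = areas[areas < config.small_agg_cutoff_um2]
        rows.append({
            "cycle": i,
            "frame": t,
            "mean_small_area_um2": float(small.mean()) if small.size else np.nan,
            "n_small": int(small.size),
            "n_objects": int(areas.size),
        })
    return pd.DataFrame(rows)


def cycle_report(per_cell: list[pd.DataFrame]) -> pd.DataFrame:
    """Average the per-cell cycle tables across cells (mean, SE, n per cycle)."""
    if not per_cell:
        raise ValueError("no cells")
    cat = pd.concat(per_cell, keys=range(len(per_cell)), names=["cell"])
    g = cat.groupby("cycle")["mean_small_area_um2"]
    out = pd.DataFrame({
        "mean_small_area_um2": g.mean(),
        "se": g.std(ddof=1) / np.sqrt(g.count()),
        "n_cells": g.count(),
    }).reset_index()
    return out


def bulk_intensity_trace(stack: ImageStack, roi: CellROI, channel: str | int, z: int = 0) -> np.ndarray:
    """Total channel intensity within the ROI per frame, normalized to frame 0.

    A value pinned near 1 means the signal is conserved — objects are being
    reorganized, not created or destroyed.
    """
    if stack.n_frames < 2:
        raise ValueError("need >= 2 frames")
    ci = stack.channel_index(channel)
    sums = stack.data[:, z, ci][:, roi.mask].sum(axis=1)
    if sums[0] == 0:
        raise ValueError("frame-0 intensity sum is zero; cannot normalize")
    return sums / sums[0]
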