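"""Intensity-threshold segmentation with physical-unit object measurements.

The procedure: pick the reference frame with the maximum mean cytoplasmic
brightness, estimate background mean and SD in a condensate/aggregate-free
cytoplasmic region, threshold every frame at ``mean + k * SD`` (default
k = 2.5), keep 8-connected (2D) / 26-connected (3D) components of at least
16 pixels / 64 voxels, and report per-object geometry and per-channel
integrated intensities in micrometre units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .datamodel import CellROI, ConfigurationError, ImageStack

OBJECT_COLUMNS_2D = [
    "object_id", "n_px", "area_um2", "centroid_y_um", "centroid_x_um",
    "equivalent_radius_um", "perimeter_um", "circularity",
]
OBJECT_COLUMNS_3D = [
    "object_id", "n_vox", "volume_um3", "centroid_z_um", "centroid_y_um",
    "centroid_x_um", "equivalent_radius_um",
]


@dataclass
class LabeledObjects:
    """Label image (0 = background, labels contiguous from 1) plus records."""

    labels: np.ndarray
    records: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def select_reference_frame(stack: ImageStack, roi: CellROI, channel: str | int, z: int = 0) -> int:
    """Frame with the maximum mean cytoplasmic brightness; ties break earliest."""
    if not roi.mask.any():
        raise ValueError("ROI is empty")
    ci = stack.channel_index(channel)
    means = stack.data[:, z, ci][:, roi.mask].mean(axis=1)
    return int(np.argmax(means))


def estimate_background(frame: np.ndarray, region: CellROI | np.ndarray) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of intensities in the region."""
    mask = region.mask if isinstance(region, CellROI) else np.asarray(region, dtype=bool)
    vals = np.asarray(frame, dtype=float)[mask]
    if vals.size < 2:
        raise ValueError("background region needs at least 2 pixels (SD undefined)")
    return float(vals.mean()), float(vals.std(ddof=1))


def compute_threshold(mean: float, sd: float, k: float = 2.5) -> float:
    """Background mean plus ``k`` standard deviations."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return mean + k * sd


def auto_background_region(
    frame: np.ndarray,
    roi: CellROI,
    pixel_size_um: float,
    tile_um: float = 2.0,
) -> CellROI:
    """Automatic proxy for a cytoplasmic region free of bright objects.

    The ROI is tiled into ``tile_um`` x ``tile_um`` squares; among tiles
    lying fully inside the ROI whose 99th-percentile intensity stays below
    the ROI median + 1 SD (i.e. containing no bright structure), the one
    with the lowest mean is selected.  Falls back to the lowest-mean tile
    if no tile passes the brightness screen.
    """
    frame = np.asarray(frame, dtype=float)
    tile_px = max(2, int(round(tile_um / pixel_size_um)))
    roi_vals = frame[roi.mask]
    ceiling = float(np.median(roi_vals) + roi_vals.std(ddof=1))
    ys, xs = np.nonzero(roi.mask)
    best = None  # (passes_screen, mean, (y0, x0))
    for y0 in range(ys.min(), ys.max() - tile_px + 2, tile_px):
        for x0 in range(xs.min(), xs.max() - tile_px + 2, tile_px):
            sub_mask = roi.mask[y0:y0 + tile_px, x0:x0 + tile_px]
            if sub_mask.shape != (tile_px, tile_px) or not sub_mask.all():
                continue
            tile = frame[y0:y0 + tile_px, x0:x0 + tile_px]
            passes = float(np.percentile(tile, 99)) < ceiling
            key = (not passes, float(tile.mean()))
            if best is None or key < best[0]:
                best = (key, (y0, x0))
    if best is None:
        raise ValueError("ROI too small to hold one background tile")
    y0, x0 = best[1]
    mask = np.zeros_like(roi.mask)
    mask[y0:y0 + tile_px, x0:x0 + tile_px] = True
    return CellROI(cell_id=f"{roi.cell_id}-bg", mask=mask, provenance="auto")


def _relabel(binary: np.ndarray, connectivity: int, min_size: int) -> np.ndarray:
    labels = measure.label(binary, connectivity=connectivity)
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    keep = np.nonzero(counts[1:] >= min_size)[0] + 1
    lut = np.zeros(counts.size, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1)
    return lut[labels]


def segment_2d(frame: np.ndarray, roi: CellROI | np.ndarray | None, threshold: float,
               min_area_px: int = 16) -> LabeledObjects:
    """Threshold one 2D frame and keep 8-connected components >= ``min_area_px``.

    Pixels strictly above the threshold and inside the ROI are foreground.
    An empty result is valid.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    frame = np.asarray(frame, dtype=float)
    binary = frame > threshold
    if roi is not None:
        mask = roi.mask if isinstance(roi, CellROI) else np.asarray(roi, dtype=bool)
        binary &= mask
    labels = _relabel(binary, connectivity=2, min_size=min_area_px)
    ids = np.arange(1, labels.max() + 1)
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)[1:]
    records = pd.DataFrame({"object_id": ids, "n_px": counts.astype(int)})
    return LabeledObjects(labels=labels, records=records)


def segment_3d(volume: np.ndarray, roi: CellROI | np.ndarray | None, threshold: float,
               min_vox: int = 64) -> LabeledObjects:
    """Threshold a (z, y, x) volume, 26-connectivity, voxel-count filter."""
    if min_vox < 1:
        raise ValueError("min_vox must be >= 1")
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or volume.shape[0] < 2:
        raise ValueError("volume must have >= 2 z-sections; use segment_2d for single planes")
    binary = volume > threshold
    if roi is not None:
        mask = roi.mask if isinstance(roi, CellROI) else np.asarray(roi, dtype=bool)
        binary &= mask[np.newaxis] if mask.ndim == 2 else mask
    labels = _relabel(binary, connectivity=3, min_size=min_vox)
    ids = np.arange(1, labels.max() + 1)
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)[1:]
    records = pd.DataFrame({"object_id": ids, "n_vox": counts.astype(int)})
    return LabeledObjects(labels=labels, records=records)


def measure_objects(
    labeled: LabeledObjects,
    pixel_size_um: float,
    z_step_um: float | None = None,
    channel_images: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-object geometry in physical units plus integrated intensities.

    2D objects get area, centroid, equivalent-disk radius, perimeter and
    circularity (``4 pi A / P^2``, Crofton perimeter); 3D objects get volume,
    centroid and equivalent-sphere radius.  ``channel_images`` adds one
    ``intint_<name>`` column per channel with the sum of raw intensities
    over the object's pixels.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um required for physical measurements")
    labels = labeled.labels
    is_3d = labels.ndim == 3
    if is_3d and (z_step_um is None or z_step_um <= 0):
        raise ConfigurationError("z_step_um required for 3D measurements")
    rows = []
    for rp in measure.regionprops(labels):
        if is_3d:
            cz, cy, cx = rp.centroid
            n = int(rp.area)
            row = {
                "object_id": rp.label,
                "n_vox": n,
                "volume_um3": n * pixel_size_um**2 * z_step_um,
                "centroid_z_um": cz * z_step_um,
                "centroid_y_um": cy * pixel_size_um,
                "centroid_x_um": cx * pixel_size_um,
            }
            row["equivalent_radius_um"] = (3.0 * row["volume_um3"] / (4.0 * np.pi)) ** (1.0 / 3.0)
        else:
            cy, cx = rp.centroid
            n = int(rp.area)
            area = n * pixel_size_um**2
            perim = rp.perimeter_crofton * pixel_size_um
            row = {
                "object_id": rp.label,
                "n_px": n,
                "area_um2": area,
                "centroid_y_um": cy * pixel_size_um,
                "centroid_x_um": cx * pixel_size_um,
                "equivalent_radius_um": np.sqrt(area / np.pi),
                "perimeter_um": perim,
                "circularity": 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan,
            }
        if channel_images:
            obj = labels == rp.label
            for name, img in channel_images.items():
                row[f"intint_{name}"] = float(np.asarray(img, dtype=float)[obj].sum())
        rows.append(row)
    base = OBJECT_COLUMNS_3D if is_3d else OBJECT_COLUMNS_2D
    cols = base + [f"intint_{n}" for n in (channel_images or {})]
    return pd.DataFrame(rows, columns=cols)


def segment_stack_frame(
    stack: ImageStack,
    roi: CellROI,
    channel: str | int,
    t: int,
    threshold: float,
    min_area_px: int = 16,
    z: int = 0,
) -> tuple[LabeledObjects, pd.DataFrame]:
    """Segment one frame of a stack and measure it with all channels attached."""
    frame = stack.frame(t, channel, z)
    labeled = segment_2d(frame, roi, threshold, min_area_px)
    channels = {name: stack.frame(t, name, z) for name in stack.channel_names}
    return labeled, measure_objects(labeled, stack.pixel_size_um, channel_images=channels)
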