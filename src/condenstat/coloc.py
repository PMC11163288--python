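"""Interface profiling and two-channel colocalization statistics.

Radial intensity profiles around condensate centres in units of normalized
radius r/R (an interfacial shell shows up as a peak at r/R = 1); Pearson
correlation between channels over object pairs in physical contact; PCC
binned by aggregate size; and integrated-intensity-versus-size curves
normalized to channel maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .datamodel import CellROI


@dataclass
class RadialProfile:
    """Cross-condensate-averaged intensity vs. normalized radius r/R."""

    bin_centers: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_condensates: int

    @property
    def peak_bin_center(self) -> float:
        return float(self.bin_centers[int(np.nanargmax(self.mean))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_over_R": self.bin_centers, "mean_intensity": self.mean,
            "se": self.se, "n_condensates": self.n_condensates,
        })


@dataclass
class PairPCC:
    """Pearson correlation for one aggregate/condensate pair in contact."""

    equivalent_radius_um: float
    pcc: float
    n_px: int
    defined: bool = True


def radial_profile(
    image: np.ndarray,
    condensates: list[tuple[float, float, float]],
    pixel_size_um: float,
    roi: CellROI | None = None,
    r_max_rel: float = 2.0,
    n_bins: int = 20,
    normalize: str = "per_condensate",
    background: float = 0.0,
) -> RadialProfile:
    """Average radial intensity profile about condensate centres.

    ``condensates`` holds ``(y_um, x_um, R_um)`` per condensate.  Pixel
    intensities are binned by r/R on a uniform grid over [0, r_max_rel]
    (default bin width 0.1); per-condensate profiles are normalized to their
    own maximum (``normalize="per_condensate"``, the default) or left raw
    (``"none"``), then averaged with an SE across condensates.  Pixels
    outside the cell ROI are excluded; a condensate whose centre falls
    outside the ROI is skipped with a warning.  ``background`` (e.g. the
    estimated cytoplasmic mean) is subtracted before binning so the profile
    reflects signal above the diffuse pool.
    """
    if r_max_rel < 1:
        raise ValueError("r_max_rel must be >= 1 to cover the interface")
    image = np.asarray(image, dtype=float) - background
    ny, nx = image.shape
    edges = np.linspace(0.0, r_max_rel, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = roi.mask if roi is not None else np.ones_like(image, dtype=bool)
    profiles = []
    for (y_um, x_um, R) in condensates:
        if R <= 0:
            raise ValueError("condensate radius must be > 0")
        cy, cx = y_um / pixel_size_um, x_um / pixel_size_um
        iy, ix = int(round(cy)), int(round(cx))
        if not (0 <= iy < ny and 0 <= ix < nx) or not mask[iy, ix]:
            warnings.warn(f"condensate centre ({y_um:.2f}, {x_um:.2f}) um outside ROI; skipped")
            continue
        r_px = r_max_rel * R / pixel_size_um
        y0, y1 = max(0, int(cy - r_px)), min(ny, int(cy + r_px) + 2)
        x0, x1 = max(0, int(cx - r_px)), min(nx, int(cx + r_px) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rrel = np.hypot(yy - cy, xx - cx) * pixel_size_um / R
        sel = (rrel <= r_max_rel) & mask[y0:y1, x0:x1]
        idx = np.clip(np.digitize(rrel[sel], edges) - 1, 0, n_bins - 1)
        vals = image[y0:y1, x0:x1][sel]
        prof = np.full(n_bins, np.nan)
        for b in range(n_bins):
            v = vals[idx == b]
            if v.size:
                prof[b] = v.mean()
        if normalize == "per_condensate":
            m = np.nanmax(prof)
            if m > 0:
                prof = prof / m
        profiles.append(prof)
    if not profiles:
        raise ValueError("no usable condensates")
    arr = np.vstack(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        n_eff = np.sum(~np.isnan(arr), axis=0)
        se = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    return RadialProfile(bin_centers=centers, mean=mean, se=se, n_condensates=len(profiles))


_DILATE_8 = np.ones((3, 3), dtype=bool)  # 1-px dilation, 8-neighbourhood


def pair_pcc(
    img_a: np.ndarray,
    img_b: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    equivalent_radius_um: float = float("nan"),
) -> PairPCC:
    """Pearson correlation over one object pair's contact region.

    The region is the union of the two masks each dilated by one pixel; the
    pair must be in physical contact, i.e. the dilated masks must overlap
    or touch.  Zero variance in either channel makes the PCC undefined
    (flagged, not reported as 0).
    """
    a_d = binary_dilation(np.asarray(mask_a, bool), _DILATE_8)
    b_d = binary_dilation(np.asarray(mask_b, bool), _DILATE_8)
    # contact = the dilated masks overlap or are 8-adjacent
    if not (binary_dilation(a_d, _DILATE_8) & b_d).any():
        raise ValueError("objects are not in physical contact (dilated masks disjoint)")
    region = a_d | b_d
    a = np.asarray(img_a, dtype=float)[region]
    b = np.asarray(img_b, dtype=float)[region]
    n = int(region.sum())
    da, db = a - a.mean(), b - b.mean()
    va, vb = (da**2).sum(), (db**2).sum()
    if va == 0 or vb == 0:
        return PairPCC(equivalent_radius_um, float("nan"), n, defined=False)
    rho = float((da * db).sum() / np.sqrt(va * vb))
    return PairPCC(equivalent_radius_um, rho, n, defined=True)


def pcc_vs_size(pairs: list[PairPCC] | pd.DataFrame, radius_bin_edges) -> pd.DataFrame:
    """Mean PCC with SE, binned by aggregate equivalent radius.

    Empty bins are omitted from the output; single-pair bins carry SE NaN.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs
    else:
        df = pd.DataFrame({
            "equivalent_radius_um": [p.equivalent_radius_um for p in pairs],
            "pcc": [p.pcc for p in pairs],
            "defined": [p.defined for p in pairs],
        })
        df = df[df["defined"]]
    edges = np.asarray(radius_bin_edges, dtype=float)
    idx = np.digitize(df["equivalent_radius_um"].to_numpy(), edges) - 1
    rows = []
    for b in range(edges.size - 1):
        sel = df.loc[idx == b, "pcc"]
        if sel.empty:
            continue
        rows.append({
            "bin_center_um": 0.5 * (edges[b] + edges[b + 1]),
            "mean_pcc": float(sel.mean()),
            "se": float(sel.std(ddof=1) / np.sqrt(len(sel))) if len(sel) > 1 else np.nan,
            "n_pairs": int(len(sel)),
        })
    return pd.DataFrame(rows, columns=["bin_center_um", "mean_pcc", "se", "n_pairs"])


def integrated_intensity_vs_size(
    objects: pd.DataFrame,
    channels: list[str],
    size_column: str = "area_um2",
) -> pd.DataFrame:
    """Per-channel integrated intensities normalized to their maxima vs. size.

    Expects ``intint_<channel>`` columns (from ``measure_objects``); returns
    the table sorted by size with one ``<channel>_norm`` column per channel,
    each scaled so its maximum is exactly 1.
    """
    if len(objects) < 1:
        raise ValueError("no objects")
    out = objects[[size_column]].copy()
    for ch in channels:
        col = f"intint_{ch}"
        if col not in objects:
            raise KeyError(f"missing column {col}")
        m = objects[col].max()
        if m == 0:
            raise ValueError(f"channel {ch!r} has zero maximum integrated intensity")
        out[f"{ch}_norm"] = objects[col] / m
    return out.sort_values(size_column).reset_index(drop=True)
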