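"""Intracellular phase diagrams for optogenetic condensation.

Cytoplasmic intensities of the scaffold (iLID-tagged 24-mer core) and
client (sspB fusion) channels, measured before light activation, are
converted to micromolar concentrations via FCS-derived calibration
factors.  Each cell then maps to a point in

    (core concentration C, valence V)

space, where C is the 24-mer scaffold concentration (monomer
concentration / 24) and V the average number of clients per core
(client concentration / C).  Cells are classified as condensing or not
from their light response, and the binodal separating the two classes is
fitted as a logistic decision boundary in log-log space; when the boundary
is compatible with the hyperbola V * C = K the interpretable threshold
K is reported, and boundary shifts between conditions are tested by a
seeded bootstrap on log K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .datamodel import CalibrationFactors, CellROI, ConfigurationError, ImageStack, PipelineConfig
from .segment import (
    auto_background_region,
    compute_threshold,
    estimate_background,
    measure_objects,
    segment_2d,
)

#: scaffold oligomer stoichiometry (ferritin 24-mer)
CORE_STOICHIOMETRY = 24


def intensity_to_concentration(intensity: float, channel: str, calib: CalibrationFactors) -> float:
    """Convert mean intensity to micromolar via the FCS calibration line."""
    if channel not in calib.slope:
        raise ConfigurationError(f"no calibration for channel {channel!r}")
    offset = calib.channel_offset(channel)
    if intensity < offset:
        raise ValueError(f"intensity {intensity} below calibration offset {offset}")
    return (intensity - offset) / calib.slope[channel]


def concentration_to_intensity(conc_uM: float, channel: str, calib: CalibrationFactors) -> float:
    return conc_uM * calib.slope[channel] + calib.channel_offset(channel)


def cytoplasm_intensity(
    stack: ImageStack,
    roi: CellROI,
    region_area_um2: float = 10.0,
    z: int = 0,
) -> dict[str, float]:
    """Per-channel mean intensity in a ~10 um^2 cytoplasmic patch.

    Measured on the last frame before the first light-on interval (i.e.
    before any light-induced structure exists), in a patch auto-selected by
    the same dark-tile rule used for segmentation backgrounds.
    """
    if not stack.light_schedule:
        raise ValueError("stack has no light schedule; cannot find a pre-activation frame")
    first_on = stack.light_schedule[0][0]
    if first_on < 1:
        raise ValueError("no frame precedes the first light-on interval")
    t = first_on - 1
    tile_um = float(np.sqrt(region_area_um2))
    ref = stack.frame(t, 0, z)
    patch = auto_background_region(ref, roi, stack.pixel_size_um, tile_um=tile_um)
    return {
        name: float(stack.frame(t, name, z)[patch.mask].mean())
        for name in stack.channel_names
    }


def phase_point(c_ilid_monomer_uM: float, c_sspb_uM: float) -> tuple[float, float]:
    """Map monomer-calibrated concentrations to (core concentration, valence).

    Core concentration is the 24-mer scaffold concentration,
    ``c_ilid_monomer / 24``; valence is the average number of sspB clients
    per core, ``c_sspb / c_core``.
    """
    if c_ilid_monomer_uM <= 0 or c_sspb_uM <= 0:
        raise ValueError("concentrations must be > 0")
    c_core = c_ilid_monomer_uM / CORE_STOICHIOMETRY
    return c_core, c_sspb_uM / c_core


def _activation_frames(stack: ImageStack) -> tuple[int, int]:
    if not stack.light_schedule:
        raise ValueError("stack has no light schedule")
    a, b = stack.light_schedule[0]
    if a < 1:
        raise ValueError("no pre-activation frame")
    return a - 1, b - 1


def _circular_object_count(frame, pre_frame, roi, pixel_size_um, config) -> int:
    bg = auto_background_region(pre_frame, roi, pixel_size_um)
    mean, sd = estimate_background(pre_frame, bg)
    thr = compute_threshold(mean, sd, config.threshold_k)
    labeled = segment_2d(frame, roi, thr, config.min_area_px)
    if labeled.n_objects == 0:
        return 0
    rec = measure_objects(labeled, pixel_size_um)
    return int((rec["circularity"] >= config.circularity_min).sum())


def classify_condensation(
    stack: ImageStack,
    roi: CellROI,
    channel: str | int = 0,
    config: PipelineConfig | None = None,
    z: int = 0,
) -> tuple[bool, dict]:
    """Did this cell condense during the first light-on interval?

    A cell is condensed when the coefficient of variation (SD/mean) of the
    ROI intensity at the end of activation exceeds its pre-activation value
    by at least ``sd_ratio_min`` (texture appears; CV rather than raw SD
    makes the metric invariant to illumination gain) AND at least one
    detected object is droplet-like (circularity >= ``circularity_min``).
    Returns the verdict and an evidence dict with both numbers.
    """
    config = config or PipelineConfig()
    t_pre, t_end = _activation_frames(stack)
    pre = stack.frame(t_pre, channel, z)
    post = stack.frame(t_end, channel, z)
    cv_pre = pre[roi.mask].std() / pre[roi.mask].mean()
    cv_post = post[roi.mask].std() / post[roi.mask].mean()
    ratio = float(cv_post / cv_pre) if cv_pre > 0 else float("inf")
    n_circ = _circular_object_count(post, pre, roi, stack.pixel_size_um, config)
    condensed = ratio >= config.sd_ratio_min and n_circ >= 1
    return condensed, {
        "cv_ratio": ratio,
        "n_circular_objects": n_circ,
        "frame_pre": t_pre,
        "frame_end": t_end,
    }


def classify_cellwide(
    stack: ImageStack,
    roi: CellROI,
    channel: str | int = 0,
    config: PipelineConfig | None = None,
    z: int = 0,
) -> tuple[str, dict]:
    """Droplet-type response vs. absence of de novo spherical condensates.

    ``droplet_condensation`` requires >= 2 droplet-like (circular) objects
    during activation; recruitment onto irregular pre-existing aggregates
    alone yields ``no_droplet_condensation``.  The raw droplet count is
    surfaced so either labelling convention can be applied downstream.
    """
    config = config or PipelineConfig()
    t_pre, t_end = _activation_frames(stack)
    pre = stack.frame(t_pre, channel, z)
    post = stack.frame(t_end, channel, z)
    n_circ = _circular_object_count(post, pre, roi, stack.pixel_size_um, config)
    label = "droplet_condensation" if n_circ >= 2 else "no_droplet_condensation"
    return label, {"n_circular_objects": n_circ, "frame_pre": t_pre, "frame_end": t_end}


@dataclass
class PhaseBoundary:
    """Logistic decision boundary in (log C, log V) with the hyperbola readout.

    ``K_hat`` (the threshold of V * C = K) is reported only when the two
    log-coefficients agree within 20%, i.e. the fitted boundary is
    compatible with a product-threshold binodal.
    """

    beta0: float
    beta_logc: float
    beta_logv: float
    K_hat: float
    accuracy: float
    n_points: int

    @property
    def has_K(self) -> bool:
        return np.isfinite(self.K_hat)


def fit_phase_boundary(points: pd.DataFrame) -> PhaseBoundary:
    """Fit the binodal as a logistic decision surface in log-log space.

    ``points`` needs columns ``c_core_uM``, ``valence``, ``condensed``.
    Requires >= 10 points with both classes present.  A weak L2 penalty
    keeps the fit defined on perfectly separable data; the decision
    boundary itself is insensitive to it.
    """
    if len(points) < 10:
        raise ValueError("need >= 10 cells to fit a boundary")
    y = points["condensed"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both condensed and non-condensed cells are required")
    X = np.column_stack([
        np.log(points["c_core_uM"].to_numpy(dtype=float)),
        np.log(points["valence"].to_numpy(dtype=float)),
    ])
    clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=5000)
    clf.fit(X, y)
    b0 = float(clf.intercept_[0])
    b1, b2 = (float(v) for v in clf.coef_[0])
    acc = float(clf.score(X, y))
    if b1 != 0 and abs(b1 - b2) / abs(b1) < 0.2:
        K_hat = float(np.exp(-b0 / (0.5 * (b1 + b2))))
    else:
        K_hat = float("nan")
    return PhaseBoundary(beta0=b0, beta_logc=b1, beta_logv=b2,
                         K_hat=K_hat, accuracy=acc, n_points=len(points))


@dataclass
class BoundaryShift:
    """Bootstrap comparison of two fitted binodals."""

    K_a: float
    K_b: float
    log_ratio: float
    ci_low: float
    ci_high: float
    shifted: bool
    n_boot: int
    degenerate_fraction: float
    flagged: bool


def compare_boundaries(
    a: pd.DataFrame,
    b: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> BoundaryShift:
    """Is the binodal of condition b shifted relative to condition a?

    Reports log(K_b / K_a) with a percentile bootstrap CI (cells resampled
    within each condition); "shifted" iff the 95% CI excludes 0.  Resamples
    that lose a class (or an interpretable K) are skipped; the comparison is
    flagged when more than 10% of resamples are degenerate.
    """
    fit_a, fit_b = fit_phase_boundary(a), fit_phase_boundary(b)
    if not (fit_a.has_K and fit_b.has_K):
        raise ValueError("boundary of one condition is not an interpretable product threshold")
    point = float(np.log(fit_b.K_hat / fit_a.K_hat))
    rng = np.random.default_rng(seed)
    ratios = []
    n_degenerate = 0
    for _ in range(n_boot):
        ra = a.sample(n=len(a), replace=True, random_state=rng.integers(2**31))
        rb = b.sample(n=len(b), replace=True, random_state=rng.integers(2**31))
        try:
            ka = fit_phase_boundary(ra).K_hat
            kb = fit_phase_boundary(rb).K_hat
        except ValueError:
            n_degenerate += 1
            continue
        if not (np.isfinite(ka) and np.isfinite(kb)):
            n_degenerate += 1
            continue
        ratios.append(np.log(kb / ka))
    degen = n_degenerate / n_boot
    if not ratios:
        raise ValueError("all bootstrap resamples were degenerate")
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return BoundaryShift(
        K_a=fit_a.K_hat, K_b=fit_b.K_hat, log_ratio=point,
        ci_low=float(lo), ci_high=float(hi),
        shifted=bool(lo > 0 or hi < 0),
        n_boot=len(ratios), degenerate_fraction=degen,
        flagged=degen > 0.10,
    )
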