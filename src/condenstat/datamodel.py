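"""Core data model for calibrated fluorescence time-lapse analysis.

Conventions used throughout the package:

* image axis order is ``(t, z, c, y, x)``; purely 2D data carries a
  singleton z axis;
* all public geometry is in physical units (micrometres); pixel/um
  conversions are centralized on :class:`ImageStack`;
* coordinates are 0-based, intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """A required piece of metadata or configuration is missing or invalid."""


@dataclass
class ImageStack:
    """Calibrated multi-channel, multi-frame (optionally multi-z) stack.

    Parameters
    ----------
    data
        Nonnegative intensities indexed ``(t, z, c, y, x)``.
    pixel_size_um
        Edge length of one pixel in micrometres (> 0).
    channel_names
        One label per channel.
    frame_interval_s
        Seconds between consecutive frames (> 0).
    z_step_um
        Micrometres per optical section; ``None`` for single-section 2D data.
    light_schedule
        Disjoint, sorted half-open frame-index intervals ``[t_on, t_off)``
        during which blue-light activation is on.
    """

    data: np.ndarray
    pixel_size_um: float
    channel_names: list[str]
    frame_interval_s: float = 1.0
    z_step_um: float | None = None
    light_schedule: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ConfigurationError(
                f"data must be (t, z, c, y, x); got {self.data.ndim} axes"
            )
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be > 0")
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise ConfigurationError("z_step_um must be > 0 when present")
        if len(self.channel_names) != self.data.shape[2]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[2]} channels"
            )
        self.light_schedule = [(int(a), int(b)) for a, b in self.light_schedule]
        prev_off = 0
        for t_on, t_off in self.light_schedule:
            if not (0 <= t_on < t_off <= self.n_frames):
                raise ValueError(f"light interval [{t_on}, {t_off}) out of range")
            if t_on < prev_off:
                raise ValueError("light_schedule intervals must be sorted, disjoint")
            prev_off = t_off

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    @property
    def voxel_volume_um3(self) -> float:
        if self.z_step_um is None:
            raise ConfigurationError("z_step_um not set; stack is 2D")
        return self.pixel_size_um**2 * self.z_step_um

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ConfigurationError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def frame(self, t: int, channel: str | int, z: int = 0) -> np.ndarray:
        """One (y, x) image plane."""
        return self.data[t, z, self.channel_index(channel)]

    def volume(self, t: int, channel: str | int) -> np.ndarray:
        """One (z, y, x) volume."""
        return self.data[t, :, self.channel_index(channel)]

    def light_on(self, t: int) -> bool:
        return any(a <= t < b for a, b in self.light_schedule)


@dataclass
class CellROI:
    """Region of interest covering exactly one cell.

    ``provenance`` records whether the mask was drawn by hand, taken from
    simulation ground truth, or produced by an automatic method.
    """

    cell_id: str
    mask: np.ndarray
    provenance: str = "manual"

    _PROVENANCES = ("manual", "synthetic_truth", "auto")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D (y, x)")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"provenance must be one of {self._PROVENANCES}")

    @property
    def n_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class CalibrationFactors:
    """Per-channel linear intensity-to-concentration conversion.

    Determined experimentally by fluorescence correlation spectroscopy:
    ``intensity = slope * concentration_uM + offset`` per fluorophore, so
    concentration is recovered as ``(I - offset) / slope``.
    """

    slope: dict[str, float]
    offset: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, s in self.slope.items():
            if s <= 0:
                raise ConfigurationError(f"slope for channel {ch!r} must be > 0")
        for ch in self.offset:
            if self.offset[ch] < 0:
                raise ConfigurationError(f"offset for channel {ch!r} must be >= 0")

    def channel_offset(self, channel: str) -> float:
        return self.offset.get(channel, 0.0)


@dataclass
class PipelineConfig:
    """Analysis constants.

    Defaults are the printed constants of the underlying protocol: a
    threshold of background mean + 2.5 SD, minimum object sizes of 16 pixels
    (2D) / 64 voxels (3D), a 5 um^2 "small aggregate" cutoff, a 10 um^2
    "large aggregate" cutoff, a circularity floor of 0.8 for calling
    droplet-like objects, and a coefficient-of-variation ratio of 1.5 for
    calling condensation.
    """

    threshold_k: float = 2.5
    min_area_px: int = 16
    min_vox: int = 64
    small_agg_cutoff_um2: float = 5.0
    large_agg_cutoff_um2: float = 10.0
    circularity_min: float = 0.8
    sd_ratio_min: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "threshold_k",
            "min_area_px",
            "min_vox",
            "small_agg_cutoff_um2",
            "large_agg_cutoff_um2",
            "circularity_min",
            "sd_ratio_min",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "threshold_k": self.threshold_k,
            "min_area_px": self.min_area_px,
            "min_vox": self.min_vox,
            "small_agg_cutoff_um2": self.small_agg_cutoff_um2,
            "large_agg_cutoff_um2": self.large_agg_cutoff_um2,
            "circularity_min": self.circularity_min,
            "sd_ratio_min": self.sd_ratio_min,
            "rng_seed": self.rng_seed,
        }


def filter_consistency_counts(
    area_um2: float = 0.116,
    volume_um3: float = 0.116,
    pixel_size_um: float | None = None,
    z_step_um: float = 0.25,
) -> tuple[int, int]:
    """Pixel and voxel counts implied by the physical size filters.

    The 2D filter (0.116 um^2) and 3D filter (0.116 um^3) are mutually
    consistent for 250-nm optical sectioning: with the pixel size p chosen so
    that 16 p^2 = 0.116 um^2 (p = 85.1 nm), the voxel count is
    volume / (p^2 * 0.25 um) = 64.  Returns ``(n_px, n_vox)`` rounded to the
    nearest integer.
    """
    if pixel_size_um is None:
        pixel_size_um = float(np.sqrt(area_um2 / 16.0))
    n_px = area_um2 / pixel_size_um**2
    n_vox = volume_um3 / (pixel_size_um**2 * z_step_um)
    return int(round(n_px)), int(round(n_vox))
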