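"""File I/O: TIFF stacks with YAML sidecar metadata, mask images, CSV tables.

A stack on disk is a plain (OME-)TIFF holding the ``(t, z, c, y, x)`` array
plus a YAML sidecar (``<stem>.yaml`` next to the TIFF unless given
explicitly) carrying the physical geometry and the light-activation
schedule, which TIFF metadata alone cannot express.  Sidecar keys:
``pixel_size_um``, ``z_step_um``, ``frame_interval_s``, ``channel_names``,
``light_schedule``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datamodel import CellROI, ConfigurationError, ImageStack, PipelineConfig

SIDECAR_KEYS = ("pixel_size_um", "z_step_um", "frame_interval_s", "light_schedule")


def _sidecar_path(path: str | os.PathLike) -> Path:
    p = Path(path)
    # stack.ome.tiff -> stack.ome.yaml; stack.tif -> stack.yaml
    return p.with_suffix(".yaml")


def write_stack(stack: ImageStack, path: str | os.PathLike, meta: str | os.PathLike | None = None) -> None:
    """Write a stack as TIFF plus YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), metadata={"axes": "TZCYX"})
    sidecar = {
        "shape_tzcyx": [int(s) for s in stack.data.shape],
        "pixel_size_um": float(stack.pixel_size_um),
        "z_step_um": None if stack.z_step_um is None else float(stack.z_step_um),
        "frame_interval_s": float(stack.frame_interval_s),
        "channel_names": list(stack.channel_names),
        "light_schedule": [[int(a), int(b)] for a, b in stack.light_schedule],
    }
    meta_path = _sidecar_path(path) if meta is None else Path(meta)
    with open(meta_path, "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_stack(path: str | os.PathLike, meta: str | os.PathLike | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack; geometry comes from the YAML sidecar.

    Missing z is treated as a single optical section.  A missing pixel size
    raises :class:`ConfigurationError` naming the field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    meta_path = _sidecar_path(path) if meta is None else Path(meta)
    if not meta_path.exists():
        raise ConfigurationError(
            f"no metadata sidecar at {meta_path}; pixel_size_um unavailable"
        )
    with open(meta_path) as fh:
        sidecar = yaml.safe_load(fh) or {}
    if sidecar.get("shape_tzcyx"):
        data = data.reshape(sidecar["shape_tzcyx"])
    else:  # singleton axes squeezed by the TIFF writer are restored in front
        while data.ndim < 5:
            data = data[np.newaxis]
    if sidecar.get("pixel_size_um") is None:
        raise ConfigurationError(f"pixel_size_um missing from sidecar {meta_path}")
    return ImageStack(
        data=data,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        channel_names=list(sidecar.get("channel_names") or [f"ch{i}" for i in range(data.shape[2])]),
        frame_interval_s=float(sidecar.get("frame_interval_s") or 1.0),
        z_step_um=(None if sidecar.get("z_step_um") is None else float(sidecar["z_step_um"])),
        light_schedule=[tuple(iv) for iv in (sidecar.get("light_schedule") or [])],
    )


def write_mask(roi: CellROI, path: str | os.PathLike) -> None:
    tifffile.imwrite(Path(path), roi.mask.astype(np.uint8))


def read_mask(path: str | os.PathLike, cell_id: str | None = None, provenance: str = "manual") -> CellROI:
    arr = np.asarray(tifffile.imread(Path(path)))
    return CellROI(cell_id=cell_id or Path(path).stem, mask=arr > 0, provenance=provenance)


def write_results(records: pd.DataFrame | list[dict], path: str | os.PathLike, columns: list[str] | None = None) -> None:
    """Write a results table to CSV with stable column order and full float precision.

    An empty record list still yields a header-only CSV when ``columns`` is
    given (or the frame already carries columns).  Units are encoded in
    column names (e.g. ``area_um2``).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(records, columns=columns)
    if columns is not None:
        df = df.reindex(columns=columns)
    # pandas' default float formatting is the shortest round-trip repr:
    # full precision, and 0.116 prints as "0.116"
    df.to_csv(Path(path), index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def load_config(path: str | os.PathLike | None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(d)


def save_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
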