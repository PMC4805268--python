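"""Calibrated multi-channel image I/O and results-table export.

The in-memory container is :class:`CalibratedImageSet`: a mapping from
channel *role* (``phase``, ``membrane``, ``dapi``, ``reporter``) to a 2-D
float raster, plus the pixel size in micrometres.  Intensities are used
exactly as stored on disk — no bit-depth rescaling or normalisation —
because fluorescence comparisons across frames assume a common camera
scale.

Coordinate convention (package-wide): 0-based pixel indices, pixel
centers at integer coordinates, ``x`` = column (rightward), ``y`` = row
(downward); physical coordinates = pixel coordinates × ``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

ROLES = ("phase", "membrane", "dapi", "reporter")


@dataclass
class CalibratedImageSet:
    """Aligned multi-channel 2-D rasters with physical pixel calibration.

    Parameters
    ----------
    channels
        Mapping from channel role to a 2-D array of non-negative
        intensities. All rasters must share one shape.
    pixel_size
        Micrometres per pixel (square pixels).
    source_id
        Free-text provenance label, carried into results tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel role must be present")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for role in self.channels:
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            self.channels[role] = np.asarray(self.channels[role], dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


def load_image_set(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size: float,
) -> CalibratedImageSet:
    """Read a single- or multi-channel TIFF into a :class:`CalibratedImageSet`.

    ``channel_map`` assigns roles to page/plane indices of the TIFF
    (e.g. ``{"phase": 0, "membrane": 1, "reporter": 2}``).  Calibration
    comes from the required ``pixel_size`` argument, never from TIFF
    metadata dialects.  Values are converted to float without rescaling.
    """
    if np.ndim(pixel_size) != 0:
        raise ValueError("non-square pixels are not supported; "
                         "pixel_size must be a scalar (um/px)")
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        planes = arr[None, ...]
    elif arr.ndim == 3:
        # channel axis is whichever axis is smallest and not a spatial one;
        # for page-per-channel TIFFs tifffile already puts it first
        planes = arr if arr.shape[0] <= min(arr.shape[1:]) else np.moveaxis(arr, -1, 0)
    else:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {arr.shape}")

    channels: dict[str, np.ndarray] = {}
    for role, idx in channel_map.items():
        if not 0 <= idx < planes.shape[0]:
            raise IndexError(
                f"channel index {idx} for role {role!r} out of range "
                f"(file has {planes.shape[0]} channels)"
            )
        channels[role] = planes[idx].astype(float)
    return CalibratedImageSet(channels=channels, pixel_size=float(pixel_size),
                              source_id=str(path))


def write_image_set(image_set: CalibratedImageSet, path: str | Path,
                    order: Iterable[str] | None = None) -> dict[str, int]:
    """Write channels as a multi-page float32 TIFF; returns the channel map."""
    roles = list(order) if order is not None else [r for r in ROLES if r in image_set]
    stack = np.stack([image_set[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric="minisblack")
    return {r: i for i, r in enumerate(roles)}


def export_results(table: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a results table as delimited text with a header row.

    Numeric columns keep full float precision so a re-read reproduces the
    values; an empty table produces a header-only file.
    """
    table.to_csv(path, sep=sep, index=False)


def read_results(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def modal_background(raster: np.ndarray, bins: int = 256) -> float:
    """Modal intensity of a frame — the background estimate used throughout.

    The mode is the center of the fullest histogram bin over the frame's
    intensity range; for fields where background dominates the area this
    is robust to the bright minority of cell pixels.
    """
    raster = np.asarray(raster, dtype=float)
    lo, hi = float(raster.min()), float(raster.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(raster, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))
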