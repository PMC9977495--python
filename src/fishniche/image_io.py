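"""Calibrated multi-channel images, labeled object masks, and tabular I/O.

All spatial analysis in this package runs on 2D rasters with an isotropic
physical calibration.  Pixel coordinates are ``(row, col)`` indices, 0-based,
with the origin at the center of the top-left pixel; physical coordinates are
obtained by exact multiplication with ``pixel_size_um``.  Throughout the
package the convention for named physical axes is ``x_um = col * pixel_size_um``
and ``y_um = row * pixel_size_um``.

The calibration is user-supplied rather than parsed from TIFF metadata:
resolution tags in microscope TIFF dialects are inconsistent enough that a
silent misread is worse than an explicit argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class CalibrationError(ValueError):
    """Raised when an image or mask calibration is invalid or inconsistent."""


@dataclass
class CalibratedImage:
    """A 2D multi-channel fluorescence field with a physical pixel size.

    Parameters
    ----------
    channels
        Mapping from channel name (typically the probe, e.g. ``"Wnt2"``) to a
        2D non-negative intensity raster.  All rasters must share one shape.
    pixel_size_um
        Isotropic pixel size in micrometres; must be positive.
    field_id, animal_id, condition
        Free-form provenance labels carried into every downstream table.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    field_id: str = ""
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("CalibratedImage requires at least one channel")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise CalibrationError(
                f"pixel_size_um must be positive, got {self.pixel_size_um!r}"
            )
        shapes = set()
        for name, raster in self.channels.items():
            arr = np.asarray(raster)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D (ndim={arr.ndim})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.size and arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            shapes.add(arr.shape)
            self.channels[name] = arr
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None


@dataclass
class ObjectMask:
    """Labeled binary objects from one channel.

    ``labels`` is a 2D integer raster where 0 is background and object ``k``
    occupies the pixels labeled ``k``.  Labels are consecutive ``1..n`` and
    every object has at least one pixel.
    """

    labels: np.ndarray
    channel: str
    pixel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("labels must be a 2D raster")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must be an integer raster")
        if arr.size and arr.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(arr)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("object labels must be consecutive integers 1..n")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise CalibrationError(
                f"pixel_size_um must be positive, got {self.pixel_size_um!r}"
            )
        self.labels = arr

    @property
    def n_objects(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0


def read_image(
    path: str | Path,
    pixel_size_um: float,
    channel_names: list[str] | tuple[str, ...],
    field_id: str = "",
    animal_id: str = "",
    condition: str = "",
) -> CalibratedImage:
    """Read a multi-page/multi-channel TIFF into a :class:`CalibratedImage`.

    The number of ``channel_names`` must match the number of pages (or the
    leading axis of a 3D stack); a plain 2D TIFF is treated as one channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D or (channel, H, W) TIFF, got ndim={arr.ndim}")
    if len(channel_names) != arr.shape[0]:
        raise ValueError(
            f"{len(channel_names)} channel names given for a {arr.shape[0]}-channel TIFF"
        )
    channels = {name: arr[i] for i, name in enumerate(channel_names)}
    return CalibratedImage(
        channels=channels,
        pixel_size_um=pixel_size_um,
        field_id=field_id,
        animal_id=animal_id,
        condition=condition,
    )


def write_image(image: CalibratedImage, path: str | Path) -> None:
    """Write a :class:`CalibratedImage` as a (channel, H, W) TIFF stack."""
    stack = np.stack([image.channels[name] for name in image.channel_names])
    tifffile.imwrite(Path(path), stack)


def write_table(records, path: str | Path) -> None:
    """Write records (a DataFrame or list of dicts) as a CSV.

    Column order is preserved as given; an empty DataFrame produces a
    header-only file, so that downstream readers always see the schema.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def pixels_to_um(rows: np.ndarray, cols: np.ndarray, pixel_size_um: float):
    """Convert (row, col) pixel coordinates to (x_um, y_um)."""
    return np.asarray(cols, dtype=float) * pixel_size_um, np.asarray(
        rows, dtype=float
    ) * pixel_size_um


def um_to_pixels(x_um: np.ndarray, y_um: np.ndarray, pixel_size_um: float):
    """Convert (x_um, y_um) to fractional (row, col) pixel coordinates."""
    return np.asarray(y_um, dtype=float) / pixel_size_um, np.asarray(
        x_um, dtype=float
    ) / pixel_size_um
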