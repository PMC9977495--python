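"""Organoid size distributions, the 50 um colony rule, and CFE.

An alveolar organoid counts as a colony when its diameter reaches 50 um.
"Diameter" is the equivalent circular diameter derived from segmented area,
``pixel_size_um * 2 * sqrt(area_px / pi)`` — organoids are near-spherical in
projection and the area-based measure is far more robust to boundary noise
than a Feret caliper.  Colony-forming efficiency is the percentage of seeded
progenitor cells that produced a colony: ``100 * n_colonies / n_seeded``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .image_io import CalibratedImage, ObjectMask

COLONY_MIN_DIAMETER_UM = 50.0


@dataclass
class CultureSummary:
    """Per-culture morphometrics after the colony filter."""

    n_objects: int
    n_colonies: int
    n_seeded: int | None
    cfe_percent: float | None
    median_diameter_um: float | None  # median over colonies


def segment_organoids(
    image: CalibratedImage,
    channel: str,
    smooth_sigma_px: float = 2.0,
    min_diameter_um: float = 10.0,
) -> ObjectMask:
    """Segment organoids by Otsu thresholding the smoothed channel.

    Holes are filled and specks below ``min_diameter_um`` equivalent diameter
    are discarded.  A blank (near-constant) image returns an empty mask.
    """
    raster = image.channel(channel).astype(float)
    ps = image.pixel_size_um
    smoothed = ndi.gaussian_filter(raster, smooth_sigma_px)
    if smoothed.max() - smoothed.min() < 1e-9:
        return ObjectMask(np.zeros(raster.shape, dtype=np.int32), channel, ps)
    binary = smoothed > threshold_otsu(smoothed)
    binary = ndi.binary_fill_holes(binary)
    labels = sk_label(binary, connectivity=2)
    min_area = np.pi * (min_diameter_um / ps / 2.0) ** 2
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in regionprops(labels):
        keep[p.label] = p.area >= min_area
    filtered = np.where(keep[labels], labels, 0)
    # relabel consecutively
    out = sk_label(filtered > 0, connectivity=2).astype(np.int32)
    return ObjectMask(out, channel, ps)


def equivalent_diameter_um(area_px: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Diameter of the circle with the same area as the object."""
    return pixel_size_um * 2.0 * np.sqrt(np.asarray(area_px, dtype=float) / np.pi)


def measure_organoids(
    mask: ObjectMask, min_diameter_um: float = COLONY_MIN_DIAMETER_UM
) -> pd.DataFrame:
    """Per-object table: area, equivalent diameter, and the colony flag.

    The colony flag is ``diameter >= min_diameter_um``; an empty mask gives an
    empty (header-only) table.
    """
    ps = mask.pixel_size_um
    rows = []
    for p in regionprops(mask.labels):
        diam = float(equivalent_diameter_um(p.area, ps))
        rows.append(
            {
                "object_id": int(p.label),
                "area_px": int(p.area),
                "equivalent_diameter_um": diam,
                "is_colony": diam >= min_diameter_um,
            }
        )
    return pd.DataFrame(
        rows, columns=["object_id", "area_px", "equivalent_diameter_um", "is_colony"]
    )


def colony_forming_efficiency(n_colonies: int, n_seeded: int) -> float:
    """CFE in percent: 100 * colonies / seeded progenitor cells."""
    if n_seeded <= 0:
        raise ValueError(f"n_seeded must be > 0, got {n_seeded}")
    if n_colonies < 0:
        raise ValueError(f"n_colonies must be >= 0, got {n_colonies}")
    return 100.0 * n_colonies / n_seeded


def summarize_culture(
    table: pd.DataFrame, n_seeded: int | None = None
) -> CultureSummary:
    """Collapse a per-object table into culture-level statistics.

    The median diameter is taken over colonies (objects passing the size
    rule), matching how organoid sizes are typically reported.
    """
    colonies = table[table["is_colony"]] if len(table) else table
    n_colonies = int(len(colonies))
    return CultureSummary(
        n_objects=int(len(table)),
        n_colonies=n_colonies,
        n_seeded=n_seeded,
        cfe_percent=(
            colony_forming_efficiency(n_colonies, n_seeded)
            if n_seeded is not None
            else None
        ),
        median_diameter_um=(
            float(colonies["equivalent_diameter_um"].median()) if n_colonies else None
        ),
    )
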