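"""Wnt2/Wnt5a subtype classification of cytospun PDGFRα+ fibroblasts.

A cytospin preparation yields isolated cells, so a cell can be reconstructed
from its Pdgfra RNA signal alone: every Pdgfra object is dilated by 5 um with
a Euclidean disk, overlapping dilations are merged into one cell, and DAPI
nucleus components touching the dilation are folded in to form the cell
footprint.  A cell is then scored positive for a Wnt channel when any Wnt
object, itself dilated by 4 um, intersects the footprint — a plain Boolean
intersection, with single-object positivity (no minimum overlap fraction or
punctum-count threshold).

The two positivity flags define four subtypes: Wnt2+ single positive,
Wnt5a+ single positive, double positive, and double negative.  Cohort
fractions are reported per animal so conditions can be compared with the
same equal-variance t test used for spatial distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk

from .image_io import CalibratedImage, CalibrationError, ObjectMask
from .spot_detection import SpotDetectionParams, detect_spots
from .synthetic_data import SUBTYPES

_S8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class CellFootprint:
    """One reconstructed cell: pixel set, centroid, and nucleus status."""

    cell_id: int
    rows: np.ndarray
    cols: np.ndarray
    centroid_um: tuple[float, float]  # (x_um, y_um) of the Pdgfra signal
    anucleate: bool
    pixel_size_um: float

    @property
    def n_pixels(self) -> int:
        return len(self.rows)


@dataclass
class CellTypingResult:
    """Per-cell positivity flags, subtype calls, and cohort fractions."""

    cells: pd.DataFrame  # cell_id, x_um, y_um, wnt2_positive, wnt5a_positive, anucleate, subtype
    field_id: str = ""
    animal_id: str = ""
    condition: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def fractions(self) -> dict[str, float]:
        """Percent of cells per subtype; the four values sum to 100."""
        if self.n_cells == 0:
            raise ValueError("no cells typed")
        counts = self.cells["subtype"].value_counts()
        return {s: 100.0 * counts.get(s, 0) / self.n_cells for s in SUBTYPES}


def subtype_from_flags(wnt2: bool, wnt5a: bool) -> str:
    if wnt2 and wnt5a:
        return "double+"
    if wnt2:
        return "Wnt2+"
    if wnt5a:
        return "Wnt5a+"
    return "double-"


def _check_calibration(a: ObjectMask, b: ObjectMask) -> None:
    if a.labels.shape != b.labels.shape:
        raise CalibrationError(
            f"mask shapes differ: {a.labels.shape} vs {b.labels.shape}"
        )
    if not np.isclose(a.pixel_size_um, b.pixel_size_um):
        raise CalibrationError(
            f"pixel sizes differ: {a.pixel_size_um} vs {b.pixel_size_um}"
        )


def _dilation_radius_px(radius_um: float, pixel_size_um: float) -> int:
    return int(round(radius_um / pixel_size_um))


def _dilate(binary: np.ndarray, radius_px: int) -> np.ndarray:
    """Binary dilation with a discrete Euclidean disk of the given radius."""
    if radius_px <= 0:
        return binary
    return ndi.binary_dilation(binary, structure=disk(radius_px))


def build_cell_masks(
    pdgfra_mask: ObjectMask,
    dapi_mask: ObjectMask,
    dilation_um: float = 5.0,
) -> list[CellFootprint]:
    """Reconstruct cell footprints from Pdgfra objects and DAPI nuclei.

    Each Pdgfra object is dilated by a Euclidean disk of radius
    ``round(dilation_um / pixel_size_um)`` px; dilations that touch merge into
    one cell.  A DAPI component overlapping exactly one cell joins it; one
    contested by several cells goes to the cell with the nearer Pdgfra
    centroid (ties to the lower cell id).  DAPI pixels already inside a
    cell's dilated region stay with that cell, so footprints are disjoint.
    Cells with no DAPI overlap at all are kept but flagged anucleate.
    """
    _check_calibration(pdgfra_mask, dapi_mask)
    ps = pdgfra_mask.pixel_size_um
    r_px = _dilation_radius_px(dilation_um, ps)

    pdgfra_bin = pdgfra_mask.binary
    dilated = _dilate(pdgfra_bin, r_px)
    cell_labels = sk_label(dilated, connectivity=2)
    n_cells = int(cell_labels.max())
    if n_cells == 0:
        return []

    # Pdgfra-signal centroid per cell (uniform weight over Pdgfra pixels).
    centroids_rc = ndi.center_of_mass(
        pdgfra_bin, labels=cell_labels, index=np.arange(1, n_cells + 1)
    )

    # Assign DAPI components.
    dapi_lab, n_dapi = ndi.label(dapi_mask.binary, structure=_S8)
    owner = np.zeros(n_dapi + 1, dtype=int)
    if n_dapi:
        dapi_centroids = ndi.center_of_mass(
            dapi_mask.binary, labels=dapi_lab, index=np.arange(1, n_dapi + 1)
        )
        for k in range(1, n_dapi + 1):
            overlapping = np.unique(cell_labels[dapi_lab == k])
            overlapping = overlapping[overlapping > 0]
            if overlapping.size == 0:
                continue
            if overlapping.size == 1:
                owner[k] = int(overlapping[0])
            else:
                dr, dc = dapi_centroids[k - 1]
                dists = [
                    np.hypot(centroids_rc[c - 1][0] - dr, centroids_rc[c - 1][1] - dc)
                    for c in overlapping
                ]
                # nearest Pdgfra centroid; argmin ties resolve to lower id
                owner[k] = int(overlapping[int(np.argmin(dists))])

    # Footprint label image: dilated cells, plus assigned DAPI pixels that
    # are not already covered by any cell's dilation.
    footprint = cell_labels.copy()
    if n_dapi:
        uncovered = (footprint == 0) & (dapi_lab > 0)
        footprint[uncovered] = owner[dapi_lab[uncovered]]

    nucleated = set(int(c) for c in owner if c > 0)
    cells = []
    for cid in range(1, n_cells + 1):
        rr, cc = np.nonzero(footprint == cid)
        row_c, col_c = centroids_rc[cid - 1]
        cells.append(
            CellFootprint(
                cell_id=cid,
                rows=rr,
                cols=cc,
                centroid_um=(float(col_c) * ps, float(row_c) * ps),
                anucleate=cid not in nucleated,
                pixel_size_um=ps,
            )
        )
    return cells


def assign_wnt_status(
    cells: list[CellFootprint],
    wnt_mask: ObjectMask,
    wnt_dilation_um: float = 4.0,
) -> np.ndarray:
    """Positivity flag per cell: does any 4 um-dilated Wnt object touch it?

    Returns a boolean array aligned with ``cells``.  Positivity needs a
    single intersecting pixel.
    """
    if not cells:
        return np.zeros(0, dtype=bool)
    ps = cells[0].pixel_size_um
    if not np.isclose(ps, wnt_mask.pixel_size_um):
        raise CalibrationError(
            f"pixel sizes differ: {ps} vs {wnt_mask.pixel_size_um}"
        )
    r_px = _dilation_radius_px(wnt_dilation_um, ps)
    dilated = _dilate(wnt_mask.binary, r_px)
    return np.array(
        [bool(dilated[c.rows, c.cols].any()) for c in cells], dtype=bool
    )


def classify_cells(
    cells: list[CellFootprint],
    wnt2_mask: ObjectMask,
    wnt5a_mask: ObjectMask,
    wnt_dilation_um: float = 4.0,
    field_id: str = "",
    animal_id: str = "",
    condition: str = "",
    exclude_anucleate: bool = False,
) -> CellTypingResult:
    """Score both Wnt channels and assign the four-way subtype per cell."""
    wnt2 = assign_wnt_status(cells, wnt2_mask, wnt_dilation_um)
    wnt5a = assign_wnt_status(cells, wnt5a_mask, wnt_dilation_um)
    rows = []
    for c, w2, w5 in zip(cells, wnt2, wnt5a):
        if exclude_anucleate and c.anucleate:
            continue
        rows.append(
            {
                "cell_id": c.cell_id,
                "x_um": c.centroid_um[0],
                "y_um": c.centroid_um[1],
                "wnt2_positive": bool(w2),
                "wnt5a_positive": bool(w5),
                "anucleate": c.anucleate,
                "subtype": subtype_from_flags(bool(w2), bool(w5)),
                "field_id": field_id,
                "animal_id": animal_id,
                "condition": condition,
            }
        )
    columns = [
        "cell_id", "x_um", "y_um", "wnt2_positive", "wnt5a_positive",
        "anucleate", "subtype", "field_id", "animal_id", "condition",
    ]
    return CellTypingResult(
        cells=pd.DataFrame(rows, columns=columns),
        field_id=field_id,
        animal_id=animal_id,
        condition=condition,
    )


def segment_nuclei(
    image: CalibratedImage,
    channel: str = "DAPI",
    smooth_sigma_px: float = 2.0,
    min_diameter_um: float = 3.0,
) -> ObjectMask:
    """Segment nucleus components by Otsu thresholding the smoothed channel.

    A near-constant channel (no nuclei) yields an empty mask rather than an
    error.  Specks below ``min_diameter_um`` equivalent diameter are removed.
    """
    from skimage.filters import threshold_otsu

    raster = image.channel(channel).astype(float)
    ps = image.pixel_size_um
    smoothed = ndi.gaussian_filter(raster, smooth_sigma_px)
    if smoothed.max() - smoothed.min() < 1e-9:
        return ObjectMask(np.zeros(raster.shape, dtype=np.int32), channel, ps)
    binary = smoothed > threshold_otsu(smoothed)
    binary = ndi.binary_fill_holes(binary)
    labels = sk_label(binary, connectivity=2)
    min_area = int(np.pi * (min_diameter_um / ps / 2.0) ** 2)
    if min_area > 1 and labels.max():
        keep = np.zeros(labels.max() + 1, dtype=bool)
        for p in regionprops(labels):
            keep[p.label] = p.area >= min_area
        labels = sk_label(keep[labels], connectivity=2)
    return ObjectMask(labels.astype(np.int32), channel, ps)


def type_cytospin_field(
    image: CalibratedImage,
    pdgfra_channel: str = "Pdgfra",
    wnt2_channel: str = "Wnt2",
    wnt5a_channel: str = "Wnt5a",
    dapi_channel: str = "DAPI",
    detection_params: SpotDetectionParams | None = None,
    pdgfra_dilation_um: float = 5.0,
    wnt_dilation_um: float = 4.0,
    exclude_anucleate: bool = False,
) -> CellTypingResult:
    """End-to-end typing of one cytospin field from raw channels.

    Detects puncta in the Pdgfra and Wnt channels, segments nuclei from
    DAPI, builds cell footprints, and classifies each cell.
    """
    params = detection_params or SpotDetectionParams()
    pdgfra_mask, _ = detect_spots(image, pdgfra_channel, params)
    wnt2_mask, _ = detect_spots(image, wnt2_channel, params)
    wnt5a_mask, _ = detect_spots(image, wnt5a_channel, params)
    dapi_mask = segment_nuclei(image, dapi_channel)
    cells = build_cell_masks(pdgfra_mask, dapi_mask, pdgfra_dilation_um)
    return classify_cells(
        cells,
        wnt2_mask,
        wnt5a_mask,
        wnt_dilation_um,
        field_id=image.field_id,
        animal_id=image.animal_id,
        condition=image.condition,
        exclude_anucleate=exclude_anucleate,
    )


def subtype_fractions(
    results: list[CellTypingResult],
) -> pd.DataFrame:
    """Per-animal subtype percentages, pooled over an animal's fields.

    Returns one row per (condition, animal) with a percentage column per
    subtype and the pooled cell count; rows are ready for per-subtype
    condition comparison with :func:`fishniche.spatial_mapping.compare_conditions`.
    """
    if not results or all(r.n_cells == 0 for r in results):
        raise ValueError("no cells to summarize")
    pooled = pd.concat([r.cells for r in results], ignore_index=True)
    rows = []
    for (condition, animal), sub in sorted(
        pooled.groupby(["condition", "animal_id"], sort=True)
    ):
        counts = sub["subtype"].value_counts()
        row = {"condition": condition, "animal_id": animal, "n_cells": len(sub)}
        for s in SUBTYPES:
            row[f"pct_{s}"] = 100.0 * counts.get(s, 0) / len(sub)
        rows.append(row)
    return pd.DataFrame(rows)
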