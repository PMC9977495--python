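"""Synthetic fluorescence fields with exact ground truth.

Three generators emulate the data the analysis pipeline consumes:

* lung-section RNA-FISH fields in which AT2 anchor puncta (``Sftpc``) are
  scattered uniformly and each Wnt punctum sits at a random anchor plus an
  isotropic displacement whose radius is exponential with a configurable
  mean — the single knob that makes one Wnt channel systematically closer
  to the AT2 signal than the other;
* cytospin fields of isolated PDGFRα+ fibroblasts, each cell drawn into one
  of the four Wnt2/Wnt5a expression subtypes from a configured probability
  vector, with per-channel puncta rendered only in positive cells;
* organoid fields of non-overlapping disks with known diameters.

Every true coordinate, subtype label, and diameter is recorded in a
:class:`GroundTruth`, so detection, spatial mapping, cell typing, and
morphometrics can all be scored against an exact oracle.  All randomness
flows from a single integer seed through one ``numpy`` Generator per call;
a fixed seed reproduces outputs byte-for-byte.

Rendering model: each punctum is an isotropic Gaussian of configurable
amplitude and sigma added to a flat background, followed by Poisson shot
noise on the total expected photon count and optional additive Gaussian
read noise.  The peak signal-to-noise ratio at default settings
(amplitude 100 over background 100) is amplitude / sqrt(background) = 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_io import CalibratedImage, ObjectMask

#: Canonical subtype labels, in the order used by probability vectors.
SUBTYPES = ("Wnt2+", "Wnt5a+", "double+", "double-")

#: Which channels each subtype expresses.
SUBTYPE_CHANNELS = {
    "Wnt2+": ("Wnt2",),
    "Wnt5a+": ("Wnt5a",),
    "double+": ("Wnt2", "Wnt5a"),
    "double-": (),
}


@dataclass
class GroundTruth:
    """The simulator's record of everything the analysis should recover."""

    spots_um: dict[str, np.ndarray] = field(default_factory=dict)
    cell_centers_um: np.ndarray | None = None
    cell_subtypes: list[str] | None = None
    organoid_diameters_um: np.ndarray | None = None

    def spot_count(self, channel: str) -> int:
        return 0 if channel not in self.spots_um else len(self.spots_um[channel])


@dataclass
class SectionSimConfig:
    """Configuration for one simulated lung-section RNA-FISH field.

    ``wnt2_offset_mean_um`` / ``wnt5a_offset_mean_um`` are the means of the
    exponential radial displacement from each Wnt punctum to its (uniformly
    chosen) Sftpc anchor.  Defaults place Wnt2 closer than Wnt5a, the
    normocapnic arrangement; a hypercapnia-like condition is expressed purely
    as config deltas (smaller Wnt5a offset, more Wnt5a puncta), never as a
    separate code path.
    """

    seed: int = 0
    field_um: float = 200.0
    pixel_size_um: float = 0.5
    n_sftpc_cells: int = 100
    n_pdgfra_spots: int = 200
    wnt2_offset_mean_um: float = 5.0
    wnt5a_offset_mean_um: float = 9.0
    wnt_counts: dict[str, int] = field(
        default_factory=lambda: {"Wnt2": 200, "Wnt5a": 200}
    )
    psf_sigma_px: float = 2.0
    spot_amplitude: float = 100.0
    background_level: float = 100.0
    poisson_noise: bool = True
    gaussian_noise_sigma: float = 0.0
    field_id: str = ""
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.field_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("field_um and pixel_size_um must be positive")
        if self.wnt2_offset_mean_um < 0 or self.wnt5a_offset_mean_um < 0:
            raise ValueError("offset means must be >= 0")
        if self.n_sftpc_cells < 0 or self.n_pdgfra_spots < 0:
            raise ValueError("counts must be >= 0")
        if any(c < 0 for c in self.wnt_counts.values()):
            raise ValueError("wnt_counts must be >= 0")

    def offset_mean_for(self, channel: str) -> float:
        if channel == "Wnt2":
            return self.wnt2_offset_mean_um
        if channel == "Wnt5a":
            return self.wnt5a_offset_mean_um
        raise KeyError(f"no offset mean configured for channel {channel!r}")


@dataclass
class CytospinSimConfig:
    """Configuration for one simulated cytospin field of isolated cells.

    Each cell is a non-overlapping nucleus disk (DAPI) with Pdgfra puncta
    scattered over the whole cell footprint and Wnt puncta only for the
    channels its subtype expresses.  ``subtype_probs`` follows the order of
    :data:`SUBTYPES`.
    """

    seed: int = 0
    n_cells: int = 45
    subtype_probs: tuple[float, float, float, float] = (0.3, 0.2, 0.25, 0.25)
    field_um: float = 300.0
    pixel_size_um: float = 0.5
    nucleus_radius_um: float = 4.0
    cell_radius_um: float = 8.0
    min_separation_um: float = 30.0
    puncta_per_positive_channel: int = 6
    pdgfra_puncta_per_cell: int = 8
    psf_sigma_px: float = 2.0
    spot_amplitude: float = 100.0
    background_level: float = 100.0
    poisson_noise: bool = True
    gaussian_noise_sigma: float = 0.0
    field_id: str = ""
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        probs = np.asarray(self.subtype_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0):
            raise ValueError("subtype_probs must be 4 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"subtype_probs must sum to 1, got {probs.sum()!r}")
        if self.cell_radius_um < self.nucleus_radius_um:
            raise ValueError("cell_radius_um must be >= nucleus_radius_um")


class PlacementError(RuntimeError):
    """Raised when requested objects cannot be placed without overlap."""


def _field_shape(field_um: float, pixel_size_um: float) -> tuple[int, int]:
    n = int(round(field_um / pixel_size_um))
    return n, n


def _render_gaussian_spots(
    canvas: np.ndarray,
    coords_px: np.ndarray,
    sigma_px: float,
    amplitude: float,
) -> None:
    """Add a Gaussian of the given amplitude at each (row, col) position.

    Peaks are centered at the true sub-pixel coordinate; rendering is local
    (±4 sigma window) for speed and is an in-place accumulation.
    """
    if len(coords_px) == 0:
        return
    h, w = canvas.shape
    half = max(1, int(math.ceil(4.0 * sigma_px)))
    for r, c in coords_px:
        r0 = max(0, int(math.floor(r)) - half)
        r1 = min(h, int(math.floor(r)) + half + 1)
        c0 = max(0, int(math.floor(c)) - half)
        c1 = min(w, int(math.floor(c)) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=float)
        cc = np.arange(c0, c1, dtype=float)
        gr = np.exp(-((rr - r) ** 2) / (2.0 * sigma_px**2))
        gc = np.exp(-((cc - c) ** 2) / (2.0 * sigma_px**2))
        canvas[r0:r1, c0:c1] += amplitude * np.outer(gr, gc)


def _apply_noise(
    expected: np.ndarray,
    rng: np.random.Generator,
    poisson: bool,
    gaussian_sigma: float,
) -> np.ndarray:
    out = (
        rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
        if poisson
        else expected.copy()
    )
    if gaussian_sigma > 0:
        out = out + rng.normal(0.0, gaussian_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def simulate_section_field(config: SectionSimConfig) -> tuple[CalibratedImage, GroundTruth]:
    """Simulate one calibrated lung-section field with Sftpc/Pdgfra/Wnt channels.

    Sftpc anchors and Pdgfra puncta are uniform over the field.  Each Wnt
    punctum picks an anchor uniformly at random and is displaced by an
    exponential radius (mean from the config) in a uniform direction;
    positions falling outside the field are redrawn.  Ground truth records
    exact physical coordinates per channel.
    """
    rng = np.random.default_rng(config.seed)
    L = config.field_um
    ps = config.pixel_size_um
    shape = _field_shape(L, ps)

    anchors = rng.uniform(0.0, L, size=(config.n_sftpc_cells, 2))  # (x, y) um
    truth = GroundTruth(spots_um={"Sftpc": anchors})

    truth.spots_um["Pdgfra"] = rng.uniform(0.0, L, size=(config.n_pdgfra_spots, 2))

    for chan, count in config.wnt_counts.items():
        mean = config.offset_mean_for(chan)
        pts = np.empty((count, 2))
        for i in range(count):
            if config.n_sftpc_cells == 0:
                pts[i] = rng.uniform(0.0, L, size=2)
                continue
            while True:
                anchor = anchors[rng.integers(0, len(anchors))]
                r = rng.exponential(mean) if mean > 0 else 0.0
                theta = rng.uniform(0.0, 2.0 * math.pi)
                p = anchor + r * np.array([math.cos(theta), math.sin(theta)])
                if 0.0 <= p[0] < L and 0.0 <= p[1] < L:
                    pts[i] = p
                    break
        truth.spots_um[chan] = pts

    channels: dict[str, np.ndarray] = {}
    for chan, pts in truth.spots_um.items():
        canvas = np.full(shape, float(config.background_level))
        coords_px = np.column_stack([pts[:, 1] / ps, pts[:, 0] / ps])  # (row, col)
        _render_gaussian_spots(canvas, coords_px, config.psf_sigma_px, config.spot_amplitude)
        channels[chan] = _apply_noise(
            canvas, rng, config.poisson_noise, config.gaussian_noise_sigma
        )

    image = CalibratedImage(
        channels=channels,
        pixel_size_um=ps,
        field_id=config.field_id,
        animal_id=config.animal_id,
        condition=config.condition,
    )
    return image, truth


def simulate_spot_field(
    seed: int,
    n_spots: int,
    field_um: float = 200.0,
    pixel_size_um: float = 0.5,
    min_separation_um: float = 2.5,
    channel: str = "spots",
    psf_sigma_px: float = 2.0,
    spot_amplitude: float = 100.0,
    background_level: float = 100.0,
    poisson_noise: bool = True,
    gaussian_noise_sigma: float = 0.0,
) -> tuple[CalibratedImage, GroundTruth]:
    """Single-channel field of well-separated puncta for detector scoring.

    Unlike the section simulator — where Wnt puncta cluster around shared
    anchors and may coincide — true positions here keep a minimum pairwise
    separation, so detection recall/precision against ground truth is a
    property of the detector, not of unresolvable overlaps.
    """
    rng = np.random.default_rng(seed)
    pts = _place_non_overlapping(
        rng,
        n_spots,
        field_um,
        margin_um=2.0 * psf_sigma_px * pixel_size_um,
        min_separation_um=min_separation_um,
    )
    shape = _field_shape(field_um, pixel_size_um)
    canvas = np.full(shape, float(background_level))
    coords_px = np.column_stack([pts[:, 1] / pixel_size_um, pts[:, 0] / pixel_size_um])
    _render_gaussian_spots(canvas, coords_px, psf_sigma_px, spot_amplitude)
    raster = _apply_noise(canvas, rng, poisson_noise, gaussian_noise_sigma)
    image = CalibratedImage(channels={channel: raster}, pixel_size_um=pixel_size_um)
    return image, GroundTruth(spots_um={channel: pts})


def _place_non_overlapping(
    rng: np.random.Generator,
    n: int,
    field_um: float,
    margin_um: float,
    min_separation_um: float,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample n (x, y) centers with pairwise separation >= min_separation."""
    centers: list[np.ndarray] = []
    attempts = 0
    lo, hi = margin_um, field_um - margin_um
    if hi <= lo:
        raise PlacementError("field too small for the requested object size")
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could only place {len(centers)}/{n} objects "
                f"with {min_separation_um} um separation in a {field_um} um field"
            )
        p = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(p - q)) >= min_separation_um for q in centers):
            centers.append(p)
    return np.asarray(centers)


def simulate_cytospin_field(config: CytospinSimConfig) -> tuple[CalibratedImage, GroundTruth]:
    """Simulate one cytospin field of isolated PDGFRα+ cells.

    Channels rendered: ``DAPI`` (nucleus disks), ``Pdgfra`` (puncta in every
    cell), ``Wnt2`` and ``Wnt5a`` (puncta only in cells whose drawn subtype
    expresses them).  Puncta are uniform within the cell footprint disk.
    """
    rng = np.random.default_rng(config.seed)
    ps = config.pixel_size_um
    shape = _field_shape(config.field_um, ps)

    centers = _place_non_overlapping(
        rng,
        config.n_cells,
        config.field_um,
        margin_um=config.cell_radius_um + 2.0,
        min_separation_um=config.min_separation_um,
    )
    subtype_idx = rng.choice(4, size=config.n_cells, p=np.asarray(config.subtype_probs))
    subtypes = [SUBTYPES[i] for i in subtype_idx]

    def puncta_in_cell(center: np.ndarray, count: int) -> np.ndarray:
        pts = np.empty((count, 2))
        for i in range(count):
            while True:
                offset = rng.uniform(-config.cell_radius_um, config.cell_radius_um, 2)
                if np.hypot(*offset) <= config.cell_radius_um:
                    pts[i] = center + offset
                    break
        return pts

    spots: dict[str, list[np.ndarray]] = {"Pdgfra": [], "Wnt2": [], "Wnt5a": []}
    for center, subtype in zip(centers, subtypes):
        spots["Pdgfra"].append(puncta_in_cell(center, config.pdgfra_puncta_per_cell))
        for chan in SUBTYPE_CHANNELS[subtype]:
            spots[chan].append(puncta_in_cell(center, config.puncta_per_positive_channel))

    truth = GroundTruth(
        spots_um={
            chan: (np.vstack(lst) if lst else np.empty((0, 2)))
            for chan, lst in spots.items()
        },
        cell_centers_um=centers,
        cell_subtypes=subtypes,
    )

    channels: dict[str, np.ndarray] = {}
    # DAPI: solid nucleus disks over background.
    rows = np.arange(shape[0], dtype=float)[:, None] * ps
    cols = np.arange(shape[1], dtype=float)[None, :] * ps
    dapi = np.full(shape, float(config.background_level))
    for cx, cy in centers:
        dapi += config.spot_amplitude * (
            (cols - cx) ** 2 + (rows - cy) ** 2 <= config.nucleus_radius_um**2
        )
    channels["DAPI"] = _apply_noise(
        dapi, rng, config.poisson_noise, config.gaussian_noise_sigma
    )

    for chan in ("Pdgfra", "Wnt2", "Wnt5a"):
        canvas = np.full(shape, float(config.background_level))
        pts = truth.spots_um[chan]
        coords_px = np.column_stack([pts[:, 1] / ps, pts[:, 0] / ps])
        _render_gaussian_spots(canvas, coords_px, config.psf_sigma_px, config.spot_amplitude)
        channels[chan] = _apply_noise(
            canvas, rng, config.poisson_noise, config.gaussian_noise_sigma
        )

    image = CalibratedImage(
        channels=channels,
        pixel_size_um=ps,
        field_id=config.field_id,
        animal_id=config.animal_id,
        condition=config.condition,
    )
    return image, truth


def simulate_organoid_mask(
    seed: int,
    diameters_um,
    field_um: float,
    pixel_size_um: float,
) -> tuple[ObjectMask, GroundTruth]:
    """Rasterize one labeled disk per requested diameter, without overlap.

    A pixel belongs to a disk when its center lies within the disk radius of
    the disk center; disks are placed by rejection sampling with a 2 um
    clearance between boundaries.
    """
    diameters = np.asarray(list(diameters_um), dtype=float)
    rng = np.random.default_rng(seed)
    shape = _field_shape(field_um, pixel_size_um)
    labels = np.zeros(shape, dtype=np.int32)
    truth = GroundTruth(organoid_diameters_um=diameters)
    if diameters.size == 0:
        return ObjectMask(labels=labels, channel="organoid", pixel_size_um=pixel_size_um), truth

    if np.any(diameters <= 0):
        raise ValueError("diameters must be positive")
    # Place the largest disks first so tight packings still succeed.
    order = np.argsort(diameters)[::-1]
    centers = np.empty((diameters.size, 2))
    placed: list[tuple[np.ndarray, float]] = []
    max_attempts = 20000
    for idx in order:
        radius = diameters[idx] / 2.0
        lo, hi = radius + 1.0, field_um - radius - 1.0
        if hi <= lo:
            raise PlacementError(f"field {field_um} um too small for diameter {diameters[idx]} um")
        for attempt in range(max_attempts):
            p = rng.uniform(lo, hi, size=2)
            if all(
                np.hypot(*(p - q)) >= radius + r_other + 2.0 for q, r_other in placed
            ):
                centers[idx] = p
                placed.append((p, radius))
                break
        else:
            raise PlacementError("could not place organoid disks without overlap")

    rows = np.arange(shape[0], dtype=float)[:, None] * pixel_size_um
    cols = np.arange(shape[1], dtype=float)[None, :] * pixel_size_um
    for k, idx in enumerate(range(diameters.size), start=1):
        cx, cy = centers[idx]
        radius = diameters[idx] / 2.0
        labels[(cols - cx) ** 2 + (rows - cy) ** 2 <= radius**2] = k

    truth.cell_centers_um = centers
    return ObjectMask(labels=labels, channel="organoid", pixel_size_um=pixel_size_um), truth


def simulate_organoid_image(
    seed: int,
    diameters_um,
    field_um: float,
    pixel_size_um: float,
    amplitude: float = 100.0,
    background_level: float = 20.0,
    poisson_noise: bool = True,
    gaussian_noise_sigma: float = 0.0,
    field_id: str = "",
    animal_id: str = "",
    condition: str = "",
) -> tuple[CalibratedImage, ObjectMask, GroundTruth]:
    """Render the organoid mask as a noisy intensity image for segmentation tests."""
    mask, truth = simulate_organoid_mask(seed, diameters_um, field_um, pixel_size_um)
    rng = np.random.default_rng(seed + 1)
    expected = background_level + amplitude * (mask.labels > 0)
    raster = _apply_noise(expected.astype(float), rng, poisson_noise, gaussian_noise_sigma)
    image = CalibratedImage(
        channels={"organoid": raster},
        pixel_size_um=pixel_size_um,
        field_id=field_id,
        animal_id=animal_id,
        condition=condition,
    )
    return image, mask, truth
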