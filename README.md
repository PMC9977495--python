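# fishniche

Spatial quantification of Wnt-ligand RNA-FISH signal in the alveolar stem-cell
niche, for lung biologists studying how PDGFRα+ fibroblasts position
β-catenin-activating (Wnt2) versus β-catenin-inhibiting (Wnt5a) signals around
alveolar type II (AT2) progenitor cells.

The package implements, as an open and testable pipeline, the image-analysis
steps that in the original workflow lived inside proprietary microscope
software:

- **Puncta detection** — single-molecule FISH signal is punctate; each channel
  is band-pass filtered with a scale-normalized Laplacian of Gaussian tuned to
  the expected punctum diameter, local maxima above a robust contrast
  threshold are grown into objects, and every object is reduced to its
  intensity-weighted centroid ("spot").
- **Nearest-object distance mapping** — for every spot of a source channel
  (e.g. *Wnt2*), the smallest Euclidean distance to any spot of a target
  channel (e.g. *Sftpc*, marking AT2 cells):
  d_i = min_j ‖s_i − t_j‖. Distances are summarized in half-open 6 μm bins,
  so "% of signal within 6 μm" is the first bin; animals are the statistical
  unit and conditions are compared with a two-sided, equal-variance Student's
  *t* test.
- **Cell typing by dilation/intersection** — cytospun PDGFRα+ cells are
  reconstructed by dilating each *Pdgfra* object by 5 μm and merging it with
  overlapping DAPI nuclei; a cell is positive for a Wnt channel when any Wnt
  object dilated by 4 μm intersects its footprint, which yields the four
  subtypes Wnt2+, Wnt5a+, double-positive, double-negative.
- **Organoid morphometrics** — segmentation of organoid images, equivalent
  circular diameter per object, the 50 μm minimum-diameter colony rule, and
  colony-forming efficiency CFE = 100 · n_colonies / n_seeded.
- **Synthetic data with ground truth** — a first-class simulator renders
  calibrated fields (Gaussian puncta, Poisson noise) in which true spot
  positions, cell subtypes, and organoid diameters are known exactly, so
  every stage of the pipeline is verifiable without access to raw microscope
  images.

## Worked example

Simulate one lung-section field in which Wnt2 puncta sit closer to the AT2
anchors (exponential radial offset, mean 5 μm) than Wnt5a puncta (mean 9 μm),
detect spots, and map nearest distances:

```python
from fishniche import (SectionSimConfig, simulate_section_field,
                       SpotDetectionParams, detect_spots,
                       nearest_distances, bin_distances)

config = SectionSimConfig(seed=42)          # 200x200 um field, 0.5 um/px
image, truth = simulate_section_field(config)

params = SpotDetectionParams(expected_diameter_um=2.0, contrast_threshold=5.0)
spots = {ch: detect_spots(image, ch, params)[1] for ch in image.channel_names}

for wnt in ("Wnt2", "Wnt5a"):
    table = nearest_distances(spots[wnt], spots["Sftpc"])
    summary = bin_distances(table, bin_width_um=6.0)
    print(f"{wnt}: median {summary.median_um:.2f} um, "
          f"{summary.first_bin_percent:.1f}% within 6 um of Sftpc")
```

Output:

```
Wnt2: median 3.55 um, 74.9% within 6 um of Sftpc
Wnt5a: median 4.98 um, 59.5% within 6 um of Sftpc
```

The Wnt2 signal is recovered as both nearer (smaller median) and more
concentrated in the first 6 μm distance bin than Wnt5a — the spatial contrast
the niche analysis is designed to detect.  A full multi-animal run with
per-animal aggregation and the condition *t* tests is one call:

```bash
fish-niche run --config run.yaml          # mode: section | cytospin | organoid
```

The same CLI exposes each stage separately (`fish-niche simulate | detect |
map-distances | cytospin-type | organoids`); every command writes plain CSV.

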