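import numpy as np
import pytest
from scipy.spatial import cKDTree

from fishniche.cell_typing import (
    assign_wnt_status,
    build_cell_masks,
    classify_cells,
    segment_nuclei,
    subtype_from_flags,
    subtype_fractions,
    type_cytospin_field,
)
from fishniche.image_io import CalibrationError, ObjectMask
from fishniche.synthetic_data import CytospinSimConfig, simulate_cytospin_field


def mask_from_points(points_rc, shape=(64, 64), pixel_size_um=1.0, channel="c"):
    """One single-pixel object per (row, col) point, labeled in order."""
    labels = np.zeros(shape, dtype=np.int32)
    for k, (r, c) in enumerate(points_rc, start=1):
        labels[r, c] = k
    return ObjectMask(labels, channel, pixel_size_um)


def empty_mask(shape=(64, 64), pixel_size_um=1.0, channel="c"):
    return ObjectMask(np.zeros(shape, dtype=np.int32), channel, pixel_size_um)


class TestBuildCellMasks:
    def test_nucleus_3um_away_joins_footprint(self):
        # 5 um dilation at 1 um/px bridges a 3 um gap to the nucleus.
        pdgfra = mask_from_points([(30, 30)])
        dapi = mask_from_points([(30, 33)])
        cells = build_cell_masks(pdgfra, dapi, dilation_um=5.0)
        assert len(cells) == 1
        assert not cells[0].anucleate
        pix = set(zip(cells[0].rows.tolist(), cells[0].cols.tolist()))
        assert (30, 33) in pix and (30, 30) in pix

    def test_no_dapi_within_reach_is_anucleate(self):
        pdgfra = mask_from_points([(30, 30)])
        dapi = mask_from_points([(30, 45)])  # 15 um away, beyond the 5 um reach
        cells = build_cell_masks(pdgfra, dapi, dilation_um=5.0)
        assert len(cells) == 1
        assert cells[0].anucleate
        # footprint is the dilated object alone: a discrete disk of radius 5
        from skimage.morphology import disk

        assert cells[0].n_pixels == int(disk(5).sum())

    def test_two_distant_objects_make_two_cells(self):
        pdgfra = mask_from_points([(20, 20), (20, 40)])  # 20 um apart
        dapi = mask_from_points([(22, 20), (22, 40)])
        cells = build_cell_masks(pdgfra, dapi, dilation_um=5.0)
        assert len(cells) == 2
        assert not any(c.anucleate for c in cells)

    def test_overlapping_dilations_merge_into_one_cell(self):
        pdgfra = mask_from_points([(30, 30), (30, 36)])  # 6 um apart, 5 um dilation
        cells = build_cell_masks(pdgfra, empty_mask(), dilation_um=5.0)
        assert len(cells) == 1

    def test_contested_nucleus_goes_to_nearer_centroid(self):
        # One wide nucleus touching both cells' dilations, nearer to cell 1.
        pdgfra = mask_from_points([(30, 20), (30, 44)])
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[30, 23:40] = 1  # strip touching both dilations, centroid nearer cell 1
        dapi = ObjectMask(labels, "DAPI", 1.0)
        cells = build_cell_masks(pdgfra, dapi, dilation_um=5.0)
        assert len(cells) == 2
        by_id = {c.cell_id: c for c in cells}
        assert not by_id[1].anucleate
        assert by_id[2].anucleate

    def test_calibration_mismatch_rejected(self):
        with pytest.raises(CalibrationError):
            build_cell_masks(
                mask_from_points([(5, 5)], pixel_size_um=1.0),
                empty_mask(pixel_size_um=0.5),
            )


class TestAssignWntStatus:
    def test_punctum_inside_footprint_is_positive(self):
        cells = build_cell_masks(mask_from_points([(30, 30)]), empty_mask(), 5.0)
        wnt = mask_from_points([(31, 31)])
        assert assign_wnt_status(cells, wnt, 4.0).tolist() == [True]

    def test_punctum_3um_outside_is_positive_after_4um_dilation(self):
        cells = build_cell_masks(mask_from_points([(30, 30)]), empty_mask(), 5.0)
        # footprint reaches radius 5; punctum at distance 8 is 3 um outside
        wnt = mask_from_points([(30, 38)])
        assert assign_wnt_status(cells, wnt, 4.0).tolist() == [True]

    def test_punctum_beyond_dilation_reach_is_negative(self):
        cells = build_cell_masks(mask_from_points([(30, 30)]), empty_mask(), 5.0)
        wnt = mask_from_points([(30, 41)])  # 11 um away > 5 + 4
        assert assign_wnt_status(cells, wnt, 4.0).tolist() == [False]

    def test_no_wnt_objects_all_negative(self):
        cells = build_cell_masks(
            mask_from_points([(20, 20), (40, 40)]), empty_mask(), 5.0
        )
        assert assign_wnt_status(cells, empty_mask(), 4.0).tolist() == [False, False]

    def test_agrees_with_pixel_distance_oracle(self, rng):
        # positivity <=> min pixel distance between Wnt object and footprint
        # <= 4 um, up to one pixel of dilation discretization
        for trial in range(10):
            pr, pc = rng.integers(15, 49, 2)
            wr, wc = rng.integers(15, 49, 2)
            pdgfra = mask_from_points([(pr, pc)])
            wnt = mask_from_points([(wr, wc)])
            cells = build_cell_masks(pdgfra, empty_mask(), 5.0)
            got = bool(assign_wnt_status(cells, wnt, 4.0)[0])
            foot = np.column_stack([cells[0].rows, cells[0].cols]).astype(float)
            dmin = cKDTree(foot).query([[wr, wc]])[0][0]
            if abs(dmin - 4.0) > 1.0:
                assert got == (dmin <= 4.0)


class TestClassification:
    def test_subtype_mapping(self):
        assert subtype_from_flags(True, False) == "Wnt2+"
        assert subtype_from_flags(False, True) == "Wnt5a+"
        assert subtype_from_flags(True, True) == "double+"
        assert subtype_from_flags(False, False) == "double-"

    def test_four_cells_one_each_give_25_percent(self):
        pdgfra = mask_from_points(
            [(10, 10), (10, 50), (50, 10), (50, 50)], shape=(64, 64)
        )
        wnt2 = mask_from_points([(11, 10), (11, 50)])  # cells 1, 2
        wnt5a = mask_from_points([(12, 50), (51, 10)])  # cells 2, 3
        cells = build_cell_masks(pdgfra, empty_mask(), 5.0)
        result = classify_cells(cells, wnt2, wnt5a, 4.0)
        fracs = result.fractions
        assert all(v == pytest.approx(25.0) for v in fracs.values())
        assert sum(fracs.values()) == pytest.approx(100.0, abs=1e-9)

    def test_fractions_invariant_to_translation(self):
        pts = [(20, 20), (20, 44), (44, 20)]
        w2 = [(21, 20)]
        shift = 8
        res_a = classify_cells(
            build_cell_masks(mask_from_points(pts), empty_mask(), 5.0),
            mask_from_points(w2), empty_mask(), 4.0,
        )
        res_b = classify_cells(
            build_cell_masks(
                mask_from_points([(r + shift, c + shift) for r, c in pts]),
                empty_mask(), 5.0,
            ),
            mask_from_points([(r + shift, c + shift) for r, c in w2]),
            empty_mask(), 4.0,
        )
        assert res_a.fractions == res_b.fractions

    def test_exclude_anucleate_option(self):
        pdgfra = mask_from_points([(20, 20), (20, 50)])
        dapi = mask_from_points([(22, 20)])  # only cell 1 has a nucleus
        cells = build_cell_masks(pdgfra, dapi, 5.0)
        kept = classify_cells(cells, empty_mask(), empty_mask(), 4.0,
                              exclude_anucleate=True)
        assert kept.n_cells == 1


class TestEndToEnd:
    def test_simulated_field_subtypes_recovered(self):
        cfg = CytospinSimConfig(seed=13, n_cells=30, field_um=300.0)
        image, truth = simulate_cytospin_field(cfg)
        result = type_cytospin_field(image)
        assert result.n_cells == 30
        tree = cKDTree(truth.cell_centers_um)
        d, idx = tree.query(result.cells[["x_um", "y_um"]].to_numpy())
        assert d.max() < 10.0
        correct = sum(
            result.cells["subtype"].iloc[i] == truth.cell_subtypes[j]
            for i, j in enumerate(idx)
        )
        assert correct / 30 >= 0.95

    def test_nuclei_segmentation_counts_cells(self):
        cfg = CytospinSimConfig(seed=21, n_cells=12, field_um=300.0)
        image, _ = simulate_cytospin_field(cfg)
        nuclei = segment_nuclei(image, "DAPI")
        assert nuclei.n_objects == 12


class TestSubtypeFractions:
    def test_rows_per_animal_and_sum_100(self):
        cfg1 = CytospinSimConfig(seed=1, n_cells=10, field_um=250.0,
                                 pixel_size_um=2.0, animal_id="m1", condition="NC")
        cfg2 = CytospinSimConfig(seed=2, n_cells=10, field_um=250.0,
                                 pixel_size_um=2.0, animal_id="m2", condition="NC")
        results = []
        for cfg in (cfg1, cfg2):
            image, _ = simulate_cytospin_field(cfg)
            results.append(type_cytospin_field(image))
        out = subtype_fractions(results)
        assert len(out) == 2
        pct_cols = [c for c in out.columns if c.startswith("pct_")]
        np.testing.assert_allclose(out[pct_cols].sum(axis=1), 100.0)
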