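import numpy as np
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from fishniche.synthetic_data import (
    SUBTYPES,
    CytospinSimConfig,
    PlacementError,
    SectionSimConfig,
    simulate_cytospin_field,
    simulate_organoid_mask,
    simulate_section_field,
    simulate_spot_field,
)


class TestSectionField:
    def test_fixed_seed_is_bitwise_reproducible(self):
        cfg = SectionSimConfig(seed=7, field_um=100.0, n_sftpc_cells=20,
                               n_pdgfra_spots=30, wnt_counts={"Wnt2": 30, "Wnt5a": 30})
        img1, truth1 = simulate_section_field(cfg)
        img2, truth2 = simulate_section_field(cfg)
        for name in img1.channel_names:
            np.testing.assert_array_equal(img1.channel(name), img2.channel(name))
        for chan in truth1.spots_um:
            np.testing.assert_array_equal(truth1.spots_um[chan], truth2.spots_um[chan])

    def test_spot_counts_match_config_exactly(self):
        cfg = SectionSimConfig(seed=3, field_um=150.0, n_sftpc_cells=40,
                               n_pdgfra_spots=55, wnt_counts={"Wnt2": 17, "Wnt5a": 23})
        _, truth = simulate_section_field(cfg)
        assert truth.spot_count("Sftpc") == 40
        assert truth.spot_count("Pdgfra") == 55
        assert truth.spot_count("Wnt2") == 17
        assert truth.spot_count("Wnt5a") == 23

    def test_zero_wnt_counts_give_background_only_channels(self):
        cfg = SectionSimConfig(seed=5, field_um=100.0, n_sftpc_cells=10,
                               n_pdgfra_spots=10, wnt_counts={"Wnt2": 0, "Wnt5a": 0},
                               poisson_noise=False)
        img, truth = simulate_section_field(cfg)
        assert truth.spot_count("Wnt2") == 0
        np.testing.assert_array_equal(
            img.channel("Wnt2"), np.full(img.shape, cfg.background_level)
        )

    def test_offset_means_separate_wnt_channels(self):
        # Sparse anchors so a Wnt spot's nearest anchor is almost always its
        # own; the empirical gap in mean nearest-anchor distance should sit
        # within 3 standard errors of the configured 4 um difference.
        cfg = SectionSimConfig(
            seed=11, field_um=400.0, pixel_size_um=2.0, n_sftpc_cells=30,
            n_pdgfra_spots=0, wnt2_offset_mean_um=5.0, wnt5a_offset_mean_um=9.0,
            wnt_counts={"Wnt2": 300, "Wnt5a": 300},
        )
        _, truth = simulate_section_field(cfg)
        tree = cKDTree(truth.spots_um["Sftpc"])
        d2, _ = tree.query(truth.spots_um["Wnt2"])
        d5, _ = tree.query(truth.spots_um["Wnt5a"])
        assert d2.mean() < d5.mean()
        gap = d5.mean() - d2.mean()
        se = np.sqrt(d2.var(ddof=1) / len(d2) + d5.var(ddof=1) / len(d5))
        assert abs(gap - 4.0) < 3 * se

    def test_rendered_peak_sits_at_true_location(self):
        cfg = SectionSimConfig(
            seed=2, field_um=60.0, pixel_size_um=1.0, n_sftpc_cells=1,
            n_pdgfra_spots=0, wnt_counts={}, poisson_noise=False,
            background_level=0.0,
        )
        img, truth = simulate_section_field(cfg)
        x, y = truth.spots_um["Sftpc"][0]
        peak = np.unravel_index(np.argmax(img.channel("Sftpc")), img.shape)
        assert abs(peak[0] - y / cfg.pixel_size_um) <= 1
        assert abs(peak[1] - x / cfg.pixel_size_um) <= 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SectionSimConfig(wnt2_offset_mean_um=-1.0)
        with pytest.raises(ValueError):
            SectionSimConfig(n_sftpc_cells=-5)


class TestCytospinField:
    def test_degenerate_probs_give_single_subtype(self):
        cfg = CytospinSimConfig(seed=1, n_cells=20, subtype_probs=(1.0, 0, 0, 0),
                                field_um=300.0, pixel_size_um=2.0)
        _, truth = simulate_cytospin_field(cfg)
        assert all(s == "Wnt2+" for s in truth.cell_subtypes)
        assert truth.spot_count("Wnt5a") == 0

    def test_subtype_tally_is_multinomial(self):
        # 400 cells drawn at (0.3, 0.2, 0.25, 0.25): a chi-square GOF test on
        # the recorded labels should not reject at p = 0.001.
        cfg = CytospinSimConfig(
            seed=9, n_cells=400, subtype_probs=(0.3, 0.2, 0.25, 0.25),
            field_um=1000.0, pixel_size_um=4.0,
        )
        _, truth = simulate_cytospin_field(cfg)
        counts = np.array([truth.cell_subtypes.count(s) for s in SUBTYPES])
        assert counts.sum() == 400
        res = stats.chisquare(counts, f_exp=400 * np.array([0.3, 0.2, 0.25, 0.25]))
        assert res.pvalue > 0.001

    def test_fixed_seed_reproducible(self):
        cfg = CytospinSimConfig(seed=4, n_cells=10, field_um=250.0, pixel_size_um=2.0)
        img1, t1 = simulate_cytospin_field(cfg)
        img2, t2 = simulate_cytospin_field(cfg)
        assert t1.cell_subtypes == t2.cell_subtypes
        for name in img1.channel_names:
            np.testing.assert_array_equal(img1.channel(name), img2.channel(name))

    def test_cells_respect_minimum_separation(self):
        cfg = CytospinSimConfig(seed=6, n_cells=15, field_um=300.0,
                                pixel_size_um=2.0, min_separation_um=30.0)
        _, truth = simulate_cytospin_field(cfg)
        centers = truth.cell_centers_um
        dists = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        np.fill_diagonal(dists, np.inf)
        assert dists.min() >= 30.0

    def test_impossible_packing_raises(self):
        with pytest.raises(PlacementError):
            simulate_cytospin_field(
                CytospinSimConfig(seed=0, n_cells=200, field_um=100.0,
                                  pixel_size_um=2.0, min_separation_um=30.0)
            )

    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CytospinSimConfig(subtype_probs=(0.5, 0.2, 0.2, 0.2))


class TestOrganoidMask:
    def test_single_disk_area_matches_circle(self):
        mask, truth = simulate_organoid_mask(
            seed=0, diameters_um=[60.0], field_um=200.0, pixel_size_um=1.0
        )
        assert mask.n_objects == 1
        area = int((mask.labels == 1).sum())
        assert abs(area - np.pi * 30.0**2) / (np.pi * 30.0**2) < 0.02

    def test_empty_diameter_list_gives_empty_mask(self):
        mask, truth = simulate_organoid_mask(
            seed=0, diameters_um=[], field_um=100.0, pixel_size_um=1.0
        )
        assert mask.n_objects == 0

    def test_fixed_seed_reproducible(self):
        a, _ = simulate_organoid_mask(1, [40, 60], 300.0, 1.0)
        b, _ = simulate_organoid_mask(1, [40, 60], 300.0, 1.0)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_field_too_small_raises(self):
        with pytest.raises(PlacementError):
            simulate_organoid_mask(0, [150.0], 100.0, 1.0)


class TestSpotField:
    def test_spots_keep_minimum_separation(self):
        _, truth = simulate_spot_field(seed=2, n_spots=100, field_um=150.0,
                                       min_separation_um=2.5)
        pts = truth.spots_um["spots"]
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2.5
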