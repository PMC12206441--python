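"""Segmentation pipeline: nuclei, cells, membrane ring, trafficking metrics."""

import numpy as np
import pandas as pd
import pytest

from kirquant import image_quant as iq
from kirquant.synthetic import cell_field_preset, simulate_cell_field

from conftest import best_match_iou


class TestNucleusSegmentation:
    def test_blank_image_yields_no_nuclei(self):
        assert iq.segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_counts_and_iou_with_nucleoli(self, noiseless_field):
        img, truth = noiseless_field
        labels = iq.segment_nuclei(img.nuclei)
        assert labels.max() == 5
        for cid in truth.cells.cell_id:
            assert best_match_iou(labels, truth.nucleus_labels == cid) >= 0.9

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((80, 120))
        yy, xx = np.mgrid[0:80, 0:120]
        for cx in (48, 71):  # centres 23 px apart, radius 12 -> touching blob
            img[(yy - 40) ** 2 + (xx - cx) ** 2 <= 144] = 150.0
        labels = iq.segment_nuclei(img)
        assert labels.max() == 2


class TestCellSegmentation:
    def test_single_cell_iou(self):
        p = cell_field_preset("WT", seed=21, n_cells=1, noise_gaussian_sd=0.0)
        img, truth = simulate_cell_field(p)
        seg = iq.segment_field(img)
        assert seg.cell_labels.max() == 1
        assert best_match_iou(seg.cell_labels, truth.cell_labels == 1) >= 0.8

    def test_exact_counts_on_nonoverlapping_fields(self):
        for n in (2, 7, 13):
            p = cell_field_preset("WT", seed=40 + n, n_cells=n, noise_gaussian_sd=0.0)
            img, _ = simulate_cell_field(p)
            seg = iq.segment_field(img)
            assert seg.cell_labels.max() == n
            assert len(np.unique(seg.nucleus_labels)) - 1 == n

    def test_each_cell_contains_its_nucleus(self, noiseless_field):
        img, _ = noiseless_field
        seg = iq.segment_field(img)
        for lab in range(1, seg.nucleus_labels.max() + 1):
            covered = seg.cell_labels[seg.nucleus_labels == lab]
            assert (covered == lab).all()

    def test_no_nuclei_is_an_upstream_error(self):
        with pytest.raises(ValueError, match="nucle"):
            iq.segment_cells(np.zeros((32, 32), dtype=np.int32), np.ones((32, 32)))

    def test_zero_cytoplasm_collapses_to_flagged_dilated_nuclei(self):
        p = cell_field_preset("WT", seed=9, n_cells=3, noise_gaussian_sd=0.0,
                              marker_intensity=0.0, total_expression=0.0)
        img, _ = simulate_cell_field(p)
        nuc = iq.segment_nuclei(img.nuclei)
        cells, radius, flags = iq.segment_cells(nuc, img.marker + img.target)
        assert "low_foreground" in flags.get(0, [])
        assert cells.max() == 3
        cfg = iq.ImageQuantConfig()
        # cap honoured: no cell pixel farther than cap_factor x median radius
        from skimage import measure

        for region in measure.regionprops(nuc):
            cy, cx = region.centroid
            yy, xx = np.nonzero(cells == region.label)
            d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            assert d.max() <= cfg.cap_factor * radius + region.equivalent_diameter


class TestMembraneSegmentation:
    def test_ring_iou(self, noiseless_field):
        img, truth = noiseless_field
        seg = iq.segment_field(img)
        for cid in truth.cells.cell_id:
            assert best_match_iou(seg.membrane_labels, truth.membrane_labels == cid) >= 0.8

    def test_ring_disjoint_from_eroded_interior(self, noiseless_field):
        img, _ = noiseless_field
        seg = iq.segment_field(img)
        from skimage import morphology

        cfg = iq.ImageQuantConfig()
        w = cfg.membrane_width_px + cfg.boundary_slack_px
        interior = morphology.erosion(seg.cell_labels > 0, morphology.disk(w))
        assert not (interior & (seg.membrane_labels > 0)).any()

    def test_zero_marker_gives_empty_mask_and_flags(self, noiseless_field):
        img, _ = noiseless_field
        nuc = iq.segment_nuclei(img.nuclei)
        cells, _, _ = iq.segment_cells(nuc, img.marker + img.target)
        membrane, flags = iq.segment_membrane(np.zeros_like(img.marker), cells)
        assert membrane.max() == 0
        assert all("no_marker" in v for v in flags.values())

    def test_candidate_band_grows_with_width(self, noiseless_field):
        img, _ = noiseless_field
        nuc = iq.segment_nuclei(img.nuclei)
        cells, _, _ = iq.segment_cells(nuc, img.marker + img.target)
        areas = []
        for w in (1, 3, 5):
            cfg = iq.ImageQuantConfig(membrane_width_px=w, marker_threshold=-1.0)
            membrane, _ = iq.segment_membrane(img.marker, cells, cfg)
            areas.append((membrane > 0).sum())
        assert areas[0] < areas[1] < areas[2]


class TestMembraneQuantification:
    def test_fraction_recovered_within_tolerance(self):
        p = cell_field_preset("WT", seed=3, n_cells=5, noise_gaussian_sd=0.0,
                              membrane_fraction=0.6)
        img, _ = simulate_cell_field(p)
        df = iq.quantify_field(img)
        assert np.all(np.abs(df["mem_fraction_of_total"] - 0.6) <= 0.05)

    def test_null_membrane_fraction_bounded_leakage(self):
        p = cell_field_preset("WT", seed=6, n_cells=4, noise_gaussian_sd=0.0,
                              membrane_fraction=0.0)
        img, _ = simulate_cell_field(p)
        df = iq.quantify_field(img)
        assert np.all(df["mem_fraction_of_total"] < 0.05)

    def test_monotone_in_generator_membrane_fraction(self):
        from scipy.stats import spearmanr

        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for mf in grid:
            p = cell_field_preset("WT", seed=11, n_cells=6, noise_gaussian_sd=0.0,
                                  membrane_fraction=mf)
            img, _ = simulate_cell_field(p)
            df = iq.quantify_field(img)
            assert np.all(np.abs(df["mem_fraction_of_total"] - mf) <= 0.05)
            means.append(df["mem_fraction_of_total"].mean())
        assert np.all(np.diff(means) > 0)
        rho, _ = spearmanr(grid, means)
        assert rho == pytest.approx(1.0)

    def test_homogeneity_under_expression_scaling(self):
        base = cell_field_preset("WT", seed=13, n_cells=4, noise_gaussian_sd=0.0)
        img1, _ = simulate_cell_field(base)
        img2, _ = simulate_cell_field(
            cell_field_preset("WT", seed=13, n_cells=4, noise_gaussian_sd=0.0,
                              total_expression=2 * base.total_expression)
        )
        df1 = iq.quantify_field(img1).set_index("cell_id")
        df2 = iq.quantify_field(img2).set_index("cell_id")
        assert np.allclose(
            df1["mem_fraction_of_total"], df2["mem_fraction_of_total"], atol=0.01
        )
        assert np.allclose(
            df2["mem_signal_per_area"], 2.0 * df1["mem_signal_per_area"], rtol=0.01
        )

    def test_fraction_always_within_unit_interval(self):
        for grp, seed in (("WT", 1), ("MT", 2)):
            img, _ = simulate_cell_field(cell_field_preset(grp, seed=seed))
            df = iq.quantify_field(img, group=grp)
            frac = df["mem_fraction_of_total"].dropna()
            assert ((frac >= 0.0) & (frac <= 1.0)).all()

    def test_zero_total_target_flagged(self):
        p = cell_field_preset("WT", seed=4, n_cells=2, noise_gaussian_sd=0.0,
                              total_expression=0.0)
        img, _ = simulate_cell_field(p)
        seg = iq.segment_field(img)
        quants = iq.quantify_membrane(img.target, seg)
        assert all(np.isnan(q.mem_fraction_of_total) for q in quants)
        assert all("zero_total_target" in q.flags for q in quants)


class TestAggregation:
    def _two_group_frames(self, identical=False):
        frames = {}
        for grp, seed in (("WT", 31), ("MT", 31 if identical else 32)):
            preset = "WT" if identical else grp
            img, _ = simulate_cell_field(cell_field_preset(preset, seed=seed, n_cells=6))
            frames[grp] = iq.quantify_field(img)
        return frames

    def test_direction_of_effect(self):
        frames = self._two_group_frames()
        agg = iq.aggregate_cells(frames, positivity_threshold=100.0)
        means = agg.groupby("group")["mem_fraction_of_total"].mean()
        per_area = agg.groupby("group")["mem_signal_per_area"].mean()
        assert means["WT"] > means["MT"]
        assert per_area["WT"] > per_area["MT"]

    def test_identical_groups_not_significant(self):
        from kirquant.stats import t_unpaired

        frames = self._two_group_frames(identical=True)
        agg = iq.aggregate_cells(frames)
        wt = agg.loc[agg["group"] == "WT", "mem_fraction_of_total"]
        mt = agg.loc[agg["group"] == "MT", "mem_fraction_of_total"]
        cmp = t_unpaired(wt, mt, labels=("WT", "MT"))
        assert cmp.stars == "ns" and cmp.p_value == pytest.approx(1.0)

    def test_positivity_threshold_above_all_cells_errors(self):
        frames = self._two_group_frames()
        with pytest.raises(ValueError, match="positivity"):
            iq.aggregate_cells(frames, positivity_threshold=1e12)

    def test_single_group_rejected(self):
        img, _ = simulate_cell_field(cell_field_preset("WT", seed=1, n_cells=3))
        with pytest.raises(ValueError, match="two groups"):
            iq.aggregate_cells(iq.quantify_field(img, group="WT"))
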