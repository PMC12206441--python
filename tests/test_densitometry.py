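"""Lane densitometry: profiles, background, band detection, normalisation."""

import numpy as np
import pandas as pd
import pytest

from kirquant import densitometry as dens
from kirquant.synthetic import BlotSimParams, blot_preset, default_ladder, simulate_blot


def _quantify(params, ladder=None):
    stack, lad, truth = simulate_blot(
        params if isinstance(params, list) else [params], ladder
    )
    quants = []
    for img, p in zip(stack, params if isinstance(params, list) else [params]):
        prof = dens.extract_lane_profile(
            img, (0, img.shape[1]), lane_id=p.lane_id, calibration=lad
        )
        quants.append(dens.quantify_lane(prof, group=p.group, treatment=p.treatment))
    return quants, truth


class TestProfileExtraction:
    def test_uniform_image_flat_profile(self):
        prof = dens.extract_lane_profile(np.full((200, 30), 7.0), (5, 25))
        assert np.allclose(prof.intensity, 7.0)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            dens.extract_lane_profile(np.zeros((100, 20)), (10, 30))

    def test_two_bands_peak_at_true_centers(self):
        p = BlotSimParams(abundance=300.0, upper_frac=0.5, noise_sd=0.0,
                          background_level=0.0, background_tilt=0.0)
        stack, ladder, _ = simulate_blot([p])
        prof = dens.extract_lane_profile(stack[0], (0, 40), calibration=ladder)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(prof.intensity, height=1.0)
        expected = sorted(
            float(ladder.mw_to_pos(m)) for m in (50.0, 45.0, 43.0)
        )
        assert len(peaks) == 3
        assert np.allclose(sorted(peaks), expected, atol=1.0)


class TestBackgroundSubtraction:
    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(0)
        y = np.zeros(300)
        y[100:110] = 50.0
        base = dens.LaneProfile(np.arange(300.0), y)
        shifted = dens.LaneProfile(np.arange(300.0), y + 25.0)
        a = dens.subtract_background(base).intensity
        b = dens.subtract_background(shifted).intensity
        assert np.allclose(a, b)

    def test_all_zero_profile_stays_zero(self):
        prof = dens.LaneProfile(np.arange(100.0), np.zeros(100))
        assert np.allclose(dens.subtract_background(prof).intensity, 0.0)

    def test_tilted_baseline_recovered_within_2_percent(self):
        p = BlotSimParams(abundance=300.0, upper_frac=0.7, noise_sd=0.0,
                          background_level=40.0, background_tilt=0.05)
        quants, truth = _quantify(p)
        q, row = quants[0], truth.lanes.iloc[0]
        assert q.upper == pytest.approx(row.true_upper, rel=0.02)
        assert q.lower == pytest.approx(row.true_lower, rel=0.02)
        assert q.loading == pytest.approx(row.true_loading, rel=0.02)

    def test_too_short_profile_rejected(self):
        prof = dens.LaneProfile(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError, match="short"):
            dens.subtract_background(prof)


class TestBandDetection:
    def test_integrated_amounts_within_3_percent(self):
        p = BlotSimParams(abundance=300.0, upper_frac=2.0 / 3.0, noise_sd=0.0)
        quants, _ = _quantify(p)
        assert quants[0].upper == pytest.approx(200.0, rel=0.03)
        assert quants[0].lower == pytest.approx(100.0, rel=0.03)

    def test_collapsed_band_flags_upper_absent(self):
        p = BlotSimParams(abundance=300.0, upper_frac=0.0, noise_sd=0.0)
        quants, _ = _quantify(p)
        assert "upper_absent" in quants[0].flags
        assert quants[0].upper == 0.0
        assert quants[0].lower == pytest.approx(300.0, rel=0.03)

    def test_empty_lane_all_bands_absent(self):
        p = BlotSimParams(abundance=0.0, tubulin_amount=0.0, noise_sd=0.0,
                          background_level=10.0)
        quants, _ = _quantify(p)
        assert {"upper_absent", "lower_absent", "loading_absent"} <= set(quants[0].flags)

    def test_additivity_of_integration(self):
        # splitting the target mass across the two glycoform bands conserves
        # the integrated total
        totals = []
        for uf in (0.3, 0.7):
            p = BlotSimParams(abundance=240.0, upper_frac=uf, noise_sd=0.0)
            quants, _ = _quantify(p)
            totals.append(quants[0].total_target)
        assert totals[0] == pytest.approx(totals[1], rel=0.02)
        assert totals[0] == pytest.approx(240.0, rel=0.02)

    @pytest.mark.parametrize("uf", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_ratio_tracks_truth_across_grid(self, uf):
        p = BlotSimParams(abundance=300.0, upper_frac=uf, noise_sd=0.0)
        quants, _ = _quantify(p)
        true_ratio = uf / (1.0 - uf)
        assert dens.band_ratio(quants[0]) == pytest.approx(true_ratio, rel=0.05)


class TestRatiosAndNormalisation:
    def test_ratio_arithmetic(self):
        lq = dens.LaneQuant("x", upper=200.0, lower=100.0, loading=150.0)
        assert dens.band_ratio(lq) == pytest.approx(2.0)

    def test_zero_lower_band_flags_not_infinity(self):
        lq = dens.LaneQuant("x", upper=200.0, lower=0.0, loading=150.0)
        assert np.isnan(dens.band_ratio(lq))
        assert "ratio_undefined" in lq.flags

    def test_untreated_and_deglycosylated_preset_ratios(self):
        wt, _ = _quantify(blot_preset("WT", seed=1, jitter_abundance=False))
        png, _ = _quantify(blot_preset("WT_PNGaseF", seed=1, jitter_abundance=False))
        assert dens.band_ratio(wt[0]) >= 2.0
        assert dens.band_ratio(png[0]) <= 0.5

    def test_reference_lanes_normalise_to_one(self):
        lanes = [dens.LaneQuant(f"wt{i}", group="WT", upper=200.0 + i, lower=100.0,
                                loading=150.0) for i in range(3)]
        out = dens.normalize_to_reference(lanes, ("WT", "none"))
        assert out["fold_change"].mean() == pytest.approx(1.0)

    def test_exposure_scale_invariance(self):
        lanes = [
            dens.LaneQuant("wt", group="WT", upper=200.0, lower=100.0, loading=150.0),
            dens.LaneQuant("mt", group="MT", upper=80.0, lower=40.0, loading=150.0),
        ]
        scaled = [
            dens.LaneQuant(l.lane_id, group=l.group, upper=3 * l.upper,
                           lower=3 * l.lower, loading=3 * l.loading)
            for l in lanes
        ]
        f1 = dens.normalize_to_reference(lanes, "WT")["fold_change"]
        f2 = dens.normalize_to_reference(scaled, "WT")["fold_change"]
        assert np.allclose(f1, f2)

    def test_ratio_invariant_to_loading(self):
        a = dens.LaneQuant("x", upper=200.0, lower=100.0, loading=150.0)
        b = dens.LaneQuant("x", upper=200.0, lower=100.0, loading=300.0)
        assert dens.band_ratio(a) == dens.band_ratio(b)

    def test_mutant_fold_change_from_rendered_lanes(self):
        params = [blot_preset("WT", seed=s, lane_id=f"WT-{s}") for s in (1, 2, 3)]
        params += [blot_preset("MT", seed=s, lane_id=f"MT-{s}") for s in (4, 5, 6)]
        quants, _ = _quantify(params)
        out = dens.normalize_to_reference(quants, ("WT", "none"))
        mt_mean = out.loc[out["group"] == "MT", "fold_change"].mean()
        assert mt_mean == pytest.approx(0.40, abs=0.08)
        assert mt_mean < 0.5

    def test_missing_reference_rejected(self):
        lanes = [dens.LaneQuant("mt", group="MT", upper=80.0, lower=40.0, loading=150.0)]
        with pytest.raises(ValueError, match="reference"):
            dens.normalize_to_reference(lanes, ("WT", "none"))

    def test_nt_lanes_excluded_from_reference(self):
        lanes = [
            dens.LaneQuant("nt", group="NT", upper=1.0, lower=1.0, loading=150.0),
            dens.LaneQuant("wt", group="WT", upper=200.0, lower=100.0, loading=150.0),
        ]
        out = dens.normalize_to_reference(lanes, lambda row: True)
        wt_fold = out.loc[out["group"] == "WT", "fold_change"].iloc[0]
        assert wt_fold == pytest.approx(1.0)

    def test_band_table_roundtrip(self):
        df = pd.DataFrame(
            {
                "lane_id": ["a", "b"],
                "group": ["WT", "MT"],
                "treatment": ["none", "none"],
                "upper": [200.0, 80.0],
                "lower": [100.0, 40.0],
                "loading": [150.0, 150.0],
            }
        )
        lanes = dens.lanes_from_table(df)
        out = dens.lane_table(lanes)
        assert out["norm_expression"].tolist() == [pytest.approx(2.0), pytest.approx(0.8)]
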