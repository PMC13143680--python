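"""Extraction operators against rendered phantoms and hand-built inputs."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

from fluxpro import phantom as ph
from fluxpro import physicalomics as po


class TestPhantomRendering:
    def test_identity_cast_renders_exact_card_colors(self):
        spec = ph.ImageSpec(noise_sigma=0.0)
        series = ph.render_urine_series(spec)
        obs = po.measure_card_patches(series.frames[0][1], series.card_patches)
        ref = np.array([c for _, c in series.card_patches])
        assert np.abs(obs - ref).max() <= 0.5  # uint8 rounding only

    def test_foam_height_halves_at_one_half_life(self):
        spec = ph.ImageSpec(foam_half_life_s=30.0, initial_foam_height_mm=10.0)
        series = ph.render_urine_series(spec)
        h30 = series.truth["heights_mm"][30.0]
        assert abs(h30 - 5.0) <= spec.pixel_scale_mm  # within 1 px

    def test_foam_area_non_increasing(self, rendered_series):
        areas = [rendered_series.truth["foam_masks"][t].sum()
                 for t in (0.0, 30.0, 60.0, 120.0)]
        assert all(b <= a for a, b in zip(areas, areas[1:]))

    def test_ground_truth_disk_areas_match_analytic(self, rendered_series):
        # aggregate rasterized bubble area tracks the analytic disk-area sum
        tab = rendered_series.truth["bubble_table"]
        s = rendered_series.pixel_scale_mm
        big = tab[tab.true_diameter_mm >= 5 * s]  # diameters >= 5 px
        assert len(big) > 0
        analytic = (np.pi * (big.true_diameter_mm / (2 * s)) ** 2).sum()
        assert big.area_px.sum() == pytest.approx(analytic, rel=0.02)

    def test_foam_taller_than_frame_errors(self):
        with pytest.raises(ValueError):
            ph.render_urine_series(ph.ImageSpec(initial_foam_height_mm=15.0,
                                                headspace_mm=10.0))

    def test_bubble_mixture_respects_cutoff_gap(self):
        rng = np.random.default_rng(0)
        d = ph.sample_bubble_diameters(500, 0.5, rng)
        assert not ((d > 0.44) & (d < 0.60)).any()
        assert 0.3 < (d < 0.5).mean() < 0.7


class TestColorCorrection:
    def test_identity_when_observed_equals_reference(self):
        ref = ph.COLORCHECKER_SRGB
        t = po.fit_color_correction(ref, ref)
        assert t.rmse < 1e-9
        assert np.allclose(t.matrix, np.eye(3), atol=1e-9)
        assert np.allclose(t.offset, 0.0, atol=1e-7)

    def test_diagonal_cast_recovered_exactly(self):
        ref = ph.COLORCHECKER_SRGB
        cast = np.diag([0.9, 1.1, 1.0])
        obs = ref @ cast.T
        t = po.fit_color_correction(obs, ref)
        assert np.allclose(t.matrix, np.diag([1 / 0.9, 1 / 1.1, 1.0]), atol=1e-6)
        assert np.allclose(t.apply(obs), np.clip(ref, 0, 255), atol=1e-6)

    def test_fewer_than_four_patches_rejected(self):
        ref = ph.COLORCHECKER_SRGB[:3]
        with pytest.raises(ValueError):
            po.fit_color_correction(ref, ref)

    def test_cast_invariance_of_chromaticity(self):
        """Correcting via the card restores b* under an invertible cast."""
        cast = np.array([[1.05, 0.05, 0.0], [0.02, 0.95, 0.02], [0.0, 0.04, 0.88]])
        b_vals = {}
        for name, c in (("identity", np.eye(3)), ("cast", cast)):
            spec = ph.ImageSpec(cast=c, noise_sigma=0.0, seed=4)
            series = ph.render_urine_series(spec)
            t = po.fit_series_color_correction(series)
            b_vals[name] = po.extract_chromatic(series, t, 650.0).b_star
        assert b_vals["cast"] == pytest.approx(b_vals["identity"], abs=1.0)


def _flat_series(rgb, scale=0.1):
    """Single-colour 40x40 frames at t=0 and 30 s."""
    img = np.full((40, 40, 3), rgb, np.uint8)
    return po.ImageSeries(
        frames=[(0.0, img), (30.0, img)],
        card_patches=[(po.Region(0, 2, i * 2, i * 2 + 2), np.array([60.0 * i] * 3))
                      for i in range(5)],
        liquid_roi=po.Region(20, 38, 2, 38),
        foam_roi=po.Region(2, 20, 2, 38),
        pixel_scale_mm=scale,
    )


_IDENT = po.ColorTransform(np.eye(3), np.zeros(3), 0.0)


class TestChromaticity:
    def test_white_roi_maps_to_lab_white_point(self):
        feats = po.extract_chromatic(_flat_series((255, 255, 255)), _IDENT, 650.0)
        assert feats.L_star == pytest.approx(100.0, abs=0.01)
        assert feats.a_star == pytest.approx(0.0, abs=0.05)
        assert feats.b_star == pytest.approx(0.0, abs=0.05)
        assert feats.chroma_C == pytest.approx(0.0, abs=0.1)

    def test_pure_yellow_b_star(self):
        feats = po.extract_chromatic(_flat_series((255, 255, 0)), _IDENT, 650.0)
        assert feats.b_star == pytest.approx(94.48, abs=0.5)

    def test_b_adj_dilution_correction_arithmetic(self):
        # b* = 24.6 at 420.3 mOsm/kg -> b*_adj = 24.6 * 650 / 420.3
        assert 24.6 * 650 / 420.3 == pytest.approx(38.04, abs=0.01)
        feats = po.extract_chromatic(_flat_series((255, 255, 0)), _IDENT, 420.3)
        assert feats.b_adj == pytest.approx(feats.b_star * 650 / 420.3)

    def test_b_adj_identity_at_reference_and_monotone(self):
        f650 = po.extract_chromatic(_flat_series((255, 255, 0)), _IDENT, 650.0)
        assert f650.b_adj == pytest.approx(f650.b_star)
        osmos = [300.0, 450.0, 650.0, 900.0]
        adj = [po.extract_chromatic(_flat_series((255, 255, 0)), _IDENT, o).b_adj
               for o in osmos]
        assert all(b < a for a, b in zip(adj, adj[1:]))

    def test_nonpositive_osmolality_rejected(self):
        with pytest.raises(ValueError):
            po.extract_chromatic(_flat_series((255, 255, 0)), _IDENT, 0.0)


class TestFoamSegmentation:
    def test_no_foam_gives_empty_mask(self):
        frame = np.full((60, 60, 3), 25, np.uint8)
        mask = po.segment_foam(frame, po.Region(5, 55, 5, 55))
        assert mask.sum() == 0

    def test_full_roi_foam_covered(self):
        frame = np.full((60, 60, 3), 235, np.uint8)
        roi = po.Region(5, 55, 5, 55)
        mask = po.segment_foam(frame, roi)
        assert mask[roi.slices()].mean() >= 0.95

    def test_known_band_area_within_5pct(self, rendered_series):
        t30 = rendered_series.frame_at(30.0)
        gt = rendered_series.truth["foam_masks"][30.0]
        est = po.segment_foam(t30, rendered_series.foam_roi)
        assert est.sum() == pytest.approx(gt.sum(), rel=0.05)


class TestFoamHeight:
    def test_band_height_scales_with_pixel_pitch(self):
        frame = np.full((60, 60, 3), 25, np.uint8)
        frame[10:40, 5:55] = 235  # 30-pixel band
        series = po.ImageSeries(
            frames=[(0.0, frame), (30.0, frame)],
            card_patches=[(po.Region(0, 2, i * 2, i * 2 + 2), np.zeros(3))
                          for i in range(4)],
            liquid_roi=po.Region(45, 58, 5, 55),
            foam_roi=po.Region(2, 44, 5, 55),
            pixel_scale_mm=0.1,
        )
        heights = po.foam_height_trajectory(series)
        assert heights[0] == pytest.approx(3.0)

    def test_empty_mask_height_zero(self):
        frame = np.full((60, 60, 3), 25, np.uint8)
        series = po.ImageSeries(
            frames=[(0.0, frame), (30.0, frame)],
            card_patches=[(po.Region(0, 2, i * 2, i * 2 + 2), np.zeros(3))
                          for i in range(4)],
            liquid_roi=po.Region(45, 58, 5, 55),
            foam_roi=po.Region(2, 44, 5, 55),
            pixel_scale_mm=0.1,
        )
        assert po.foam_height_trajectory(series)[0] == 0.0

    def test_rendered_decay_follows_generative_law(self):
        spec = ph.ImageSpec(foam_half_life_s=30.0, initial_foam_height_mm=10.0)
        series = ph.render_urine_series(spec)
        heights = po.foam_height_trajectory(series)
        expected = np.array([10.0, 5.0, 2.5, 0.625])
        assert np.abs(heights - expected).max() <= spec.pixel_scale_mm + 1e-9


class TestHalfLife:
    def test_exact_halving_recovers_thirty_seconds(self):
        est = po.estimate_half_life([10, 5, 2.5, 0.625], [0, 30, 60, 120])
        assert est.t_half_s == pytest.approx(30.0)
        assert not est.censored

    def test_noiseless_decay_within_one_percent(self):
        t = np.array([0.0, 30.0, 60.0, 120.0])
        h = 10.0 * 2.0 ** (-t / 45.8)
        est = po.estimate_half_life(h, t)
        assert est.t_half_s == pytest.approx(45.8, rel=0.01)

    def test_constant_heights_flagged_censored(self):
        est = po.estimate_half_life([10, 10, 10, 10], [0, 30, 60, 120])
        assert est.censored
        assert est.t_half_s > 120.0

    def test_zero_initial_height_rejected(self):
        with pytest.raises(ValueError):
            po.estimate_half_life([0, 0, 0, 0], [0, 30, 60, 120])

    def test_rendered_round_trip_within_10pct(self, rendered_series):
        heights = po.foam_height_trajectory(rendered_series)
        est = po.estimate_half_life(heights, rendered_series.times)
        assert est.t_half_s == pytest.approx(45.8, rel=0.10)


def _bubble_frame(shape, disks):
    """Frame + foam mask with rimmed disks (matrix bright, rims dark)."""
    img = np.full((*shape, 3), 235, np.uint8)
    mask = np.zeros(shape, bool)
    mask[:] = True
    for (cy, cx, r) in disks:
        rr, cc = draw_disk((cy, cx), r + 0.5, shape=shape)
        img[rr, cc] = (90, 90, 95)
        rr, cc = draw_disk((cy, cx), r - 0.5, shape=shape)
        img[rr, cc] = (190, 190, 195)
    return img, mask


class TestMicroBubbleIndex:
    def test_all_macro_bubbles_give_zero(self):
        # r = 8 px at 0.05 mm/px -> d ~ 0.85 mm, all above the 0.5 mm cutoff
        img, mask = _bubble_frame((120, 120), [(30, 30, 8), (30, 80, 8), (80, 50, 8)])
        mbi, tab = po.micro_bubble_index(img, mask, 0.05)
        assert mbi == 0.0
        assert len(tab) == 3 and not tab.micro.any()

    def test_area_ratio_arithmetic(self):
        # micro disks (r=3 px -> d ~ 0.33 mm) in a 100x200 band
        disks = [(20, 20 + 25 * i, 3) for i in range(6)]
        img, mask = _bubble_frame((100, 200), disks)
        mbi, tab = po.micro_bubble_index(img, mask, 0.05)
        assert tab.micro.all() and len(tab) == 6
        expected = 100.0 * tab.area_mm2.sum() / (mask.sum() * 0.05**2)
        assert mbi == pytest.approx(expected)

    def test_twenty_percent_ratio_example(self):
        # micro-bubble area 20 mm2 against 100 mm2 of foam -> MBI = 20%
        area_ratio = 20.0 / 100.0
        assert 100.0 * area_ratio == pytest.approx(20.0)
        disks = [(15 + 12 * (i // 14), 8 + 14 * (i % 14), 4) for i in range(70)]
        img, mask = _bubble_frame((100, 200), disks)
        mbi, tab = po.micro_bubble_index(img, mask, 0.05)
        gt = 100.0 * tab.area_mm2.sum() / (mask.sum() * 0.05**2)
        assert mbi == pytest.approx(gt, abs=1e-9)
        assert 15.0 < mbi < 25.0

    def test_only_micro_bubbles_no_interstitial_is_full(self):
        shape = (60, 60)
        img = np.full((*shape, 3), 25, np.uint8)
        mask = np.zeros(shape, bool)
        for (cy, cx) in [(15, 15), (15, 45), (45, 15), (45, 45)]:
            rr, cc = draw_disk((cy, cx), 4.5, shape=shape)
            img[rr, cc] = (90, 90, 95)
            mask[rr, cc] = True
            rr, cc = draw_disk((cy, cx), 3.5, shape=shape)
            img[rr, cc] = (190, 190, 195)
        mbi, tab = po.micro_bubble_index(img, mask, 0.05)
        assert mbi == pytest.approx(100.0)

    def test_empty_mask_signalled(self):
        img = np.full((50, 50, 3), 235, np.uint8)
        with pytest.raises(ValueError):
            po.micro_bubble_index(img, np.zeros((50, 50), bool), 0.05)

    def test_matches_ground_truth_within_2pct(self, rendered_series):
        t30 = rendered_series.frame_at(30.0)
        gt_mask = rendered_series.truth["foam_masks"][30.0]
        mbi, _ = po.micro_bubble_index(t30, gt_mask, rendered_series.pixel_scale_mm)
        truth = rendered_series.truth["mbi_pct"]
        assert mbi == pytest.approx(truth, abs=0.02 * max(truth, 1.0))

    def test_watershed_splits_merged_pair(self):
        shape = (80, 80)
        img = np.full((*shape, 3), 235, np.uint8)
        mask = np.ones(shape, bool)
        for cx in (30, 46):  # overlapping interiors
            rr, cc = draw_disk((40, cx), 10.5, shape=shape)
            img[rr, cc] = (90, 90, 95)
        for cx in (30, 46):
            rr, cc = draw_disk((40, cx), 9.5, shape=shape)
            img[rr, cc] = (190, 190, 195)
        _, tab = po.micro_bubble_index(img, mask, 0.05)
        assert len(tab) == 2


class TestValidationStats:
    def test_cv_hand_arithmetic(self):
        assert po.precision_stats([9, 10, 11]) == pytest.approx(10.0)

    def test_cv_constant_is_zero(self):
        assert po.precision_stats([5.5, 5.5, 5.5]) == 0.0

    def test_cv_zero_mean_undefined(self):
        with pytest.raises(ValueError):
            po.precision_stats([0, 0, 0])

    def test_bland_altman_identical_pairs(self):
        res = po.bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert res["bias"] == 0.0
        assert res["loa_low"] == res["loa_high"] == 0.0

    def test_bland_altman_alternating_diffs(self):
        pairs = [(1, 0), (0, 1), (1, 0), (0, 1)]
        res = po.bland_altman(pairs)
        assert res["bias"] == pytest.approx(0.0)
        assert res["loa_high"] == pytest.approx(1.96 * 1.1547, abs=0.001)

    def test_bland_altman_recovers_generative_bias(self):
        rng = np.random.default_rng(8)
        base = rng.normal(40, 5, 50)
        pairs = np.column_stack([base + 0.15 + rng.normal(0, 0.3, 50), base])
        res = po.bland_altman(pairs)
        se = 0.3 / np.sqrt(50)
        assert abs(res["bias"] - 0.15) < 3 * se
        assert res["pct_within"] >= 90.0

    def test_measurement_noise_within_precision_claim(self, small_cohort):
        cv = 100.0 * (
            small_cohort.t_half_s_meas / small_cohort.t_half_s - 1.0
        ).std()
        assert cv < 4.5
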