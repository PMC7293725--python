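import dataclasses

import numpy as np
import pytest

from steatoquant import (
    DegenerateInputError,
    GraySlide,
    QuantConfig,
    Region,
    SlideImage,
    adaptive_gray_filter,
    compute_steatosis,
    detect_candidate_regions,
    filter_regions,
    quantify_slide,
    segment_tissue,
    to_gray,
)
from steatoquant.image_io import BinaryMask
from steatoquant.synthetic import SlideSpec, generate_slide

from .oracles import background_from_border, crack_perimeter_loop


def gray_from(arr) -> GraySlide:
    return GraySlide(np.asarray(arr, dtype=float))


def rgb(arr01) -> SlideImage:
    vals = np.round(np.asarray(arr01) * 255).astype(np.uint8)
    return SlideImage(np.stack([vals] * 3, axis=-1))


class TestToGray:
    @pytest.mark.parametrize(
        "color, expected",
        [((255, 255, 255), 1.0), ((0, 0, 0), 0.0), ((255, 0, 0), 0.299)],
    )
    def test_luma_weights(self, flat_slide, color, expected):
        gray = to_gray(flat_slide(color))
        assert np.allclose(gray.pixels, expected, atol=1e-12)

    def test_range_and_shape(self, disk_slide):
        slide, _ = disk_slide
        gray = to_gray(slide)
        assert gray.pixels.shape == slide.pixels.shape[:2]
        assert gray.pixels.min() >= 0 and gray.pixels.max() <= 1


class TestAdaptiveGrayFilter:
    def test_bimodal_threshold_lies_between_modes(self):
        rng = np.random.default_rng(0)
        vals = np.where(rng.random((40, 40)) < 0.5, 0.3, 0.9)
        thr = adaptive_gray_filter(gray_from(vals), tissue=BinaryMask(np.ones((40, 40), bool)))
        assert 0.3 < thr < 0.9

    def test_candidate_mask_invariant_under_intensity_rescale(self):
        rng = np.random.default_rng(1)
        vals = np.where(rng.random((50, 50)) < 0.6, 0.35, 0.88)
        tissue = BinaryMask(np.ones((50, 50), bool))
        thr = adaptive_gray_filter(gray_from(vals), tissue=tissue)
        thr_scaled = adaptive_gray_filter(gray_from(vals * 0.9), tissue=tissue)
        assert np.array_equal(vals > thr, vals * 0.9 > thr_scaled)

    def test_constant_slide_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="contrast"):
            adaptive_gray_filter(
                gray_from(np.full((20, 20), 0.5)),
                tissue=BinaryMask(np.ones((20, 20), bool)),
            )

    def test_unimodal_slide_gets_bright_tail_threshold(self):
        # no fat: Otsu would split the stain mode in half; the fallback
        # quantile must keep almost all tissue below threshold
        rng = np.random.default_rng(2)
        vals = np.clip(rng.normal(0.6, 0.02, (80, 80)), 0, 1)
        thr = adaptive_gray_filter(gray_from(vals), tissue=BinaryMask(np.ones((80, 80), bool)))
        assert (vals > thr).mean() <= 0.2


class TestSegmentTissue:
    def test_full_coverage_slide_is_all_tissue(self):
        mask = segment_tissue(gray_from(np.full((30, 30), 0.4)))
        assert mask.pixels.all()

    def test_white_frame_dark_disk_matches_flood_fill_oracle(self, disk_slide):
        slide, _ = disk_slide
        gray = to_gray(slide)
        mask = segment_tissue(gray)
        oracle_bg = background_from_border(gray.pixels, QuantConfig().tissue_white_cutoff)
        assert np.array_equal(mask.pixels, ~oracle_bg)

    def test_enclosed_bright_hole_belongs_to_tissue(self):
        vals = np.full((40, 40), 0.4)
        vals[:3, :] = vals[-3:, :] = vals[:, :3] = vals[:, -3:] = 1.0  # frame
        vals[18:22, 18:22] = 1.0  # enclosed vacuole
        mask = segment_tissue(gray_from(vals))
        assert mask.pixels[19, 19]  # hole filled into tissue
        assert not mask.pixels[0, 0]

    def test_all_white_slide_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            segment_tissue(gray_from(np.ones((20, 20))))


class TestDetectCandidateRegions:
    def test_no_pixel_above_threshold_gives_empty_list(self):
        gray = gray_from(np.full((20, 20), 0.4))
        regions, labels = detect_candidate_regions(
            gray, BinaryMask(np.ones((20, 20), bool)), threshold=0.9
        )
        assert regions == [] and labels.max() == 0

    def test_single_disk_area_matches_brute_rasterization(self):
        h = w = 50
        yy, xx = np.mgrid[0:h, 0:w]
        disk = (yy - 25) ** 2 + (xx - 25) ** 2 <= 10**2
        vals = np.where(disk, 0.95, 0.4)
        regions, _ = detect_candidate_regions(
            gray_from(vals), BinaryMask(np.ones((h, w), bool)), threshold=0.7
        )
        assert len(regions) == 1
        assert regions[0].pixel_count == int(disk.sum())
        assert regions[0].perimeter == crack_perimeter_loop(disk)
        assert not regions[0].touches_border

    def test_two_disjoint_disks_give_two_regions(self):
        vals = np.full((40, 60), 0.4)
        vals[10:18, 10:18] = 0.95
        vals[25:33, 40:48] = 0.95
        regions, _ = detect_candidate_regions(
            gray_from(vals), BinaryMask(np.ones((40, 60), bool)), threshold=0.7
        )
        assert len(regions) == 2

    def test_diagonal_touch_is_one_region(self):
        vals = np.full((10, 10), 0.2)
        vals[2, 2] = vals[3, 3] = 0.95  # 8-connectivity joins diagonals
        regions, _ = detect_candidate_regions(
            gray_from(vals), BinaryMask(np.ones((10, 10), bool)), threshold=0.5
        )
        assert len(regions) == 1 and regions[0].pixel_count == 2


def make_region(**kw) -> Region:
    base = dict(
        label=1,
        pixel_count=100,
        perimeter=40.0,
        circularity=0.785,
        solidity=0.95,
        mean_intensity=0.95,
        touches_border=False,
    )
    base.update(kw)
    return Region(**base)


class TestFilterRegions:
    def test_compact_circular_region_is_fat(self):
        out = filter_regions([make_region(circularity=0.95)])
        assert out[0].classification == "fat"

    def test_elongated_strip_excluded_by_shape(self):
        # 3x60 strip: circularity from brute-force perimeter/area
        strip = np.ones((3, 60), dtype=bool)
        area = strip.sum()
        per = crack_perimeter_loop(strip)
        circ = 4 * np.pi * area / per**2
        assert circ < 0.4  # sanity: the default cutoff separates it
        out = filter_regions([make_region(pixel_count=int(area), circularity=circ)])
        assert out[0].classification == "excluded_shape"

    def test_area_one_above_max_is_excluded_large(self):
        cfg = QuantConfig()
        out = filter_regions([make_region(pixel_count=cfg.max_vacuole_px + 1)], cfg)
        assert out[0].classification == "excluded_large"
        out = filter_regions([make_region(pixel_count=cfg.max_vacuole_px)], cfg)
        assert out[0].classification == "fat"

    def test_noise_regions_dropped_entirely(self):
        cfg = QuantConfig()
        assert filter_regions([make_region(pixel_count=cfg.min_vacuole_px - 1)], cfg) == []

    def test_exclusion_precedence_large_beats_shape_beats_border(self):
        cfg = QuantConfig()
        both = make_region(
            pixel_count=cfg.max_vacuole_px + 1, circularity=0.1, touches_border=True
        )
        assert filter_regions([both], cfg)[0].classification == "excluded_large"
        shape_and_border = make_region(circularity=0.1, touches_border=True)
        assert filter_regions([shape_and_border], cfg)[0].classification == "excluded_shape"

    def test_border_exclusion_respects_flag(self):
        touching = make_region(touches_border=True)
        assert filter_regions([touching])[0].classification == "excluded_border"
        cfg = dataclasses.replace(QuantConfig(), exclude_border_regions=False)
        assert filter_regions([touching], cfg)[0].classification == "fat"

    def test_low_solidity_excluded(self):
        out = filter_regions([make_region(solidity=0.5)])
        assert out[0].classification == "excluded_shape"


class TestComputeSteatosis:
    def test_no_fat_regions_gives_zero(self):
        res = compute_steatosis([], BinaryMask(np.ones((100, 100), bool)))
        assert res.steatosis_pct == 0.0 and res.tissue_area_px == 10_000

    def test_arithmetic_by_definition(self):
        regions = [make_region(pixel_count=2500)]
        res = compute_steatosis(regions, BinaryMask(np.ones((100, 100), bool)))
        assert res.steatosis_pct == 25.0
        assert res.fat_area_px == 2500 and res.n_fat_regions == 1

    def test_excluded_regions_counted_but_not_summed(self):
        regions = [
            make_region(pixel_count=2500),
            make_region(label=2, pixel_count=3000, classification="excluded_large"),
        ]
        res = compute_steatosis(regions, BinaryMask(np.ones((100, 100), bool)))
        assert res.fat_area_px == 2500 and res.n_excluded_regions == 1

    def test_zero_tissue_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_steatosis([], BinaryMask(np.zeros((5, 5), bool)))


class TestQuantifySlide:
    def test_deterministic_bit_identical(self):
        slide = generate_slide(SlideSpec(height=128, width=128, target_fat_fraction=0.2, seed=5))
        a = quantify_slide(slide.image)
        b = quantify_slide(slide.image)
        assert a == b

    def test_zero_vacuole_slide_reads_near_zero(self):
        slide = generate_slide(SlideSpec(height=256, width=256, target_fat_fraction=0.0, seed=5))
        res = quantify_slide(slide.image)
        assert res.steatosis_pct < 1.0

    def test_recovers_ground_truth_fraction(self):
        slide = generate_slide(SlideSpec(target_fat_fraction=0.30, seed=7))
        res = quantify_slide(slide.image)
        assert abs(res.steatosis_pct - 100 * slide.achieved_fat_fraction) <= 3.0

    def test_vessel_filtering_reduces_estimate(self):
        slide = generate_slide(
            SlideSpec(target_fat_fraction=0.2, n_vessels=2, vessel_scale=100, seed=3)
        )
        filtered = quantify_slide(slide.image)
        naive = quantify_slide(slide.image, apply_filters=False)
        assert filtered.steatosis_pct < naive.steatosis_pct

    def test_monotone_in_added_fat_region(self):
        spec = SlideSpec(height=256, width=256, target_fat_fraction=0.1, seed=9)
        slide = generate_slide(spec)
        base = quantify_slide(slide.image)
        # paint one extra vacuole into a clear patch of tissue
        from scipy import ndimage as ndi

        free = slide.tissue_truth.pixels & ~slide.fat_truth.pixels
        free[:20, :] = free[-20:, :] = free[:, :20] = free[:, -20:] = False
        clearance = ndi.distance_transform_edt(free)
        cy, cx = np.unravel_index(np.argmax(clearance), clearance.shape)
        assert clearance[cy, cx] > 12
        px = slide.image.pixels.copy()
        yy, xx = np.mgrid[0:256, 0:256]
        extra = (yy - cy) ** 2 + (xx - cx) ** 2 <= 8**2
        assert not (slide.fat_truth.pixels & extra).any()
        px[extra] = (246, 246, 248)
        more = quantify_slide(SlideImage(px))
        assert more.steatosis_pct > base.steatosis_pct

    def test_fat_within_candidates_within_tissue(self):
        slide = generate_slide(SlideSpec(height=256, width=256, target_fat_fraction=0.25, seed=2))
        gray = to_gray(slide.image)
        cfg = QuantConfig()
        tissue = segment_tissue(gray, cfg)
        thr = adaptive_gray_filter(gray, cfg, tissue=tissue)
        regions, labels = detect_candidate_regions(gray, tissue, thr, cfg)
        classified = filter_regions(regions, cfg)
        fat_labels = [r.label for r in classified if r.classification == "fat"]
        fat_mask = np.isin(labels, fat_labels)
        candidate_mask = labels > 0
        assert not (fat_mask & ~candidate_mask).any()
        assert not (candidate_mask & ~tissue.pixels).any()
        res = compute_steatosis(classified, tissue, cfg)
        assert 0.0 <= res.steatosis_pct <= 100.0


class TestQuantConfig:
    def test_unknown_json_keys_rejected(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text('{"bright_quantile": 0.8, "bogus": 1}')
        with pytest.raises(ValueError, match="bogus"):
            QuantConfig.from_json(p)

    def test_json_round_trip(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text('{"bright_quantile": 0.8, "min_vacuole_px": 10}')
        cfg = QuantConfig.from_json(p)
        assert cfg.bright_quantile == 0.8 and cfg.min_vacuole_px == 10

    @pytest.mark.parametrize(
        "kw",
        [
            {"bright_quantile": 1.5},
            {"min_vacuole_px": 0},
            {"min_vacuole_px": 100, "max_vacuole_px": 50},
            {"tissue_white_cutoff": 1.2},
        ],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            QuantConfig(**kw)
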