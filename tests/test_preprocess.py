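"""Color normalization, stain segmentation, candidate extraction and
tissue measurement."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from plaquescope.preprocess import (CandidateObject, ColorStats, PreprocessConfig,
                                    color_stats, crop_candidate, extract_candidates,
                                    normalize_transfer_array, refine_mask,
                                    reinhard_normalize, stain_mask, tile_slide,
                                    tissue_area, to_transfer_space)
from plaquescope.synthetic import SlideImage


def slide_of(pixels, mpp=0.5):
    return SlideImage(np.asarray(pixels, dtype=np.uint8), mpp, "test")


@pytest.fixture()
def random_slide(rng):
    return slide_of(rng.integers(0, 256, (64, 64, 3)))


class TestColorStats:
    def test_constant_image_has_zero_std(self):
        s = color_stats(slide_of(np.full((16, 16, 3), 128)))
        assert np.allclose(s.std, 0.0, atol=1e-12)

    def test_row_permutation_invariance(self, random_slide, rng):
        s1 = color_stats(random_slide)
        perm = rng.permutation(64)
        s2 = color_stats(slide_of(random_slide.pixels[perm]))
        assert np.allclose(s1.mean, s2.mean) and np.allclose(s1.std, s2.std)

    def test_matches_per_pixel_recomputation(self, random_slide):
        s = color_stats(random_slide)
        lab = to_transfer_space(random_slide.pixels)
        flat = lab.reshape(-1, 3)
        mean = flat.sum(axis=0) / len(flat)
        var = ((flat - mean) ** 2).sum(axis=0) / len(flat)
        assert np.allclose(s.mean, mean, atol=1e-9)
        assert np.allclose(s.std, np.sqrt(var), atol=1e-9)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            color_stats(slide_of(np.empty((0, 0, 3))))


class TestReinhard:
    def test_self_normalization_is_identity_within_quantization(self, random_slide):
        out = reinhard_normalize(random_slide, color_stats(random_slide))
        diff = out.pixels.astype(int) - random_slide.pixels.astype(int)
        assert np.abs(diff).max() <= 1

    def test_constant_image_maps_to_reference_mean_color(self):
        const = slide_of(np.full((8, 8, 3), 90))
        ref_img = slide_of(np.full((8, 8, 3), (180, 40, 220)))
        out = reinhard_normalize(const, color_stats(ref_img))
        expected = ref_img.pixels[0, 0]
        assert np.abs(out.pixels.astype(int) - expected.astype(int)).max() <= 1

    def test_transfer_space_moments_match_reference(self, random_slide, rng):
        reference = ColorStats((0.1, -0.02, 0.03), (0.4, 0.05, 0.02))
        lab = to_transfer_space(random_slide.pixels)
        lab2 = normalize_transfer_array(lab, color_stats(random_slide), reference)
        flat = lab2.reshape(-1, 3)
        assert np.allclose(flat.mean(axis=0), reference.mean, atol=1e-6)
        assert np.allclose(flat.std(axis=0), reference.std, atol=1e-6)

    def test_idempotent_within_quantization(self, random_slide, rng):
        # realistic in-gamut reference: stats of another image
        other = slide_of(np.random.default_rng(5).integers(30, 220, (64, 64, 3)))
        reference = color_stats(other)
        once = reinhard_normalize(random_slide, reference)
        twice = reinhard_normalize(once, reference)
        diff = twice.pixels.astype(int) - once.pixels.astype(int)
        assert np.abs(diff).max() <= 1

    def test_cielab_backend(self, random_slide):
        ref = color_stats(random_slide, "cielab")
        out = reinhard_normalize(random_slide, ref)
        assert np.abs(out.pixels.astype(int) - random_slide.pixels.astype(int)).max() <= 1


class TestTileSlide:
    @pytest.mark.parametrize("shape,tile,expected", [
        ((7680, 7680), 1536, 25),
        ((1536, 1536), 1536, 1),
        ((2000, 1700), 1536, 1),
        ((1000, 3000), 1536, 0),
    ])
    def test_grid_counts(self, shape, tile, expected):
        img = slide_of(np.zeros(shape + (3,)))
        tiles = tile_slide(img, tile)
        assert len(tiles) == expected

    def test_single_tile_origin_and_disjointness(self, rng):
        img = slide_of(rng.integers(0, 255, (3100, 1600, 3)))
        tiles = tile_slide(img, 1536)
        assert [(y, x) for y, x, _ in tiles] == [(0, 0), (1536, 0)]
        for y, x, t in tiles:
            assert t.shape == (1536, 1536, 3)
            assert np.array_equal(t, img.pixels[y:y + 1536, x:x + 1536])


class TestStainMask:
    def test_white_image_empty_mask(self):
        assert not stain_mask(slide_of(np.full((32, 32, 3), 255))).any()

    def test_brown_disk_recovered_exactly(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        rr, cc = draw_disk((32, 32), 15)
        img[rr, cc] = (140, 90, 40)  # brown: hue ~25 deg, high sat, mid value
        mask = stain_mask(slide_of(img))
        expected = np.zeros((64, 64), dtype=bool)
        expected[rr, cc] = True
        assert (mask ^ expected).sum() == 0

    def test_out_of_band_noise_ignored(self, rng):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        rr, cc = draw_disk((20, 20), 10)
        img[rr, cc] = (140, 90, 40)
        base = stain_mask(slide_of(img))
        noisy = img.copy()
        region = np.zeros((64, 64), dtype=bool)
        region[40:, 40:] = True  # pure green-channel noise away from the disk
        noisy[region, 1] = rng.integers(200, 255, int(region.sum()))
        assert np.array_equal(stain_mask(slide_of(noisy)), base)

    def test_wraparound_hue_band(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[:] = (200, 40, 60)  # hue ~ 353 deg
        cfg = PreprocessConfig(hsv_low=(350 / 360, 0.2, 0.1), hsv_high=(10 / 360, 1.0, 0.9))
        assert stain_mask(slide_of(img), cfg).all()


class TestRefineMask:
    def test_empty_stays_empty(self):
        assert not refine_mask(np.zeros((32, 32), dtype=bool), 2).any()

    def test_isolated_speckle_removed(self):
        m = np.zeros((32, 32), dtype=bool)
        m[10, 10] = True
        assert not refine_mask(m, 2).any()

    def test_interior_hole_closed(self):
        m = np.zeros((120, 120), dtype=bool)
        m[10:110, 10:110] = True
        m[50, 50] = False
        out = refine_mask(m, 2)
        from skimage.morphology import disk, opening, closing
        expected = closing(opening(m, disk(2)), disk(2)).astype(bool)
        assert out[50, 50]
        assert np.array_equal(out, expected)

    def test_radius_zero_is_identity(self, rng):
        m = rng.random((20, 20)) > 0.5
        assert np.array_equal(refine_mask(m, 0), m)


from oracles import flood_fill_components


class TestExtractCandidates:
    def test_three_disks_found(self):
        m = np.zeros((300, 300), dtype=bool)
        for c in [(60, 60), (60, 220), (220, 140)]:
            rr, cc = draw_disk(c, 40)
            m[rr, cc] = True
        cands = extract_candidates(m)
        assert len(cands) == 3
        assert all(c.stained_area_px >= 1500 for c in cands)

    def test_small_disk_below_area_floor(self):
        m = np.zeros((100, 100), dtype=bool)
        rr, cc = draw_disk((50, 50), 21)  # ~1385 px < 1500
        m[rr, cc] = True
        assert extract_candidates(m) == []

    def test_empty_mask(self):
        assert extract_candidates(np.zeros((10, 10), dtype=bool)) == []

    def test_matches_flood_fill_oracle_on_small_masks(self, rng):
        cfg = PreprocessConfig(min_stain_area_px=5)
        for trial in range(10):
            m = rng.random((48, 48)) > 0.72
            cands = extract_candidates(m, cfg)
            comps = [c for c in flood_fill_components(m, 8) if len(c) >= 5]
            assert len(cands) == len(comps)
            got = sorted((c.stained_area_px for c in cands))
            assert got == sorted(len(c) for c in comps)

    def test_four_connectivity(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2, 2] = m[3, 3] = True  # diagonal touch
        cfg = PreprocessConfig(min_stain_area_px=1, connectivity=4)
        assert len(extract_candidates(m, cfg)) == 2
        cfg8 = PreprocessConfig(min_stain_area_px=1, connectivity=8)
        assert len(extract_candidates(m, cfg8)) == 1

    def test_sorted_by_centroid(self, rng):
        m = np.zeros((200, 400), dtype=bool)
        for c in [(100, 300), (100, 60), (30, 180)]:
            rr, cc = draw_disk(c, 25)
            m[rr, cc] = True
        cands = extract_candidates(m, PreprocessConfig(min_stain_area_px=100))
        cents = [c.centroid for c in cands]
        assert cents == sorted(cents)


class TestCropCandidate:
    def cand(self, cy, cx):
        return CandidateObject("s", (cy, cx), (cy - 1, cx - 1, cy + 1, cx + 1), 9)

    def test_interior_centroid_slices_image(self, rng):
        img = slide_of(rng.integers(0, 255, (400, 400, 3)))
        tile = crop_candidate(img, self.cand(128, 128), 256)
        assert np.array_equal(tile, img.pixels[0:256, 0:256])

    def test_corner_centroid_white_padded_and_centered(self, rng):
        img = slide_of(rng.integers(0, 254, (300, 300, 3)))
        img.pixels[10, 10] = (1, 2, 3)  # marker at the centroid
        tile = crop_candidate(img, self.cand(10, 10), 256)
        assert tile.shape == (256, 256, 3)
        assert tuple(tile[128, 128]) == (1, 2, 3)  # centroid lands at tile center
        assert (tile[:100, :100] == 255).all()  # off-slide area is white

    def test_output_shape_always_square(self, rng):
        img = slide_of(rng.integers(0, 255, (270, 270, 3)))
        for cy, cx in [(0, 0), (269, 269), (135, 10)]:
            assert crop_candidate(img, self.cand(cy, cx), 256).shape == (256, 256, 3)

    def test_outside_centroid_rejected(self, rng):
        img = slide_of(rng.integers(0, 255, (64, 64, 3)))
        with pytest.raises(ValueError):
            crop_candidate(img, self.cand(70, 10), 32)


class TestTissueArea:
    def test_all_white_slide_zero(self):
        assert tissue_area(slide_of(np.full((128, 128, 3), 250))) == (0, 0.0)

    def test_square_millimetre_conversion(self):
        img = np.full((1100, 1100, 3), 250, dtype=np.uint8)
        img[50:1050, 50:1050] = (241, 216, 226)  # 1000 x 1000 px tissue
        area_px, area_mm2 = tissue_area(slide_of(img, mpp=0.5))
        assert area_mm2 == pytest.approx(0.25, rel=1e-3)

    def test_adding_tissue_never_decreases_area(self):
        img = np.full((256, 256, 3), 250, dtype=np.uint8)
        img[50:150, 50:150] = (241, 216, 226)
        a1, _ = tissue_area(slide_of(img))
        img[150:220, 50:150] = (241, 216, 226)
        a2, _ = tissue_area(slide_of(img))
        assert a2 >= a1

    def test_bleaching_tissue_reduces_area(self):
        img = np.full((256, 256, 3), 250, dtype=np.uint8)
        img[40:200, 40:200] = (241, 216, 226)
        a1, _ = tissue_area(slide_of(img))
        img[100:200, 40:200] = 250
        a2, _ = tissue_area(slide_of(img))
        assert a2 <= a1

    def test_bad_mpp_rejected(self):
        with pytest.raises(ValueError):
            tissue_area(slide_of(np.full((64, 64, 3), 250), mpp=-1))
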