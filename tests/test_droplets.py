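"""Droplet segmentation and quantification against simulator ground truth."""

import numpy as np
import pytest

from staz import (
    ChannelImage,
    LarvaSimParams,
    LiverMask,
    SegmentationConfig,
    quantify,
    segment_droplets,
    simulate_larva,
)
from staz.droplets import Droplet
from staz.errors import ConfigurationError, ConsistencyError


def _disk_image(shape, centers, radius, level, background):
    img = np.full(shape, background, dtype=float)
    rr, cc = np.meshgrid(
        np.arange(shape[0]) + 0.5, np.arange(shape[1]) + 0.5, indexing="ij"
    )
    for y, x in centers:
        img[(rr - y) ** 2 + (cc - x) ** 2 <= radius**2] += level
    return img


class TestSegmentation:
    def test_uniform_image_yields_no_droplets(self, square_mask):
        green = ChannelImage(np.full((32, 32), 7.0), "lipid_green")
        with pytest.warns(UserWarning, match="constant"):
            assert segment_droplets(green, square_mask) == []

    def test_recovers_ten_disks(self):
        """10 well-separated radius-3 disks at SNR >> 10 are each found
        with area within 20% of pi * 3^2."""
        mask = LiverMask(np.ones((64, 64), dtype=bool))
        centers = [
            (8, 8), (8, 24), (8, 40), (8, 56), (28, 8),
            (28, 28), (28, 48), (48, 8), (48, 28), (48, 48),
        ]
        img = _disk_image((64, 64), centers, 3.0, 120.0, 10.0)
        img += np.random.default_rng(0).normal(0, 2.0, img.shape)
        green = ChannelImage(np.clip(img, 0, None), "lipid_green")
        droplets = segment_droplets(green, mask)
        assert len(droplets) == 10
        for d in droplets:
            assert abs(d.area_px - np.pi * 9) <= 0.2 * np.pi * 9

    def test_min_area_filter_drops_speck(self):
        mask = LiverMask(np.ones((64, 64), dtype=bool))
        centers = [(10, 10), (10, 30), (10, 50), (30, 10), (30, 30),
                   (30, 50), (50, 10), (50, 30), (50, 50), (18, 40)]
        img = _disk_image((64, 64), centers, 3.0, 120.0, 10.0)
        img[55, 55] += 120.0  # 1-px speck
        green = ChannelImage(img, "lipid_green")
        cfg = SegmentationConfig(smoothing_radius_px=0, min_area_px=4)
        droplets = segment_droplets(green, mask, cfg)
        assert len(droplets) == 10
        cfg1 = SegmentationConfig(smoothing_radius_px=0, min_area_px=1)
        assert len(segment_droplets(green, mask, cfg1)) == 11

    def test_wrong_role_rejected(self, square_mask):
        blue = ChannelImage(np.ones((32, 32)), "norm_blue")
        with pytest.raises(ConfigurationError):
            segment_droplets(blue, square_mask)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 8.0])
    def test_otsu_scale_invariance(self, scale, rng, square_mask):
        """Otsu-mode segmentation is unchanged when intensities are scaled
        by a positive constant (power of two: exact in float)."""
        img = _disk_image((32, 32), [(16, 16), (12, 22)], 2.5, 80.0, 5.0)
        img += rng.normal(0, 1.0, img.shape)
        img = np.clip(img, 0, None)
        a = segment_droplets(ChannelImage(img, "lipid_green"), square_mask)
        b = segment_droplets(ChannelImage(img * scale, "lipid_green"), square_mask)
        assert len(a) == len(b)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.pixel_set, db.pixel_set)

    def test_all_pixels_inside_mask(self):
        """Components are clipped to the liver even when bright signal
        extends beyond it."""
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        img = _disk_image((32, 32), [(8, 8)], 4.0, 100.0, 5.0)  # straddles corner
        droplets = segment_droplets(
            ChannelImage(img, "lipid_green"),
            LiverMask(mask),
            SegmentationConfig(smoothing_radius_px=0),
        )
        for d in droplets:
            assert mask[d.pixel_set[:, 0], d.pixel_set[:, 1]].all()

    def test_watershed_splits_touching_pair(self):
        mask = LiverMask(np.ones((40, 40), dtype=bool))
        img = _disk_image((40, 40), [(20, 14), (20, 21)], 4.0, 100.0, 5.0)
        green = ChannelImage(img, "lipid_green")
        merged = segment_droplets(
            green, mask, SegmentationConfig(smoothing_radius_px=0)
        )
        split = segment_droplets(
            green,
            mask,
            SegmentationConfig(smoothing_radius_px=0, split_touching=True),
        )
        assert len(merged) == 1
        assert len(split) == 2

    def test_fixed_threshold(self, square_mask):
        img = np.full((32, 32), 10.0)
        img[12:16, 12:16] = 50.0
        cfg = SegmentationConfig(
            smoothing_radius_px=0, threshold_method="fixed", fixed_threshold=30.0
        )
        droplets = segment_droplets(ChannelImage(img, "lipid_green"), square_mask, cfg)
        assert len(droplets) == 1 and droplets[0].area_px == 16

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SegmentationConfig(threshold_method="fixed")
        with pytest.raises(ConfigurationError):
            SegmentationConfig(min_area_px=0)


class TestQuantify:
    def test_empty_droplet_list(self, square_mask):
        q = quantify([], square_mask)
        assert q.n_droplets == 0 and q.ld_dens == 0.0 and q.ld_area == 0.0

    def test_hand_arithmetic(self):
        mask = LiverMask(np.ones((100, 100), dtype=bool))
        droplets = []
        for i in range(5):
            coords = np.array(
                [(r, c) for r in range(i * 10, i * 10 + 10) for c in range(10)]
            )
            droplets.append(Droplet(coords, 100, (0.0, 0.0), 0.0))
        q = quantify(droplets, mask)
        assert q.ld_dens == pytest.approx(5e-4, abs=0)
        assert q.ld_area == pytest.approx(0.05, abs=0)

    def test_droplet_filling_liver(self, square_mask):
        coords = np.argwhere(square_mask.mask)
        d = Droplet(coords, len(coords), (15.5, 15.5), 0.0)
        assert quantify([d], square_mask).ld_area == 1.0

    def test_pixel_outside_mask_rejected(self, square_mask):
        d = Droplet(np.array([[0, 0], [0, 1], [1, 0], [1, 1]]), 4, (0.5, 0.5), 2.0)
        with pytest.raises(ConsistencyError):
            quantify([d], square_mask)

    def test_ld_area_equals_brute_force_pixel_count(self, rng):
        """ld_area equals an independent per-pixel loop: count in-mask
        pixels above threshold surviving the size filter / liver area."""
        mask_arr = np.zeros((48, 48), dtype=bool)
        mask_arr[6:42, 6:42] = True
        mask = LiverMask(mask_arr)
        img = _disk_image((48, 48), [(15, 15), (30, 30), (15, 33)], 3.0, 90.0, 8.0)
        img += rng.normal(0, 1.5, img.shape)
        img = np.clip(img, 0, None)
        green = ChannelImage(img, "lipid_green")
        cfg = SegmentationConfig(smoothing_radius_px=0, min_area_px=4)
        q = quantify(segment_droplets(green, mask, cfg), mask)

        from skimage.filters import threshold_otsu

        thr = threshold_otsu(img[mask_arr])
        fg = np.zeros_like(mask_arr)
        for r in range(48):
            for c in range(48):
                fg[r, c] = mask_arr[r, c] and img[r, c] > thr
        # 8-connected components by brute-force flood fill, drop area < 4
        seen = np.zeros_like(fg)
        kept = 0
        for r in range(48):
            for c in range(48):
                if fg[r, c] and not seen[r, c]:
                    stack, comp = [(r, c)], []
                    seen[r, c] = True
                    while stack:
                        y, x = stack.pop()
                        comp.append((y, x))
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                yy, xx = y + dy, x + dx
                                if (
                                    0 <= yy < 48
                                    and 0 <= xx < 48
                                    and fg[yy, xx]
                                    and not seen[yy, xx]
                                ):
                                    seen[yy, xx] = True
                                    stack.append((yy, xx))
                    if len(comp) >= 4:
                        kept += len(comp)
        assert q.ld_area == pytest.approx(kept / mask.area_px, abs=1e-12)


class TestSimulatorRecovery:
    def test_count_recovery_on_simulated_slices(self):
        """On non-overlapping radius >= 2 droplets at SNR >= 10, counts
        match generative truth (spot check; the full 100-seed sweep runs
        in the acceptance suite)."""
        hits = total = 0
        for seed in range(10):
            params = LarvaSimParams(
                seed=seed,
                droplet_rate=5e-3,
                droplet_radius_px=(2.5, 0.4),
                droplet_radius_min=2.0,
                n_slices=1,
            )
            rec, truth = simulate_larva(params)
            sl = rec.slices[0]
            found = segment_droplets(sl.channel("lipid_green"), sl.mask)
            hits += len(found) == truth.slices[0].n_droplets
            total += 1
        assert hits == total
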