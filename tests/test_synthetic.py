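"""Generator geometry, determinism, and the simulated experimental regimes."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage
from skimage import measure

from rrseg.synthetic import (PlacementError, SynthConfig, generate_dataset,
                             generate_sample, generate_time_course,
                             render_ring, render_rod,
                             simulate_microscope_shift)


def capsule_area(length_px, width_px):
    return length_px * width_px + np.pi * (width_px / 2) ** 2


def annulus_area(outer_px, thickness_px):
    return np.pi * (outer_px**2 - (outer_px - thickness_px) ** 2)


class TestRenderRod:
    def test_pixel_count_matches_capsule_area(self):
        # shaft 20 px, width 4 px at unit pixel size; generic (non-integer)
        # centre as drawn by the generator, avoiding row-quantisation bias
        mask = render_rod((32.5, 32.5), 0.0, 20.0, 4.0, 1.0, (64, 64))
        expected = capsule_area(20, 4)  # 80 + 4*pi ~ 92.6
        assert abs(mask.sum() - expected) / expected < 0.10

    @pytest.mark.parametrize("radius_px,tol", [(8, 0.10), (16, 0.05)])
    def test_area_convergence_with_size(self, radius_px, tol):
        width = 2 * radius_px
        length = 3 * width
        mask = render_rod((128, 128), 0.3, length, width, 1.0, (256, 256))
        expected = capsule_area(length, width)
        assert abs(mask.sum() - expected) / expected < tol

    def test_single_connected_component(self):
        for angle in (0.0, 0.5, 1.2):
            mask = render_rod((32, 32), angle, 15.0, 2.0, 1.0, (64, 64))
            assert measure.label(mask, connectivity=2).max() == 1

    def test_deterministic(self):
        a = render_rod((20, 30), 0.7, 10.0, 3.0, 1.0, (64, 64))
        b = render_rod((20, 30), 0.7, 10.0, 3.0, 1.0, (64, 64))
        np.testing.assert_array_equal(a, b)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            render_rod((10, 10), 0.0, 2.0, 3.0, 1.0, (32, 32))

    def test_off_grid_placement_rejected(self):
        with pytest.raises(PlacementError):
            render_rod((-50, -50), 0.0, 5.0, 2.0, 1.0, (32, 32))


class TestRenderRing:
    def test_pixel_count_matches_annulus_area(self):
        mask = render_ring((32, 32), 10.0, 3.0, 1.0, (64, 64))
        expected = annulus_area(10, 3)  # pi(100-49) ~ 160.2
        assert abs(mask.sum() - expected) / expected < 0.10

    def test_area_convergence_at_large_radius(self):
        mask = render_ring((64, 64), 16.0, 5.0, 1.0, (128, 128))
        expected = annulus_area(16, 5)
        assert abs(mask.sum() - expected) / expected < 0.05

    def test_thickness_must_be_strictly_below_radius(self):
        with pytest.raises(ValueError):
            render_ring((16, 16), 5.0, 5.0, 1.0, (32, 32))

    @pytest.mark.parametrize("radius_px", [6, 8, 12])
    def test_exactly_one_hole(self, radius_px):
        mask = render_ring((32, 32), float(radius_px), 2.0, 1.0, (64, 64))
        # Euler characteristic 0 <=> one component with one hole
        assert measure.euler_number(mask, connectivity=2) == 0
        assert measure.label(mask, connectivity=2).max() == 1


class TestGenerateSample:
    def test_no_objects_no_noise_gives_flat_background(self):
        cfg = SynthConfig(n_rods=(0, 0), n_rings=(0, 0), noise_sd=0.0,
                          background_level=15.0, seed=3)
        img, masks, truth = generate_sample(cfg, 0)
        assert np.allclose(img.pixels, 15.0)
        assert not masks.rod.any() and not masks.ring.any()
        assert truth.n_rods == truth.n_rings == 0

    def test_bit_identical_for_same_seed_and_index(self, small_config):
        a_img, a_masks, _ = generate_sample(small_config, 5)
        b_img, b_masks, _ = generate_sample(small_config, 5)
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        np.testing.assert_array_equal(a_masks.rod, b_masks.rod)
        np.testing.assert_array_equal(a_masks.ring, b_masks.ring)

    def test_requested_ring_count_equals_components(self):
        cfg = SynthConfig(n_rods=(0, 0), n_rings=(5, 5), seed=11)
        _, masks, truth = generate_sample(cfg, 0)
        assert truth.n_rings == 5
        assert measure.label(masks.ring, connectivity=2).max() == 5

    def test_component_counts_match_ground_truth(self, small_config):
        for idx in range(5):
            _, masks, truth = generate_sample(small_config, idx)
            assert measure.label(masks.rod, connectivity=2).max() == truth.n_rods
            assert measure.label(masks.ring, connectivity=2).max() == truth.n_rings

    def test_classes_are_disjoint_without_overlap(self, small_config):
        for idx in range(5):
            _, masks, _ = generate_sample(small_config, idx)
            assert not (masks.rod & masks.ring).any()

    def test_impossible_density_raises_placement_error(self):
        cfg = SynthConfig(image_size_px=64, n_rods=(150, 150), seed=0)
        with pytest.raises(PlacementError, match="density"):
            generate_sample(cfg, 0)


class TestGenerateDataset:
    def test_distinct_ids(self, small_config):
        data = generate_dataset(small_config, 3)
        ids = [img.id for img, _, _ in data]
        assert len(set(ids)) == 3

    def test_repeated_calls_identical(self, small_config):
        a = generate_dataset(small_config, 3)
        b = generate_dataset(small_config, 3)
        for (ia, _, _), (ib, _, _) in zip(a, b):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)

    def test_invalid_size_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_dataset(small_config, 0)

    def test_full_training_corpus_scale(self):
        # parity with the full-scale training corpus size of 287 images
        cfg = SynthConfig(image_size_px=64, n_rods=(1, 3), n_rings=(1, 3),
                          blur_sigma_px=0.0, seed=5)
        data = generate_dataset(cfg, 287)
        assert len(data) == 287
        assert len({img.id for img, _, _ in data}) == 287


class TestTimeCourse:
    def test_count_ranges_scale_with_multiplier(self):
        cfg = SynthConfig(n_rods=(0, 0), n_rings=(8, 8), noise_sd=0.0, seed=2)
        tc = generate_time_course(cfg, [1.0, 0.5, 0.0], n_images=2)
        counts = [[t.n_rings for _, _, t in ds] for ds in tc]
        assert all(c == 8 for c in counts[0])
        assert all(c == 4 for c in counts[1])
        assert all(c == 0 for c in counts[2])

    def test_zero_multiplier_yields_empty_masks(self, small_config):
        (ds,) = generate_time_course(small_config, [0.0], n_images=3)
        for _, masks, _ in ds:
            assert not masks.rod.any() and not masks.ring.any()

    def test_unit_multiplier_reproduces_generate_dataset(self, small_config):
        (ds,) = generate_time_course(small_config, [1.0], n_images=2)
        ref = generate_dataset(small_config, 2)
        for (a, _, _), (b, _, _) in zip(ds, ref):
            np.testing.assert_array_equal(a.pixels, b.pixels)


class TestMicroscopeShift:
    def _one_ring_sample(self, size=128, radius_um=1.2):
        cfg = SynthConfig(image_size_px=size, n_rods=(0, 0), n_rings=(1, 1),
                          ring_outer_radius_um=(radius_um, radius_um),
                          ring_thickness_um=(0.4, 0.4), noise_sd=0.0, seed=9)
        return cfg, *generate_sample(cfg, 0)

    @staticmethod
    def _extent_px(mask):
        rows = np.where(mask.any(axis=1))[0]
        return rows[-1] - rows[0] + 1

    def test_same_pixel_size_is_identity_up_to_grid(self):
        cfg, img, masks, _ = self._one_ring_sample()
        new_img, new_masks = simulate_microscope_shift(
            img, masks, cfg.pixel_size_um, cfg.image_size_px)
        assert abs(int(new_masks.ring.sum()) - int(masks.ring.sum())) <= \
            0.05 * masks.ring.sum() + 2

    def test_halving_pixel_size_doubles_diameter(self):
        cfg, img, masks, _ = self._one_ring_sample()
        new_img, new_masks = simulate_microscope_shift(
            img, masks, cfg.pixel_size_um / 2, cfg.image_size_px * 2)
        before = self._extent_px(masks.ring)
        after = self._extent_px(new_masks.ring)
        assert abs(after - 2 * before) <= 2

    def test_mask_area_scales_quadratically(self):
        cfg, img, masks, _ = self._one_ring_sample(radius_um=1.6)
        new_img, new_masks = simulate_microscope_shift(
            img, masks, cfg.pixel_size_um / 2, cfg.image_size_px * 2)
        ratio = new_masks.ring.sum() / masks.ring.sum()
        assert abs(ratio - 4.0) / 4.0 < 0.10
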