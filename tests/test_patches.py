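"""Patch selection and categorization rules, against an independent oracle."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from medmat.errors import ConfigurationError
from medmat.patches import (BrightnessConstraints, CategoryConfig, SourceImage,
                            average_brightness, categorize_region, generate_patches,
                            mask_fraction, normalize_image, split_dataset)
from medmat.synthetic import Layout, Region, TextureSpec, generate_scene

from conftest import brute_force_patches

CATS = CategoryConfig(names=("background", "tissue", "lesion"),
                      null="background", expert="lesion")
CONS = BrightnessConstraints(b_min=0.1, b_max=0.95, b_null=0.05, mask_tolerance=0.05)


def scene_to_source(scene, image_id="img", naive="tissue"):
    return SourceImage(pixels=scene.image, mask=scene.mask,
                       image_id=image_id, naive_category=naive)


class TestNormalize:
    def test_full_range_eight_bit(self):
        out = normalize_image(np.array([[0, 128, 255]]))
        np.testing.assert_allclose(out.pixels, [[0.0, 128 / 255, 1.0]])

    def test_negative_inverts_after_scaling(self):
        out = normalize_image(np.array([[0, 255]]), is_negative=True)
        np.testing.assert_allclose(out.pixels, [[1.0, 0.0]])

    def test_constant_image_warns_and_zeroes(self, caplog):
        with caplog.at_level(logging.WARNING, logger="medmat.patches"):
            out = normalize_image(np.full((4, 4), 17))
        assert (out.pixels == 0).all()
        assert "constant" in caplog.text

    def test_empty_image_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_image(np.empty((0, 3)))


class TestElementaryStats:
    @pytest.mark.parametrize("region, expected", [
        (np.full((3, 3), 0.5), 0.5),
        (np.array([[0, 0.2], [0.4, 1.0]]), 0.4),
        (np.ones((2, 2)), 1.0),
    ])
    def test_average_brightness(self, region, expected):
        assert average_brightness(region) == pytest.approx(expected)

    def test_mask_fraction_counts_positive_pixels(self):
        assert mask_fraction(np.ones((32, 32))) == 1.0
        m = np.zeros((4, 4)); m.ravel()[:12] = 1
        assert mask_fraction(m) == 0.75
        assert mask_fraction(None) == 0.0


class TestCategorizeRegion:
    def test_dark_region_is_null(self):
        region = np.full((32, 32), 0.01)
        cons = BrightnessConstraints(b_null=0.05)
        assert categorize_region(region, None, cons, CATS, "tissue") == CATS.index("background")

    def test_null_rule_dominates_brightness_window(self):
        # in-window brightness, but below the (raised) null ceiling -> null
        region = np.full((32, 32), 0.2)
        cons = BrightnessConstraints(b_min=0.1, b_max=0.95, b_null=0.3)
        assert categorize_region(region, None, cons, CATS, "tissue") == CATS.index("background")

    def test_high_mask_coverage_is_expert(self):
        region = np.full((32, 32), 0.5)
        mask = np.ones((32, 32)); mask[:, 0] = 0          # 31/32 = 0.969 >= 0.95
        assert categorize_region(region, mask, CONS, CATS, "tissue") == CATS.index("lesion")

    def test_boundary_straddle_rejected(self):
        region = np.full((32, 32), 0.5)
        mask = np.zeros((32, 32)); mask[:16] = 1           # fraction 0.5
        assert categorize_region(region, mask, CONS, CATS, "tissue") is None

    def test_out_of_window_brightness_rejected(self):
        region = np.full((32, 32), 0.97)
        assert categorize_region(region, None, CONS, CATS, "tissue") is None

    def test_mask_free_in_window_is_naive(self):
        region = np.full((32, 32), 0.5)
        assert categorize_region(region, None, CONS, CATS, "tissue") == CATS.index("tissue")

    def test_exclusivity_requires_tolerance_below_half(self):
        with pytest.raises(ConfigurationError, match="exclusive"):
            BrightnessConstraints(mask_tolerance=0.5)


class TestGeneratePatches:
    def test_exhaustive_enumeration_matches_brute_force(self, masked_scene):
        scene, _, _ = masked_scene
        img = scene_to_source(scene)
        ds = generate_patches([img], CONS, CATS, n_target=None)
        oracle = brute_force_patches([img], CONS, CATS)
        assert len(ds) == len(oracle)
        for got, want in zip(ds.patches, oracle):
            assert got.origin == want.origin
            assert got.category_index == want.category_index
            np.testing.assert_array_equal(got.values, want.values)

    def test_origins_are_unique(self, masked_scene):
        scene, _, _ = masked_scene
        ds = generate_patches([scene_to_source(scene)], CONS, CATS, n_target=None)
        origins = [p.origin for p in ds.patches]
        assert len(origins) == len(set(origins))

    def test_target_beyond_eligible_grid_warns_and_truncates(self, masked_scene, caplog):
        scene, _, _ = masked_scene
        img = scene_to_source(scene)
        oracle = brute_force_patches([img], CONS, CATS)
        per_cat = np.bincount([p.category_index for p in oracle], minlength=3)
        with caplog.at_level(logging.WARNING, logger="medmat.patches"):
            ds = generate_patches([img], CONS, CATS, n_target=10 * len(oracle), seed=3)
        assert "exhausted" in caplog.text
        # balanced sampling: limited by the scarcest category
        counts = np.bincount([p.category_index for p in ds.patches], minlength=3)
        assert counts.max() <= (10 * len(oracle)) // 3
        assert counts.min() == per_cat.min() or counts.min() == (10 * len(oracle)) // 3

    def test_same_seed_reproduces_patch_set(self, masked_scene):
        scene, _, _ = masked_scene
        img = scene_to_source(scene)
        a = generate_patches([img], CONS, CATS, n_target=60, seed=5)
        b = generate_patches([img], CONS, CATS, n_target=60, seed=5)
        assert [p.origin for p in a.patches] == [p.origin for p in b.patches]

    def test_missing_category_raises(self, two_region_scene):
        scene, _, _ = two_region_scene
        img = scene_to_source(scene)   # no mask -> no expert patches possible
        with pytest.raises(ConfigurationError, match="absent"):
            generate_patches([img], CONS, CATS, n_target=None)

    def test_avg_brightness_equals_mean_of_values(self, masked_scene):
        scene, _, _ = masked_scene
        ds = generate_patches([scene_to_source(scene)], CONS, CATS, n_target=None)
        for p in ds.patches[:50]:
            assert p.avg_brightness == pytest.approx(p.values.mean(), abs=1e-9)


class TestSplitDataset:
    @pytest.fixture
    def balanced_ds(self, masked_scene):
        scene, _, _ = masked_scene
        ds = generate_patches([scene_to_source(scene)], CONS, CATS, n_target=None)
        return ds

    def test_sixty_twenty_twenty_per_category(self, balanced_ds):
        train, val, test = split_dataset(balanced_ds, (0.6, 0.2, 0.2), seed=1)
        for cat, records in balanced_ds.by_category().items():
            n = len(records)
            n_tr = sum(1 for p in train.patches if p.category_index == cat)
            n_va = sum(1 for p in val.patches if p.category_index == cat)
            assert n_tr == round(0.6 * n)
            assert n_va == min(round(0.2 * n), n - n_tr)

    def test_all_in_train_with_degenerate_fractions(self, balanced_ds):
        train, val, test = split_dataset(balanced_ds, (1.0, 0.0, 0.0), seed=1)
        assert len(train) == len(balanced_ds) and len(val) == len(test) == 0

    def test_split_is_disjoint_and_exhaustive(self, balanced_ds):
        parts = split_dataset(balanced_ds, (0.6, 0.2, 0.2), seed=2)
        origins = [p.origin for part in parts for p in part.patches]
        assert len(origins) == len(balanced_ds)
        assert len(set(origins)) == len(origins)

    def test_same_seed_same_membership(self, balanced_ds):
        a = split_dataset(balanced_ds, seed=4)
        b = split_dataset(balanced_ds, seed=4)
        for pa, pb in zip(a, b):
            assert [p.origin for p in pa.patches] == [p.origin for p in pb.patches]

    def test_tiny_category_cannot_stratify(self, balanced_ds):
        from medmat.patches import PatchDataset
        tiny = PatchDataset(balanced_ds.patches[:2] if False else
                            [p for p in balanced_ds.patches if p.category_index != 2]
                            + [p for p in balanced_ds.patches if p.category_index == 2][:2],
                            balanced_ds.category_names)
        with pytest.raises(ConfigurationError, match="stratify"):
            split_dataset(tiny)
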