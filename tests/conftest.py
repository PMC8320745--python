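"""Shared fixtures: small synthetic scenes and patch datasets."""

from __future__ import annotations

import numpy as np
import pytest

from medmat.patches import (BrightnessConstraints, CategoryConfig, PatchRecord,
                            SourceImage, average_brightness, mask_fraction)
from medmat.synthetic import Layout, Region, TextureSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_region_scene():
    """Dark background frame with one textured tissue square."""
    specs = [
        TextureSpec("background", base_brightness=0.02, noise_scale=0.005, pattern="smooth"),
        TextureSpec("tissue", base_brightness=0.55, noise_scale=0.05,
                    blur_radius=0.5, pattern="speckle", cell_size=3),
    ]
    layout = Layout(height=128, width=128, fill=0,
                    regions=(Region(spec=1, x0=40, y0=40, x1=120, y1=120),))
    return generate_scene(specs, layout, seed=7), specs, layout


@pytest.fixture
def masked_scene():
    """Scene with an expert-masked lesion disk inside the tissue square."""
    specs = [
        TextureSpec("background", base_brightness=0.02, noise_scale=0.005, pattern="smooth"),
        TextureSpec("tissue", base_brightness=0.5, noise_scale=0.05,
                    blur_radius=0.5, pattern="speckle", cell_size=3),
        TextureSpec("lesion", base_brightness=0.75, noise_scale=0.05,
                    blur_radius=1.0, pattern="blob", cell_size=4),
    ]
    layout = Layout(height=160, width=160, fill=0,
                    regions=(Region(spec=1, x0=32, y0=32, x1=128, y1=128),),
                    lesion=Region(spec=2, x0=80, y0=80, shape="disk", radius=36))
    return generate_scene(specs, layout, seed=11), specs, layout


def brute_force_patches(images: list[SourceImage], constraints: BrightnessConstraints,
                        categories: CategoryConfig, grid_spacing: int = 8,
                        patch_size: int = 32) -> list[PatchRecord]:
    """Independent re-application of the categorization rules at every grid point.

    Written directly from the rule statements (null ceiling first, then the
    brightness window, then mask-coverage thresholds), without sharing code
    with ``generate_patches``.
    """
    out: list[PatchRecord] = []
    for img in images:
        h, w = img.pixels.shape
        for y in range(0, h - patch_size + 1, grid_spacing):
            for x in range(0, w - patch_size + 1, grid_spacing):
                region = img.pixels[y:y + patch_size, x:x + patch_size]
                b = region.mean()
                mf = 0.0
                if img.mask is not None:
                    mf = float((img.mask[y:y + patch_size, x:x + patch_size] > 0).mean())
                t = constraints.mask_tolerance
                if b < constraints.b_null:
                    idx = categories.index(categories.null)
                elif not (constraints.b_min <= b <= constraints.b_max):
                    continue
                elif categories.expert is not None and mf >= 1 - t:
                    idx = categories.index(categories.expert)
                elif mf <= t:
                    idx = categories.index(img.naive_category)
                else:
                    continue
                out.append(PatchRecord(values=region.copy(), category_index=idx,
                                       origin=(img.image_id, x, y),
                                       avg_brightness=average_brightness(region),
                                       mask_fraction=mf))
    return out


@pytest.fixture(scope="session")
def ladder_patch_data():
    """Small 3-category patch arrays cut from similarity-ladder scenes."""
    from medmat.synthetic import generate_similarity_ladder

    scenes = generate_similarity_ladder(3, similarity_gap=0.6, seed=5, size=96)
    X, y = [], []
    for label, scene in enumerate(scenes):
        for yy in range(0, 96 - 32 + 1, 16):
            for xx in range(0, 96 - 32 + 1, 16):
                X.append(scene.image[yy:yy + 32, xx:xx + 32])
                y.append(label)
    return np.stack(X), np.asarray(y)
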