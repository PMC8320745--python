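"""Patch selection and categorization from normalized grayscale images.

Radiography datasets rarely come with material-texture labels.  This module
builds a labeled 32x32-patch dataset automatically from three kinds of
category evidence:

* **expert** categories (e.g. tumor) come from an expert-drawn binary mask —
  a patch qualifies when at least ``(1 - T) * 100`` percent of its area lies
  inside the mask, where ``T`` is the *mask tolerance*;
* **naïve** categories (e.g. bone, healthy tissue) are assigned when a patch
  is essentially mask-free (mask fraction at most ``T``) and its average
  brightness falls inside a window ``[b_min, b_max]``;
* the **null** category (image background) absorbs any patch whose average
  brightness falls below ``b_null``, regardless of mask coverage.

Patches whose mask coverage falls strictly between ``T`` and ``1 - T``
straddle the mask boundary and are rejected outright — mixed-material
patches would blur the categories during training.  Requiring ``T < 0.5``
makes the expert and naïve rules mutually exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "BrightnessConstraints", "SourceImage", "PatchRecord", "PatchDataset",
    "CategoryConfig", "normalize_image", "average_brightness", "mask_fraction",
    "categorize_region", "generate_patches", "split_dataset",
]


@dataclass(frozen=True)
class BrightnessConstraints:
    """Run-time thresholds of the categorization rules (all on [0, 1] gray levels).

    b_null is the null-category ceiling; [b_min, b_max] the brightness window
    a non-null patch must fall in; mask_tolerance is T above.
    """

    b_min: float = 0.1
    b_max: float = 0.95
    b_null: float = 0.05
    mask_tolerance: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.b_min <= self.b_max <= 1.0:
            raise ConfigurationError(f"need 0 <= b_min <= b_max <= 1, got [{self.b_min}, {self.b_max}]")
        if not 0.0 < self.mask_tolerance < 0.5:
            raise ConfigurationError(
                f"mask_tolerance must lie in (0, 0.5) so expert/naive rules are exclusive, "
                f"got {self.mask_tolerance}")
        if not 0.0 <= self.b_null <= 1.0:
            raise ConfigurationError(f"b_null {self.b_null} outside [0, 1]")


@dataclass(frozen=True)
class CategoryConfig:
    """Category names and their roles.

    ``naive`` maps each naïve category to nothing in particular here — the
    binding of a naïve category to images happens through
    :attr:`SourceImage.naive_category`.
    """

    names: tuple[str, ...]
    null: str
    expert: str | None = None
    constraint_overrides: dict[str, BrightnessConstraints] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError(f"duplicate category names: {self.names}")
        if self.null not in self.names:
            raise ConfigurationError(f"null category {self.null!r} not in {self.names}")
        if self.expert is not None and self.expert not in self.names:
            raise ConfigurationError(f"expert category {self.expert!r} not in {self.names}")
        unknown = set(self.constraint_overrides) - set(self.names)  # keyed by modality too
        del unknown  # overrides may be keyed by modality tag; no strict check

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class SourceImage:
    """A normalized grayscale image with optional expert mask.

    ``naive_category`` names the category a mask-free patch of this image
    belongs to (per-modality binding, e.g. "bone" for knee X-rays).
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    modality_tag: str = ""
    image_id: str = ""
    naive_category: str = ""

    def __post_init__(self):
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ConfigurationError("SourceImage pixels must be normalized to [0, 1]")
        if self.mask is not None and self.mask.shape != self.pixels.shape:
            raise ConfigurationError("mask shape differs from pixel shape")


@dataclass
class PatchRecord:
    values: np.ndarray            # (patch, patch) floats in [0, 1]
    category_index: int
    origin: tuple[str, int, int]  # (image id, x, y), x to the right, y down
    avg_brightness: float
    mask_fraction: float


@dataclass
class PatchDataset:
    patches: list[PatchRecord]
    category_names: tuple[str, ...]
    split: str = "all"

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (X, y): X is (n, patch, patch), y is (n,) int labels."""
        X = np.stack([p.values for p in self.patches])
        y = np.array([p.category_index for p in self.patches], dtype=np.int64)
        return X, y

    def by_category(self) -> dict[int, list[PatchRecord]]:
        out: dict[int, list[PatchRecord]] = {k: [] for k in range(self.n_categories)}
        for p in self.patches:
            out[p.category_index].append(p)
        return out


# ---------------------------------------------------------------------------
# elementary operations

def normalize_image(raw: np.ndarray, is_negative: bool = False, **source_kwargs) -> SourceImage:
    """Min-max normalize to [0, 1]; invert first when the image is a negative.

    A constant-valued image (degenerate min-max) is emitted as all zeros
    with a logged warning.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ConfigurationError("empty image")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("constant-valued image; normalizing to all zeros")
        pixels = np.zeros_like(raw)
    else:
        pixels = (raw - lo) / (hi - lo)
        if is_negative:
            pixels = 1.0 - pixels
    return SourceImage(pixels=pixels, **source_kwargs)


def average_brightness(region: np.ndarray) -> float:
    """Mean of the region's normalized values (sum over entries / count)."""
    region = np.asarray(region)
    if region.size == 0:
        raise ConfigurationError("empty region")
    return float(region.mean())


def mask_fraction(region_mask: np.ndarray | None) -> float:
    """Fraction of mask-positive pixels in the region; 0 when no mask exists."""
    if region_mask is None:
        return 0.0
    region_mask = np.asarray(region_mask)
    return float((region_mask > 0).mean())


def categorize_region(region: np.ndarray, region_mask: np.ndarray | None,
                      constraints: BrightnessConstraints, categories: CategoryConfig,
                      naive_category: str) -> int | None:
    """Assign a candidate region to a category index, or None to reject.

    Rule order: the null rule dominates (a very dark patch is null even if
    its brightness also clears the window); then the brightness window gates
    everything else; then mask coverage decides expert vs naïve vs
    boundary-straddle rejection.
    """
    b = average_brightness(region)
    if b < constraints.b_null:
        return categories.index(categories.null)
    if not constraints.b_min <= b <= constraints.b_max:
        return None
    t = constraints.mask_tolerance
    mf = mask_fraction(region_mask)
    if categories.expert is not None and mf >= 1.0 - t:
        return categories.index(categories.expert)
    if mf <= t:
        if naive_category not in categories.names:
            raise ConfigurationError(f"naive category {naive_category!r} not configured")
        return categories.index(naive_category)
    return None  # straddles the mask boundary


# ---------------------------------------------------------------------------
# dataset construction

def _grid_points(image: SourceImage, patch_size: int, grid_spacing: int) -> list[tuple[int, int]]:
    h, w = image.pixels.shape
    return [(x, y)
            for y in range(0, h - patch_size + 1, grid_spacing)
            for x in range(0, w - patch_size + 1, grid_spacing)]


def _evaluate_point(image: SourceImage, x: int, y: int, patch_size: int,
                    constraints: BrightnessConstraints, categories: CategoryConfig) -> PatchRecord | None:
    region = image.pixels[y:y + patch_size, x:x + patch_size]
    region_mask = None if image.mask is None else image.mask[y:y + patch_size, x:x + patch_size]
    idx = categorize_region(region, region_mask, constraints, categories, image.naive_category)
    if idx is None:
        return None
    return PatchRecord(values=region.copy(), category_index=idx,
                       origin=(image.image_id, x, y),
                       avg_brightness=average_brightness(region),
                       mask_fraction=mask_fraction(region_mask))


def generate_patches(images: list[SourceImage], constraints: BrightnessConstraints,
                     categories: CategoryConfig, n_target: int | None = None,
                     grid_spacing: int = 8, patch_size: int = 32,
                     seed: int = 0, balanced: bool = True) -> PatchDataset:
    """Select and categorize unique patches from grid points across the images.

    Every candidate is the ``patch_size`` square below and to the right of a
    grid point (x, y); each accepted patch originates from a unique
    (image, x, y).  With ``n_target=None`` every grid point is evaluated and
    every accepted patch kept, in deterministic image/row-major order
    (exhaustive enumeration).  Otherwise points are visited in seeded random
    order and accepted round-robin so the final set is balanced across
    categories (``n_target // K`` patches per category); the sampler keeps
    drawing until the per-category quotas fill or the eligible grid is
    exhausted, in which case a partial dataset is returned with a warning.

    Per-modality constraint overrides are honored through
    ``categories.constraint_overrides`` keyed by the image's modality tag.
    """
    if grid_spacing < 1:
        raise ConfigurationError("grid_spacing must be >= 1")
    candidates: list[tuple[int, int, int]] = []  # (image index, x, y)
    for i, img in enumerate(images):
        if img.pixels.shape[0] < patch_size or img.pixels.shape[1] < patch_size:
            continue
        candidates.extend((i, x, y) for x, y in _grid_points(img, patch_size, grid_spacing))
    if not candidates:
        raise ConfigurationError("no image can fit a single patch")

    def cons_for(img: SourceImage) -> BrightnessConstraints:
        return categories.constraint_overrides.get(img.modality_tag, constraints)

    accepted: list[PatchRecord] = []
    if n_target is None:
        for i, x, y in candidates:
            rec = _evaluate_point(images[i], x, y, patch_size, cons_for(images[i]), categories)
            if rec is not None:
                accepted.append(rec)
    else:
        k = len(categories.names)
        per_cat = n_target // k if balanced else None
        counts = np.zeros(k, dtype=int)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(candidates))
        for j in order:
            i, x, y = candidates[j]
            rec = _evaluate_point(images[i], x, y, patch_size, cons_for(images[i]), categories)
            if rec is None:
                continue
            if balanced and counts[rec.category_index] >= per_cat:
                continue
            counts[rec.category_index] += 1
            accepted.append(rec)
            if balanced and counts.min() >= per_cat:
                break
            if not balanced and len(accepted) >= n_target:
                break
        if (balanced and counts.min() < per_cat) or (not balanced and len(accepted) < n_target):
            logger.warning("eligible grid exhausted: requested %d patches, emitting %d",
                           n_target, len(accepted))

    present = {rec.category_index for rec in accepted}
    missing = [name for i, name in enumerate(categories.names) if i not in present]
    if missing:
        raise ConfigurationError(f"categories absent from all images: {missing}")
    return PatchDataset(patches=accepted, category_names=tuple(categories.names))


def split_dataset(ds: PatchDataset, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> tuple[PatchDataset, PatchDataset, PatchDataset]:
    """Disjoint, exhaustive, per-category stratified train/val/test split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"split fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    buckets: tuple[list[PatchRecord], ...] = ([], [], [])
    for cat, records in sorted(ds.by_category().items()):
        if len(records) < 3:
            raise ConfigurationError(
                f"category {ds.category_names[cat]!r} has {len(records)} patches; "
                "need >= 3 to stratify")
        order = rng.permutation(len(records))
        n = len(records)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_val = min(n_val, n - n_train)
        for pos, j in enumerate(order):
            which = 0 if pos < n_train else (1 if pos < n_train + n_val else 2)
            buckets[which].append(records[j])
    names = ds.category_names
    return (PatchDataset(buckets[0], names, "train"),
            PatchDataset(buckets[1], names, "val"),
            PatchDataset(buckets[2], names, "test"))
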