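"""Synthetic radiography-like scenes with known ground truth.

Real radiographs pair a dark, information-free background with textured
tissue regions — e.g. the "spongy" look of trabecular bone against smoother
soft tissue — and sometimes carry an expert-drawn mask delineating a lesion.
This module procedurally generates grayscale scenes with that structure:
a dark background, two or more textured regions with controllable pairwise
similarity, and an optional masked sub-region standing in for a tumor.
Each scene ships its ground-truth ``region_map``, so downstream patch
labeling can be verified independently of the brightness/mask rules used to
build training sets.

All output is a pure function of (config, seed): the same arguments always
produce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

__all__ = [
    "TextureSpec", "Region", "Layout", "SyntheticScene",
    "generate_scene", "generate_similarity_ladder",
]

PATTERNS = ("speckle", "smooth", "blob")


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of one procedural texture category.

    base_brightness : mean gray level of the region, in [0, 1].
    noise_scale     : amplitude (std) of the texture fluctuation.
    blur_radius     : Gaussian smoothing applied to the fluctuation, pixels.
    pattern         : "speckle" (value noise on a lattice), "smooth"
                      (white noise), or "blob" (sparse bright bumps).
    cell_size       : lattice spacing of the value noise / blob radius, px.
    """

    name: str
    base_brightness: float
    noise_scale: float = 0.0
    blur_radius: float = 0.0
    pattern: str = "smooth"
    cell_size: int = 4

    def __post_init__(self):
        if not 0.0 <= self.base_brightness <= 1.0:
            raise ConfigurationError(f"base_brightness {self.base_brightness} outside [0, 1]")
        if self.noise_scale < 0 or self.blur_radius < 0:
            raise ConfigurationError("noise_scale and blur_radius must be >= 0")
        if self.pattern not in PATTERNS:
            raise ConfigurationError(f"pattern {self.pattern!r} not in {PATTERNS}")
        lo = self.base_brightness - 3 * self.noise_scale
        hi = self.base_brightness + 3 * self.noise_scale
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ConfigurationError(
                f"{self.name}: base_brightness +/- 3*noise_scale ([{lo:.3f}, {hi:.3f}]) "
                "must stay within [0, 1]")
        if self.cell_size < 1:
            raise ConfigurationError("cell_size must be >= 1")


@dataclass(frozen=True)
class Region:
    """A rectangular or disk-shaped area assigned to one texture spec.

    Rectangles are half-open ``[x0, x1) x [y0, y1)``; disks use (x0, y0) as
    the center and ``radius``.
    """

    spec: int
    x0: int
    y0: int
    x1: int = 0
    y1: int = 0
    shape: str = "rect"
    radius: int = 0


@dataclass(frozen=True)
class Layout:
    """Scene geometry: canvas size, a fill spec, and carved-out regions.

    Pixels not claimed by any region take the ``fill`` spec, so the regions
    plus the fill always tile the canvas; regions must be mutually disjoint.
    ``lesion`` is an optional *sub-region* carved on top of whatever it
    overlays — the "tumor" stand-in — and its footprint becomes the expert
    mask of the scene.
    """

    height: int = 128
    width: int = 128
    fill: int = 0
    regions: tuple[Region, ...] = field(default_factory=tuple)
    lesion: Region | None = None


@dataclass
class SyntheticScene:
    image: np.ndarray             # (H, W) float in [0, 1]
    region_map: np.ndarray        # (H, W) int spec indices (ground truth)
    seed: int
    mask: np.ndarray | None = None   # (H, W) uint8 binary, or None
    category_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.region_map.shape != self.image.shape:
            raise ConfigurationError("image and region_map shapes differ")
        if self.mask is not None and self.mask.shape != self.image.shape:
            raise ConfigurationError("image and mask shapes differ")


def _texture_field(spec: TextureSpec, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Render one spec's texture over the full canvas."""
    h, w = shape
    if spec.noise_scale == 0.0:
        return np.full(shape, spec.base_brightness)
    if spec.pattern == "smooth":
        fluct = rng.normal(0.0, 1.0, size=shape)
    elif spec.pattern == "speckle":
        # value noise: random lattice upsampled to pixel resolution
        c = spec.cell_size
        coarse = rng.normal(0.0, 1.0, size=(h // c + 2, w // c + 2))
        fluct = ndimage.zoom(coarse, c, order=1)[:h, :w]
    else:  # blob: sparse smoothed bumps
        density = 1.0 / max(spec.cell_size, 1) ** 2
        fluct = (rng.random(shape) < density).astype(float)
        fluct = ndimage.gaussian_filter(fluct, sigma=max(spec.cell_size / 2.0, 0.5))
    if spec.blur_radius > 0:
        fluct = ndimage.gaussian_filter(fluct, sigma=spec.blur_radius)
    sd = fluct.std()
    if sd > 0:
        fluct = (fluct - fluct.mean()) / sd * spec.noise_scale
    return np.clip(spec.base_brightness + fluct, 0.0, 1.0)


def _region_footprint(region: Region, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    if region.shape == "rect":
        if not (0 <= region.x0 < region.x1 <= w and 0 <= region.y0 < region.y1 <= h):
            raise ConfigurationError(f"rect region {region} outside {w}x{h} canvas")
        out[region.y0:region.y1, region.x0:region.x1] = True
    elif region.shape == "disk":
        yy, xx = np.mgrid[0:h, 0:w]
        out[(xx - region.x0) ** 2 + (yy - region.y0) ** 2 <= region.radius ** 2] = True
        if not out.any():
            raise ConfigurationError(f"disk region {region} covers no pixels")
    else:
        raise ConfigurationError(f"unknown region shape {region.shape!r}")
    return out


def generate_scene(specs: list[TextureSpec], layout: Layout, seed: int) -> SyntheticScene:
    """Compose per-spec texture fields into one scene.

    Each spec's texture is rendered over the full canvas and the region map
    selects which field supplies each pixel, so textures never bleed across
    region boundaries.  Raises :class:`ConfigurationError` for overlapping
    regions, duplicate spec names, or out-of-range spec indices.
    """
    if len(specs) < 2:
        raise ConfigurationError("need at least 2 texture specs")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate spec names in {names}")
    shape = (layout.height, layout.width)
    used = {layout.fill} | {r.spec for r in layout.regions}
    if layout.lesion is not None:
        used.add(layout.lesion.spec)
    if not used <= set(range(len(specs))):
        raise ConfigurationError("layout references a spec index outside the spec list")

    region_map = np.full(shape, layout.fill, dtype=np.int64)
    claimed = np.zeros(shape, dtype=bool)
    for region in layout.regions:
        foot = _region_footprint(region, shape)
        if (claimed & foot).any():
            raise ConfigurationError(f"region {region} overlaps a previous region")
        claimed |= foot
        region_map[foot] = region.spec

    mask = None
    if layout.lesion is not None:
        foot = _region_footprint(layout.lesion, shape)
        region_map[foot] = layout.lesion.spec
        mask = foot.astype(np.uint8)

    rng = np.random.default_rng(seed)
    image = np.zeros(shape)
    for idx, spec in enumerate(specs):
        # draw every field even when unused so the stream layout is stable
        fld = _texture_field(spec, shape, rng)
        image[region_map == idx] = fld[region_map == idx]
    return SyntheticScene(image=image, region_map=region_map, seed=seed,
                          mask=mask, category_names=tuple(names))


def ladder_specs(n_categories: int, similarity_gap: float) -> list[TextureSpec]:
    """Texture specs whose parameter distance to category 0 grows strictly.

    Categories share the speckle pattern; the mean brightness climbs by a
    constant step proportional to ``similarity_gap``, so the parameter
    distance between category 0 and category i is proportional to i.
    """
    if n_categories < 3:
        raise ConfigurationError("similarity ladder needs >= 3 categories")
    if not 0.0 < similarity_gap < 1.0:
        raise ConfigurationError("similarity_gap must lie strictly inside (0, 1)")
    lo, hi = 0.30, 0.85
    step = similarity_gap * (hi - lo) / (n_categories - 1)
    return [
        TextureSpec(name=f"rung{i}", base_brightness=lo + i * step,
                    noise_scale=0.05, blur_radius=0.8, pattern="speckle",
                    cell_size=3)
        for i in range(n_categories)
    ]


def generate_similarity_ladder(n_categories: int, similarity_gap: float,
                               seed: int, size: int = 128) -> list[SyntheticScene]:
    """One full-canvas scene per rung of a texture-similarity ladder.

    Scene ``i`` is covered entirely by category ``i``; parameter distances
    satisfy dist(0, 1) < dist(0, 2) < ... < dist(0, n-1) by construction.
    """
    specs = ladder_specs(n_categories, similarity_gap)
    scenes = []
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        image = _texture_field(spec, (size, size), rng)
        region_map = np.full((size, size), i, dtype=np.int64)
        scenes.append(SyntheticScene(image=image, region_map=region_map, seed=seed,
                                     category_names=tuple(s.name for s in specs)))
    return scenes


def default_study_specs() -> list[TextureSpec]:
    """The 4-category study configuration: background / tissue A / tissue B / lesion.

    Tissues A and B are the deliberately similar pair: nearly equal mean
    brightness (0.47 vs 0.53, far closer than the 0.02 background or the
    0.75 lesion) and the same speckle pattern at different spatial scales.
    The lesion is a brighter blob texture delineated by the expert mask;
    the background is near-black and smooth.
    """
    return [
        TextureSpec("background", base_brightness=0.02, noise_scale=0.005,
                    blur_radius=0.5, pattern="smooth"),
        TextureSpec("tissue_a", base_brightness=0.47, noise_scale=0.08,
                    blur_radius=0.5, pattern="speckle", cell_size=3),
        TextureSpec("tissue_b", base_brightness=0.53, noise_scale=0.08,
                    blur_radius=0.5, pattern="speckle", cell_size=5),
        TextureSpec("lesion", base_brightness=0.75, noise_scale=0.06,
                    blur_radius=1.0, pattern="blob", cell_size=4),
    ]


def default_study_layout(size: int = 160, tissue_spec: int = 1,
                         with_lesion: bool = True) -> Layout:
    """One modality's scene: background frame, a tissue square, optional lesion.

    Mirrors how real datasets bind one naive category per modality (bone in
    knee X-rays, healthy tissue in brain MRIs): each image carries a single
    tissue texture, and lesion-bearing images add a masked disk inside it.
    """
    m = size // 5                      # background margin; wider than a patch
    regions = (Region(spec=tissue_spec, x0=m, y0=m, x1=size - m, y1=size - m),)
    lesion = None
    if with_lesion:
        lesion = Region(spec=3, x0=size // 2, y0=size // 2,
                        shape="disk", radius=(size - 2 * m) * 3 // 8)
    return Layout(height=size, width=size, fill=0, regions=regions, lesion=lesion)
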