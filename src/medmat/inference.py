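"""Whole-image material maps and analysis artifacts.

A trained patch classifier is applied in sliding-window fashion (32x32
window, stride 4 by default) across a full image, producing a category
label map and one probability map per attribute.  Two diagnostics mirror
the standard analysis of such models: the Pearson correlation between each
attribute and the occurrence of each true category, and a 2-D stochastic
neighbor embedding (with silhouette score) comparing how well the learned
attributes separate categories versus the raw pixel features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError
from .patches import SourceImage

logger = logging.getLogger(__name__)

__all__ = ["MaterialMap", "map_shape", "sliding_window_map",
           "category_attribute_correlation", "embedding_separation"]


@dataclass
class MaterialMap:
    """Window-grid maps: cell (i, j) describes the window at (j*stride, i*stride)."""

    category_map: np.ndarray      # (Hm, Wm) int
    attribute_maps: np.ndarray    # (M, Hm, Wm) float in [0, 1]
    window: int = 32
    stride: int = 4


def map_shape(height: int, width: int, window: int = 32, stride: int = 4) -> tuple[int, int]:
    """Window-grid dimensions: floor((H - window) / stride) + 1, likewise for W."""
    if height < window or width < window:
        raise ConfigurationError(f"image {height}x{width} smaller than window {window}")
    return ((height - window) // stride + 1, (width - window) // stride + 1)


def sliding_window_map(model, image, window: int = 32, stride: int = 4,
                       batch: int = 512) -> MaterialMap:
    """Classify every strided window of a full image.

    ``model`` is a fitted :class:`~medmat.mac.MaterialAttributeClassifier`;
    ``image`` a :class:`~medmat.patches.SourceImage` or normalized 2-D array.
    """
    pixels = image.pixels if isinstance(image, SourceImage) else np.asarray(image, dtype=np.float64)
    hm, wm = map_shape(*pixels.shape, window=window, stride=stride)
    windows = sliding_window_view(pixels, (window, window))[::stride, ::stride]
    flat = windows.reshape(hm * wm, window, window)
    cats = np.empty(hm * wm, dtype=np.int64)
    attrs = np.empty((hm * wm, model.net_.n_attributes))
    for start in range(0, len(flat), batch):
        chunk = np.ascontiguousarray(flat[start:start + batch])
        cats[start:start + batch] = model.predict(chunk)
        attrs[start:start + batch] = model.predict_attributes(chunk)
    return MaterialMap(category_map=cats.reshape(hm, wm),
                       attribute_maps=np.moveaxis(attrs.reshape(hm, wm, -1), 2, 0),
                       window=window, stride=stride)


def category_attribute_correlation(attributes: np.ndarray, labels: np.ndarray,
                                   n_categories: int | None = None) -> np.ndarray:
    """Pearson correlation of each attribute with each true-category indicator.

    Entry (k, m) correlates the binary indicator "true category is k" with
    attribute m across patches.  Zero-variance attributes (or categories)
    yield NaN entries, which are logged and reported as missing.
    """
    attributes = np.asarray(attributes, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if attributes.ndim != 2 or len(attributes) != len(labels):
        raise ConfigurationError("attributes must be (n, M) aligned with labels")
    if len(labels) < 2:
        raise ConfigurationError("need at least 2 samples")
    k = int(n_categories if n_categories is not None else labels.max() + 1)
    out = np.full((k, attributes.shape[1]), np.nan)
    attr_sd = attributes.std(axis=0)
    for cat in range(k):
        indicator = (labels == cat).astype(np.float64)
        sd_c = indicator.std()
        if sd_c == 0:
            logger.warning("category %d has zero variance; correlations reported missing", cat)
            continue
        centered = indicator - indicator.mean()
        cov = centered @ (attributes - attributes.mean(axis=0)) / len(labels)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = cov / (sd_c * attr_sd)
        row[attr_sd == 0] = np.nan
        out[cat] = row
    if np.isnan(out[:, attr_sd == 0]).any() and (attr_sd == 0).any():
        logger.warning("zero-variance attributes %s reported missing",
                       np.flatnonzero(attr_sd == 0).tolist())
    return out


def embedding_separation(features: np.ndarray, labels: np.ndarray,
                         seed: int = 0) -> tuple[np.ndarray, float]:
    """2-D stochastic neighbor embedding plus silhouette score of the result.

    Returns (embedding (n, 2), silhouette in [-1, 1]).  Higher silhouette
    means the categories separate more cleanly in the feature space.
    Degenerate input (a single category, or identical features for all
    points) raises :class:`ConfigurationError`.
    """
    features = np.asarray(features, dtype=np.float64).reshape(len(features), -1)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ConfigurationError("need at least 2 categories to measure separation")
    if np.ptp(features, axis=0).max() == 0:
        raise ConfigurationError("identical features for all points; separation undefined")
    perplexity = min(30.0, (len(features) - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, init="pca", perplexity=perplexity)
    emb = tsne.fit_transform(features)
    return emb, float(silhouette_score(emb, labels))
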