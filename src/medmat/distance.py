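"""Aggregating same/different similarity decisions into a perceptual distance matrix.

Each decision is binary: ``s = 1`` when the comparison network judged a
reference/comparison patch pair to be of *different* material categories,
``s = 0`` for *same*.  Pooling decisions per comparison category yields a
K-vector ``p``; the distance between categories k and k' is the norm of the
difference of their entries.  Two readings of the pooling are provided:

* **scalar** (default): one pooled rate per comparison category,
  ``D[k, k'] = |p_k - p_k'|``;
* **profile**: one K-vector of pooled rates per *reference* category, with
  ``D[k, k']`` the Euclidean distance between the two categories' profiles.

The scalar reading is the default; the profile variant retains
reference-category information that the scalar pooling discards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["DecisionLog", "DistanceMatrix", "aggregate_decisions",
           "build_distance_matrix", "build_profile_distance_matrix"]


@dataclass
class DecisionLog:
    """Records of (reference class, comparison class, decision in {0, 1})."""

    n_categories: int
    records: list[tuple[int, int, int]] = field(default_factory=list)

    def add(self, reference: int, comparison: int, decision: int) -> None:
        if decision not in (0, 1):
            raise ValueError(f"decision must be 0 or 1, got {decision}")
        self.records.append((int(reference), int(comparison), int(decision)))

    def counts(self) -> np.ndarray:
        n = np.zeros(self.n_categories, dtype=int)
        for _, c, _ in self.records:
            n[c] += 1
        return n


@dataclass
class DistanceMatrix:
    """Symmetric K x K matrix of perceptual distances with provenance."""

    values: np.ndarray
    category_names: tuple[str, ...] = ()
    provenance: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConfigurationError(f"distance matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ConfigurationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ConfigurationError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ConfigurationError("distance matrix entries must be >= 0")
        self.values = v
        if self.category_names and len(self.category_names) != v.shape[0]:
            raise ConfigurationError("category_names length mismatch")

    @property
    def n_categories(self) -> int:
        return self.values.shape[0]


def aggregate_decisions(log: DecisionLog) -> np.ndarray:
    """Pooled different-rate per comparison category: p_k = (1/N_k) * sum of s."""
    counts = log.counts()
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ConfigurationError(f"no decisions for comparison classes {missing.tolist()}")
    totals = np.zeros(log.n_categories)
    for _, c, s in log.records:
        totals[c] += s
    return totals / counts


def build_distance_matrix(p: np.ndarray, category_names: tuple[str, ...] = (),
                          provenance: str = "") -> DistanceMatrix:
    """Scalar reading: D[k, k'] = |p_k - p_k'| for pooled rates p in [0, 1]^K."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ConfigurationError("p must be a 1-D vector")
    if (p < 0).any() or (p > 1).any():
        raise ConfigurationError("entries of p must lie in [0, 1]")
    d = np.abs(p[:, None] - p[None, :])
    return DistanceMatrix(values=d, category_names=category_names, provenance=provenance)


def build_profile_distance_matrix(log: DecisionLog, category_names: tuple[str, ...] = (),
                                  provenance: str = "") -> DistanceMatrix:
    """Profile reading: per-reference-class mean-decision vectors, pairwise L2."""
    k = log.n_categories
    totals = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for r, c, s in log.records:
        totals[r, c] += s
        counts[r, c] += 1
    if (counts == 0).any():
        empty = [tuple(ix) for ix in np.argwhere(counts == 0)]
        raise ConfigurationError(f"no decisions for reference/comparison cells {empty}")
    profiles = totals / counts
    diff = profiles[:, None, :] - profiles[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    d = 0.5 * (d + d.T)            # exact symmetry against fp rounding
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, category_names=category_names, provenance=provenance)
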