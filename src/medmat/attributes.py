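"""Machine-discovered material attributes: the K x M category-attribute matrix.

Given a perceptual distance matrix ``D`` between K material categories, this
module finds a matrix ``A`` whose rows are M-dimensional attribute
probability vectors, one per category, such that

* pairwise Euclidean distances between rows of ``A`` reproduce the entries
  of ``D`` (a metric embedding), and
* the marginal distribution of the entries of ``A`` is pulled toward a
  Beta(0.5, 0.5) (arcsine) law — attributes should be strongly present or
  strongly absent, rarely lukewarm, mirroring how human observers rate
  material traits.

The pull is implemented as the KL divergence from the Beta target to a
Gaussian kernel density estimate of the entries of ``A``, evaluated on a
fixed grid ``P`` inside (0, 1), weighted by ``gamma``.  The minimization is
box-constrained (entries in [0, 1]) quasi-Newton (L-BFGS-B) from several
random restarts.  The sum over category pairs runs over ordered pairs
(each unordered pair counted twice); the constant factor does not move the
argmin.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .distance import DistanceMatrix
from .errors import ConfigurationError

__all__ = ["BetaTarget", "beta_density", "kde_density", "attribute_objective",
           "attribute_objective_grad", "optimize_A", "AttributeEmbedding",
           "default_grid", "distance_residual_rms"]

_Q_FLOOR = 1e-12


class BetaTarget:
    """Beta(a, b) target for the entry distribution; default arcsine a = b = 0.5."""

    def __init__(self, a: float = 0.5, b: float = 0.5):
        if a <= 0 or b <= 0:
            raise ConfigurationError("Beta parameters must be positive")
        self.a, self.b = float(a), float(b)

    def density(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=np.float64)
        if ((p <= 0) | (p >= 1)).any():
            raise ConfigurationError("Beta density requested outside the open interval (0, 1)")
        return stats.beta.pdf(p, self.a, self.b)


def default_grid(n_points: int = 101, margin: float = 0.005) -> np.ndarray:
    """Equispaced KL evaluation grid strictly inside (0, 1)."""
    return np.linspace(margin, 1.0 - margin, n_points)


def beta_density(p, target: BetaTarget | None = None) -> np.ndarray | float:
    """Beta target density at p; for a = b = 0.5 this is 1 / (pi * sqrt(p(1-p)))."""
    target = target or BetaTarget()
    out = target.density(p)
    return float(out) if np.ndim(p) == 0 else out


def kde_density(p, A: np.ndarray, h: float = 0.1) -> np.ndarray | float:
    """Gaussian KDE of the entries of A at point(s) p.

    Equal-weight mixture of K*M Gaussians of bandwidth h centered on the
    entries, so the density integrates to one over the real line.
    """
    if h <= 0:
        raise ConfigurationError("bandwidth h must be positive")
    entries = np.asarray(A, dtype=np.float64).ravel()
    pa = np.atleast_1d(np.asarray(p, dtype=np.float64))
    z = (entries[:, None] - pa[None, :]) / h
    q = np.exp(-0.5 * z ** 2).sum(axis=0) / (entries.size * h * np.sqrt(2 * np.pi))
    return float(q[0]) if np.ndim(p) == 0 else q


def _pair_residuals(A: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    diff = A[:, None, :] - A[None, :, :]
    dists = np.sqrt((diff ** 2).sum(axis=2))
    return dists, dists - D


def attribute_objective(A: np.ndarray, D: np.ndarray, gamma: float = 1.0,
                        target: BetaTarget | None = None,
                        grid: np.ndarray | None = None, h: float = 0.1) -> float:
    """Distance-matching residual plus gamma-weighted KL pull toward the Beta target.

    objective = sum over ordered pairs (k, k') of (||a_k - a_k'|| - D[k,k'])^2
              + gamma * sum over p in grid of beta(p) * ln(beta(p) / q(p; A)).
    """
    A = np.asarray(A, dtype=np.float64)
    D = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=np.float64)
    if A.ndim != 2 or D.shape != (A.shape[0], A.shape[0]):
        raise ConfigurationError(f"shape mismatch: A {A.shape}, D {D.shape}")
    _, resid = _pair_residuals(A, D)
    value = float((resid ** 2).sum())        # diagonal contributes 0 - 0
    if gamma != 0.0:
        target = target or BetaTarget()
        grid = default_grid() if grid is None else np.asarray(grid)
        beta_p = target.density(grid)
        q = np.maximum(kde_density(grid, A, h), _Q_FLOOR)
        value += gamma * float((beta_p * (np.log(beta_p) - np.log(q))).sum())
    return value


def attribute_objective_grad(A: np.ndarray, D: np.ndarray, gamma: float = 1.0,
                             target: BetaTarget | None = None,
                             grid: np.ndarray | None = None, h: float = 0.1) -> np.ndarray:
    """Analytic gradient of :func:`attribute_objective` with respect to A."""
    A = np.asarray(A, dtype=np.float64)
    D = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=np.float64)
    dists, resid = _pair_residuals(A, D)
    diff = A[:, None, :] - A[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dists[:, :, None] > 0, diff / np.maximum(dists, 1e-300)[:, :, None], 0.0)
    # d/dA of sum over ordered pairs: each row k appears as first index (factor 2
    # from the square) and as second index (sign flip), and resid is symmetric.
    grad = 4.0 * (resid[:, :, None] * unit).sum(axis=1)
    if gamma != 0.0:
        target = target or BetaTarget()
        grid = default_grid() if grid is None else np.asarray(grid)
        beta_p = target.density(grid)
        entries = A.ravel()
        z = (entries[:, None] - grid[None, :]) / h
        kern = np.exp(-0.5 * z ** 2) / (entries.size * h * np.sqrt(2 * np.pi))
        q = np.maximum(kern.sum(axis=0), _Q_FLOOR)
        # dKL/da = -sum_p beta_p / q_p * dq_p/da,  dq_p/da = -kern * (a - p)/h^2
        dq_da = -kern * (entries[:, None] - grid[None, :]) / h ** 2
        grad += gamma * (-(beta_p / q)[None, :] * dq_da).sum(axis=1).reshape(A.shape)
    return grad


def optimize_A(D, M: int, gamma: float = 1.0, seed: int = 0, restarts: int = 5,
               h: float = 0.1, grid: np.ndarray | None = None,
               target: BetaTarget | None = None,
               max_iter: int = 500) -> tuple[np.ndarray, float]:
    """Best-of-restarts box-constrained minimization of the attribute objective.

    Entries are initialized i.i.d. uniform on [0.1, 0.9] (keeping the first KL
    evaluation away from the Beta density's unbounded endpoints).  Returns
    (A, objective value at A).  If no restart converges the best iterate is
    returned with a warning.
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=np.float64)
    K = Dv.shape[0]
    if M < 2:
        raise ConfigurationError("need at least M = 2 attributes")
    if restarts < 1:
        raise ConfigurationError("need at least one restart")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    any_converged = False
    for _ in range(restarts):
        a0 = rng.uniform(0.1, 0.9, size=(K, M))
        res = optimize.minimize(
            lambda v: attribute_objective(v.reshape(K, M), Dv, gamma, target, grid, h),
            a0.ravel(),
            jac=lambda v: attribute_objective_grad(v.reshape(K, M), Dv, gamma, target, grid, h).ravel(),
            method="L-BFGS-B", bounds=[(0.0, 1.0)] * (K * M),
            options={"maxiter": max_iter},
        )
        any_converged |= bool(res.success)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.reshape(K, M))
    if not any_converged:
        import warnings
        warnings.warn("L-BFGS-B did not report convergence in any restart; "
                      "returning the best iterate", RuntimeWarning, stacklevel=2)
    value, A = best
    return np.clip(A, 0.0, 1.0), value


def distance_residual_rms(A: np.ndarray, D) -> float:
    """RMS of (||a_k - a_k'|| - D[k,k']) over unordered pairs k < k'."""
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=np.float64)
    _, resid = _pair_residuals(np.asarray(A, dtype=np.float64), Dv)
    iu = np.triu_indices(Dv.shape[0], k=1)
    return float(np.sqrt((resid[iu] ** 2).mean()))


class AttributeEmbedding(BaseEstimator):
    """Category-attribute matrix estimator in the scikit-learn idiom.

    ``fit(D)`` takes a K x K perceptual distance matrix (array or
    :class:`~medmat.distance.DistanceMatrix`) and exposes the optimized
    matrix as ``embedding_`` with its objective value.

    Parameters
    ----------
    n_attributes : M, the number of attributes to discover.
    gamma : weight of the KL pull toward the Beta target.
    bandwidth : Gaussian KDE bandwidth h.
    n_grid : number of KL evaluation points inside (0, 1).
    restarts : random restarts of L-BFGS-B; the best optimum is kept.
    beta_a, beta_b : Beta target parameters.
    random_state : seed for the restart initializations.
    """

    def __init__(self, n_attributes: int = 4, gamma: float = 1.0, bandwidth: float = 0.1,
                 n_grid: int = 101, restarts: int = 5, beta_a: float = 0.5,
                 beta_b: float = 0.5, max_iter: int = 500, random_state: int = 0):
        self.n_attributes = n_attributes
        self.gamma = gamma
        self.bandwidth = bandwidth
        self.n_grid = n_grid
        self.restarts = restarts
        self.beta_a = beta_a
        self.beta_b = beta_b
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        grid = default_grid(self.n_grid)
        target = BetaTarget(self.beta_a, self.beta_b)
        A, value = optimize_A(X, self.n_attributes, self.gamma, seed=self.random_state,
                              restarts=self.restarts, h=self.bandwidth, grid=grid,
                              target=target, max_iter=self.max_iter)
        self.embedding_ = A
        self.objective_value_ = value
        self.distance_residual_rms_ = distance_residual_rms(A, X)
        Dv = X.values if isinstance(X, DistanceMatrix) else np.asarray(X)
        self.kl_term_ = (attribute_objective(A, Dv, self.gamma, target, grid, self.bandwidth)
                         - attribute_objective(A, Dv, 0.0)) / self.gamma if self.gamma else float("nan")
        return self

    def transform(self, X=None):
        """Rows of the fitted matrix: one attribute vector per category."""
        return self.embedding_
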