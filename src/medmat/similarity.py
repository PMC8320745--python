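"""Siamese similarity network over material patches (the distance-matrix CNN).

A shared-weight convolutional encoder embeds two 32x32 patches; the
comparison head takes the absolute elementwise difference of the two
embeddings through two fully connected layers and a sigmoid, yielding
``yhat`` in (0, 1) — 0 meaning *same material category*, 1 meaning
*different*.  The absolute-difference head makes the prediction exactly
symmetric in the pair order.  Weight sharing is structural: both branches
run the same encoder object.

Training minimizes binary cross-entropy over pair decisions under a
best-validation-checkpoint regimen: after every epoch the validation loss is
measured, and whenever it reaches a new minimum the weights are snapshotted
*together with* the perceptual distance matrix computed from the validation
decisions at that epoch.  The saved matrix is therefore always the one the
best checkpoint produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .distance import (DecisionLog, DistanceMatrix, aggregate_decisions,
                       build_distance_matrix, build_profile_distance_matrix)
from .errors import ConfigurationError

__all__ = ["ComparisonSample", "SiameseNet", "build_comparison_set", "pair_forward",
           "dcnn_loss", "SiameseSimilarityModel", "train_dcnn", "pairwise_accuracy_matrix"]

_EPS = 1e-7


@dataclass(frozen=True)
class ComparisonSample:
    """One reference patch index plus K comparison indices, one per class.

    Exactly one comparison shares the reference's class (label 0); the
    comparison classes are a permutation of all K classes in shuffled order.
    """

    reference: int
    reference_class: int
    comparisons: tuple[int, ...]
    comparison_classes: tuple[int, ...]
    labels: tuple[int, ...]


def build_comparison_set(y: np.ndarray, n_samples: int, seed: int,
                         n_classes: int | None = None) -> list[ComparisonSample]:
    """Draw comparison samples with reference classes balanced across samples.

    ``y`` are integer class labels of the patch pool.  Every class needs at
    least two patches so a same-class comparison can differ from the
    reference patch.
    """
    y = np.asarray(y)
    k = int(n_classes if n_classes is not None else y.max() + 1)
    pools = [np.flatnonzero(y == c) for c in range(k)]
    for c, pool in enumerate(pools):
        if pool.size < 2:
            raise ConfigurationError(f"class {c} has {pool.size} patches; need >= 2")
    rng = np.random.default_rng(seed)
    samples: list[ComparisonSample] = []
    for i in range(n_samples):
        ref_class = i % k          # balanced reference classes
        ref = int(rng.choice(pools[ref_class]))
        comp_classes = rng.permutation(k)
        comps, labels = [], []
        for c in comp_classes:
            if c == ref_class:
                choices = pools[c][pools[c] != ref]
                comps.append(int(rng.choice(choices)))
                labels.append(0)
            else:
                comps.append(int(rng.choice(pools[c])))
                labels.append(1)
        samples.append(ComparisonSample(ref, ref_class, tuple(comps),
                                        tuple(int(c) for c in comp_classes), tuple(labels)))
    return samples


def _pairs_from_samples(samples: list[ComparisonSample]) -> np.ndarray:
    """Flatten to rows (ref idx, cmp idx, label, ref class, cmp class)."""
    rows = [(s.reference, c, lab, s.reference_class, cc)
            for s in samples for c, cc, lab in zip(s.comparisons, s.comparison_classes, s.labels)]
    return np.asarray(rows, dtype=np.int64)


class SiameseNet(nn.Module):
    """Shared-weight encoder + absolute-difference comparison head."""

    def __init__(self, backbone: str, rng: np.random.Generator, head_width: int = 32):
        self.encoder = nn.build_backbone(backbone, rng)
        f = self.encoder.feature_dim
        self.fc1 = nn.Linear(f, head_width, rng)
        self.fc2 = nn.Linear(head_width, 1, rng)

    def embed(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        t = x if isinstance(x, nn.Tensor) else nn.Tensor(x)
        if t.ndim == 3:
            t = t.reshape(t.shape[0], 1, *t.shape[1:])
        feat, _ = self.encoder(t)
        return feat

    def __call__(self, ref, cmp) -> nn.Tensor:
        e1, e2 = self.embed(ref), self.embed(cmp)
        diff = (e1 - e2).abs()
        return self.fc2(self.fc1(diff).relu()).sigmoid().reshape(-1)


def pair_forward(model: SiameseNet, ref: np.ndarray, cmp: np.ndarray) -> np.ndarray:
    """Similarity probability yhat in (0, 1) for one pair or a batch of pairs.

    The decision is *different* (1) when yhat >= 0.5.
    """
    ref, cmp = np.asarray(ref, dtype=np.float64), np.asarray(cmp, dtype=np.float64)
    single = ref.ndim == 2
    if single:
        ref, cmp = ref[None], cmp[None]
    if ref.shape != cmp.shape:
        raise ConfigurationError(f"pair shape mismatch: {ref.shape} vs {cmp.shape}")
    out = model(ref, cmp).data
    return float(out[0]) if single else out


def dcnn_loss(yhat, y) -> float:
    """Mean binary cross-entropy; predictions clamped to [eps, 1-eps] first."""
    yhat = np.clip(np.asarray(yhat, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    return float(-(y * np.log(yhat) + (1 - y) * np.log(1 - yhat)).mean())


def _loss_tensor(yhat: nn.Tensor, y: np.ndarray) -> nn.Tensor:
    yc = yhat.clamp(_EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    return -(nn.Tensor(y) * yc.log() + nn.Tensor(1.0 - y) * (1.0 - yc).log()).mean()


class SiameseSimilarityModel(BaseEstimator):
    """Trainable Siamese pair classifier in the scikit-learn idiom.

    ``fit(X, y, X_val=..., y_val=...)`` trains on patches ``X`` of shape
    (n, patch, patch) with integer category labels ``y``.  Fitted
    attributes: ``net_`` (the network at the best validation checkpoint),
    ``best_val_loss_``, ``best_epoch_``, ``distance_matrix_`` (the scalar
    perceptual distance matrix from the best epoch's validation decisions),
    ``profile_distance_matrix_`` (the per-reference-class profile variant
    from the same decisions), ``decision_log_`` (those decisions), and
    ``history_`` (per-epoch train/validation loss and decision accuracy).

    Defaults follow the published training recipe: 15 epochs, batches of 50
    pairs, Adam at learning rate 1e-3.
    """

    def __init__(self, backbone: str = "tiny", epochs: int = 15, batch_size: int = 50,
                 lr: float = 1e-3, n_train_samples: int = 300, n_val_samples: int = 100,
                 head_width: int = 32, random_state: int = 0):
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.n_train_samples = n_train_samples
        self.n_val_samples = n_val_samples
        self.head_width = head_width
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _epoch_pass(self, X, pairs, optimizer, rng) -> float:
        """One training epoch over shuffled pair batches; returns mean loss."""
        order = rng.permutation(len(pairs))
        total, count = 0.0, 0
        for start in range(0, len(order), self.batch_size):
            rows = pairs[order[start:start + self.batch_size]]
            yhat = self.net_(X[rows[:, 0]], X[rows[:, 1]])
            loss = _loss_tensor(yhat, rows[:, 2])
            self.net_.zero_grad()
            loss.backward()
            optimizer.step()
            total += float(loss.data) * len(rows)
            count += len(rows)
        return total / count

    def _evaluate_pairs(self, X, pairs, batch: int = 256) -> tuple[float, np.ndarray]:
        """Validation loss and yhat for every pair, without building a graph."""
        preds = np.empty(len(pairs))
        for start in range(0, len(pairs), batch):
            rows = pairs[start:start + batch]
            preds[start:start + batch] = pair_forward(self.net_, X[rows[:, 0]], X[rows[:, 1]])
        return dcnn_loss(preds, pairs[:, 2]), preds

    @staticmethod
    def _decision_matrix(pairs: np.ndarray, preds: np.ndarray, k: int,
                         names: tuple[str, ...], provenance: str) -> tuple[DecisionLog, DistanceMatrix]:
        log = DecisionLog(n_categories=k)
        decisions = (preds >= 0.5).astype(int)
        for row, s in zip(pairs, decisions):
            log.add(row[3], row[4], s)
        return log, build_distance_matrix(aggregate_decisions(log), names, provenance)

    # -- estimator api -------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None, category_names: tuple[str, ...] = ()):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X_val is None or y_val is None:
            raise ConfigurationError("a disjoint validation set (X_val, y_val) is required "
                                     "for the best-checkpoint regimen")
        X_val = np.asarray(X_val, dtype=np.float64)
        y_val = np.asarray(y_val, dtype=np.int64)
        k = int(max(y.max(), y_val.max()) + 1)
        self.classes_ = np.arange(k)
        names = tuple(category_names) or tuple(f"category_{i}" for i in range(k))

        seed = np.random.SeedSequence([int(self.random_state), 0])
        init_rng, shuffle_rng = [np.random.default_rng(s) for s in seed.spawn(2)]
        self.net_ = SiameseNet(self.backbone, init_rng, self.head_width)
        train_pairs = _pairs_from_samples(
            build_comparison_set(y, self.n_train_samples, int(self.random_state) + 1, k))
        val_pairs = _pairs_from_samples(
            build_comparison_set(y_val, self.n_val_samples, int(self.random_state) + 2, k))

        optimizer = nn.Adam(self.net_.parameters(), lr=self.lr)
        self.best_val_loss_ = np.inf
        self.history_ = []
        best_state = None
        for epoch in range(self.epochs):
            train_loss = self._epoch_pass(X, train_pairs, optimizer, shuffle_rng)
            val_loss, preds = self._evaluate_pairs(X_val, val_pairs)
            val_acc = float(((preds >= 0.5).astype(int) == val_pairs[:, 2]).mean())
            if not np.isfinite(train_loss) or not np.isfinite(val_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: train={train_loss}, val={val_loss}")
            self.history_.append({"epoch": epoch, "train_loss": train_loss,
                                  "val_loss": val_loss, "val_acc": val_acc})
            if val_loss < self.best_val_loss_:
                self.best_val_loss_ = val_loss
                self.best_epoch_ = epoch
                best_state = self.net_.state_dict()
                self.decision_log_, self.distance_matrix_ = self._decision_matrix(
                    val_pairs, preds, k, names, provenance=f"epoch={epoch}")
                self.profile_distance_matrix_ = build_profile_distance_matrix(
                    self.decision_log_, names, provenance=f"epoch={epoch}")
        self.net_.load_state_dict(best_state)
        return self

    def predict_proba(self, X_ref, X_cmp) -> np.ndarray:
        """yhat in (0, 1) per pair: probability the pair is of different categories."""
        return np.atleast_1d(pair_forward(self.net_, np.asarray(X_ref), np.asarray(X_cmp)))

    def predict(self, X_ref, X_cmp) -> np.ndarray:
        """Binary decisions: 1 = different categories, 0 = same."""
        return (self.predict_proba(X_ref, X_cmp) >= 0.5).astype(int)


def train_dcnn(ds_train, ds_val, epochs: int = 15, batch_size: int = 50, lr: float = 1e-3,
               seed: int = 0, **kwargs) -> SiameseSimilarityModel:
    """Thin wrapper: fit a :class:`SiameseSimilarityModel` on two patch datasets."""
    X, y = ds_train.arrays()
    Xv, yv = ds_val.arrays()
    est = SiameseSimilarityModel(epochs=epochs, batch_size=batch_size, lr=lr,
                                 random_state=seed, **kwargs)
    return est.fit(X, y, X_val=Xv, y_val=yv, category_names=ds_train.category_names)


def pairwise_accuracy_matrix(model: SiameseSimilarityModel, X, y,
                             n_samples: int = 200, seed: int = 0) -> np.ndarray:
    """Decision accuracy per (reference class, comparison class) cell.

    Entry (i, j) is the fraction of correct same/different decisions among
    test pairs with reference class i and comparison class j; cells with no
    pairs are reported as NaN (missing), not zero.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    k = int(y.max() + 1)
    pairs = _pairs_from_samples(build_comparison_set(y, n_samples, seed, k))
    preds = np.empty(len(pairs))
    for start in range(0, len(pairs), 256):
        rows = pairs[start:start + 256]
        preds[start:start + 256] = pair_forward(model.net_, X[rows[:, 0]], X[rows[:, 1]])
    decisions = (preds >= 0.5).astype(int)
    correct = np.zeros((k, k))
    totals = np.zeros((k, k))
    for row, d in zip(pairs, decisions):
        i, j = row[3], row[4]
        totals[i, j] += 1
        correct[i, j] += int(d == row[2])
    with np.errstate(invalid="ignore"):
        acc = np.where(totals > 0, correct / np.maximum(totals, 1), np.nan)
    return acc
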