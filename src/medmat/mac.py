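"""Material attribute-category classifier (MAC) network and its three-term loss.

The network predicts, for each 32x32 patch, both a K-way material category
and an M-vector of attribute probabilities.  A convolutional backbone feeds

* a category head — two fully connected layers (512 then 2048 wide by
  default, as in the reference architecture; a flag swaps the order) ending
  in K logits, and
* one auxiliary classifier per backbone stage response (plus the stem's
  pooled response), each a two-layer *clipped-linear* map
  ``h(W2 h(W1 x + b1) + b2)`` with ``h`` clamping to [0, 1], producing a
  stage-wise M-vector; a combiner of the same clipped-linear form merges
  the concatenated stage predictions into the final attribute vector.

Training minimizes three terms: the negative log-likelihood of the category
predictions, a ``gamma1``-weighted KL divergence from a Beta(0.5, 0.5)
target to a Gaussian KDE of the batch's attribute predictions, and a
``gamma2``-weighted squared error between each category's row of the fixed
attribute matrix ``A`` and the mean attribute prediction over that
category's samples in the batch.  The learning rate divides by 10 after any
epoch in which validation loss rose, and the checkpoint with the lowest
validation loss is kept.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .attributes import BetaTarget, default_grid
from .errors import ConfigurationError

__all__ = ["clipped_linear", "AuxHead", "MacNet", "mac_loss", "MaterialAttributeClassifier",
           "train_maccnn", "evaluate_categories"]

_EPS = 1e-7


def clipped_linear(x):
    """Elementwise clamp to [0, 1]: 0 below, identity inside, 1 above."""
    if isinstance(x, nn.Tensor):
        return x.clip01()
    return np.clip(np.asarray(x, dtype=np.float64), 0.0, 1.0)


class AuxHead(nn.Module):
    """Two-layer clipped-linear map: f(x) = h(W2 h(W1 x + b1) + b2).

    Hidden biases start at 0.5 and weights use a reduced init gain so units
    begin inside the (0, 1) band where the clipped-linear activation passes
    gradient; units pushed outside the band receive none and can die.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, hidden: int = 64):
        self.fc1 = nn.Linear(n_in, hidden, rng, bias_init=0.5, gain=0.35)
        self.fc2 = nn.Linear(hidden, n_out, rng, bias_init=0.5, gain=0.35)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc2(self.fc1(x).clip01()).clip01()


class MacNet(nn.Module):
    """Backbone + category head + per-stage auxiliary attribute classifiers."""

    def __init__(self, n_categories: int, n_attributes: int, backbone: str,
                 rng: np.random.Generator, head_widths: tuple[int, int] = (512, 2048),
                 aux_hidden: int = 64):
        self.backbone = nn.build_backbone(backbone, rng)
        f = self.backbone.feature_dim
        w1, w2 = head_widths
        self.head1 = nn.Linear(f, w1, rng)
        self.head2 = nn.Linear(w1, w2, rng)
        self.head_out = nn.Linear(w2, n_categories, rng)
        self.aux = [AuxHead(dim, n_attributes, rng, aux_hidden)
                    for dim in self.backbone.stage_dims]
        self.combiner = AuxHead(len(self.aux) * n_attributes, n_attributes, rng, aux_hidden)
        self.n_categories = n_categories
        self.n_attributes = n_attributes

    def __call__(self, x) -> tuple[nn.Tensor, nn.Tensor]:
        """Returns (category logits (N, K), attribute probabilities (N, M))."""
        t = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=np.float64))
        if t.ndim == 2:
            t = t.reshape(1, 1, *t.shape)
        elif t.ndim == 3:
            t = t.reshape(t.shape[0], 1, *t.shape[1:])
        feat, stages = self.backbone(t)
        logits = self.head_out(self.head2(self.head1(feat).relu()).relu())
        stage_preds = [aux(s) for aux, s in zip(self.aux, stages)]
        attrs = self.combiner(nn.concatenate(stage_preds, axis=1))
        return logits, attrs


def _kl_tensor(attrs: nn.Tensor, target: BetaTarget, grid: np.ndarray, h: float) -> nn.Tensor:
    """KL(beta || KDE of the batch's attribute predictions), on the grid."""
    entries = attrs.reshape(attrs.shape[0] * attrs.shape[1], 1)
    n = entries.shape[0]
    z = (entries - nn.Tensor(grid[None, :])) * (1.0 / h)
    q = (z * z * -0.5).exp().sum(axis=0) * (1.0 / (n * h * np.sqrt(2 * np.pi)))
    beta_p = target.density(grid)
    log_q = q.clamp(1e-12, np.inf).log()
    return (nn.Tensor(beta_p) * (nn.Tensor(np.log(beta_p)) - log_q)).sum()


def mac_loss(logits, attrs, y_onehot: np.ndarray, A: np.ndarray | None = None,
             gamma1: float = 1e-2, gamma2: float = 1.0,
             target: BetaTarget | None = None, grid: np.ndarray | None = None,
             h: float = 0.1) -> nn.Tensor:
    """Three-term training loss for a batch.

    ``logits`` (N, K) category scores (softmax is applied inside the NLL
    term), ``attrs`` (N, M) attribute predictions, ``y_onehot`` (N, K) true
    one-hot labels.  The category term is averaged over the batch: the
    attribute terms are per-category means whose magnitude does not grow
    with the batch, so averaging keeps the three terms' relative weights
    independent of batch size (a summed category term would drown the
    attribute terms at realistic set sizes).  Categories with no samples in
    the batch contribute nothing to the gamma2 term.  Returns an autodiff
    scalar; use ``float(result.data)`` for the value.
    """
    y_onehot = np.asarray(y_onehot, dtype=np.float64)
    if y_onehot.ndim != 2 or y_onehot.shape[0] == 0:
        raise ConfigurationError("y_onehot must be a nonempty (N, K) one-hot array")
    if not isinstance(logits, nn.Tensor):
        logits = nn.Tensor(np.asarray(logits, dtype=np.float64))
    if not isinstance(attrs, nn.Tensor):
        attrs = nn.Tensor(np.asarray(attrs, dtype=np.float64))
    log_p = nn.log_softmax(logits).clamp(np.log(_EPS), np.inf)
    loss = -(nn.Tensor(y_onehot) * log_p).sum() * (1.0 / y_onehot.shape[0])
    if gamma1 != 0.0:
        target = target or BetaTarget()
        grid = default_grid() if grid is None else np.asarray(grid)
        loss = loss + gamma1 * _kl_tensor(attrs, target, grid, h)
    if gamma2 != 0.0:
        if A is None:
            raise ConfigurationError("gamma2 > 0 requires the attribute matrix A")
        A = np.asarray(A, dtype=np.float64)
        counts = y_onehot.sum(axis=0)                       # samples per category
        present = counts > 0
        weights = y_onehot / np.maximum(counts, 1.0)        # (N, K) mean-pooling weights
        means = nn.Tensor(weights.T) @ attrs                # (K, M) per-category means
        diff = (nn.Tensor(A) - means) * nn.Tensor(present.astype(float)[:, None])
        loss = loss + gamma2 * (diff * diff).sum()
    return loss


class MaterialAttributeClassifier(BaseEstimator, ClassifierMixin):
    """Joint category + attribute patch classifier in the scikit-learn idiom.

    ``fit(X, y, A=...)`` trains on (n, patch, patch) patches with integer
    category labels against a fixed K x M attribute matrix ``A``.  A
    disjoint validation set drives the best-checkpoint rule and the
    divide-by-10 learning-rate schedule.  Defaults follow the published
    recipe: 15 epochs, batch 50, initial learning rate 1e-4, gamma1 = 1e-2,
    gamma2 = 1.

    Fitted attributes include ``net_``, ``best_val_loss_``, ``best_epoch_``,
    ``history_`` (with the learning rate in force at each epoch), and
    ``attribute_matrix_``.
    """

    def __init__(self, backbone: str = "tiny", epochs: int = 15, batch_size: int = 50,
                 lr: float = 1e-4, gamma1: float = 1e-2, gamma2: float = 1.0,
                 bandwidth: float = 0.1, n_grid: int = 101, beta_a: float = 0.5,
                 beta_b: float = 0.5, head_widths: tuple[int, int] = (512, 2048),
                 swap_head: bool = False, aux_hidden: int = 64, random_state: int = 0):
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.gamma1 = gamma1
        self.gamma2 = gamma2
        self.bandwidth = bandwidth
        self.n_grid = n_grid
        self.beta_a = beta_a
        self.beta_b = beta_b
        self.head_widths = head_widths
        self.swap_head = swap_head
        self.aux_hidden = aux_hidden
        self.random_state = random_state

    def _batch_loss(self, X_rows, y1h_rows, A) -> nn.Tensor:
        logits, attrs = self.net_(X_rows)
        return mac_loss(logits, attrs, y1h_rows, A, self.gamma1, self.gamma2,
                        self._target, self._grid, self.bandwidth)

    def _dataset_loss(self, X, y1h, A, batch: int = 200) -> float:
        total = 0.0
        for start in range(0, len(X), batch):
            loss = self._batch_loss(X[start:start + batch], y1h[start:start + batch], A)
            total += float(loss.data)
        return total / len(X)

    def fit(self, X, y, A=None, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X_val is None or y_val is None:
            raise ConfigurationError("a disjoint validation set (X_val, y_val) is required")
        X_val = np.asarray(X_val, dtype=np.float64)
        y_val = np.asarray(y_val, dtype=np.int64)
        k = int(max(y.max(), y_val.max()) + 1)
        self.classes_ = np.arange(k)
        if A is None:
            if self.gamma2 != 0.0:
                raise ConfigurationError("pass the fixed attribute matrix A, or set gamma2=0")
            m = 2
        else:
            A = np.asarray(A, dtype=np.float64)
            if A.shape[0] != k:
                raise ConfigurationError(f"A has {A.shape[0]} rows but there are {k} categories")
            m = A.shape[1]
        self.attribute_matrix_ = A
        self._target = BetaTarget(self.beta_a, self.beta_b)
        self._grid = default_grid(self.n_grid)

        widths = tuple(reversed(self.head_widths)) if self.swap_head else tuple(self.head_widths)
        seed = np.random.SeedSequence([int(self.random_state), 1])
        init_rng, shuffle_rng = [np.random.default_rng(s) for s in seed.spawn(2)]
        self.net_ = MacNet(k, m, self.backbone, init_rng, widths, self.aux_hidden)

        eye = np.eye(k)
        y1h, y1h_val = eye[y], eye[y_val]
        optimizer = nn.Adam(self.net_.parameters(), lr=self.lr)
        self.best_val_loss_ = np.inf
        self.history_ = []
        self.lr_history_ = []
        best_state = None
        prev_val = None
        for epoch in range(self.epochs):
            self.lr_history_.append(optimizer.lr)
            order = shuffle_rng.permutation(len(X))
            total, count = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                rows = order[start:start + self.batch_size]
                loss = self._batch_loss(X[rows], y1h[rows], A)
                self.net_.zero_grad()
                loss.backward()
                optimizer.step()
                total += float(loss.data)
                count += len(rows)
            train_loss = total / count
            val_loss = self._dataset_loss(X_val, y1h_val, A)
            if not np.isfinite(train_loss) or not np.isfinite(val_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: train={train_loss}, val={val_loss}")
            val_acc = float((self.predict(X_val) == y_val).mean())
            self.history_.append({"epoch": epoch, "lr": self.lr_history_[-1],
                                  "train_loss": train_loss, "val_loss": val_loss,
                                  "val_acc": val_acc})
            if val_loss < self.best_val_loss_:
                self.best_val_loss_ = val_loss
                self.best_epoch_ = epoch
                best_state = self.net_.state_dict()
            if prev_val is not None and val_loss > prev_val:
                optimizer.lr /= 10.0      # decay after an epoch where val loss rose
            prev_val = val_loss
        self.net_.load_state_dict(best_state)
        return self

    # -- prediction --------------------------------------------------------
    def _forward_arrays(self, X, batch: int = 256) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 2
        if single:
            X = X[None]
        logits = np.empty((len(X), len(self.classes_)))
        attrs = np.empty((len(X), self.net_.n_attributes))
        for start in range(0, len(X), batch):
            lg, at = self.net_(X[start:start + batch])
            logits[start:start + batch] = lg.data
            attrs[start:start + batch] = at.data
        return logits, attrs

    def predict(self, X) -> np.ndarray:
        logits, _ = self._forward_arrays(X)
        return logits.argmax(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        logits, _ = self._forward_arrays(X)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_attributes(self, X) -> np.ndarray:
        """M attribute probabilities in [0, 1] per patch."""
        _, attrs = self._forward_arrays(X)
        return attrs


def train_maccnn(ds_train, ds_val, A, epochs: int = 15, batch_size: int = 50,
                 lr: float = 1e-4, gamma1: float = 1e-2, gamma2: float = 1.0,
                 seed: int = 0, **kwargs) -> MaterialAttributeClassifier:
    """Thin wrapper: fit a :class:`MaterialAttributeClassifier` on patch datasets."""
    X, y = ds_train.arrays()
    Xv, yv = ds_val.arrays()
    est = MaterialAttributeClassifier(epochs=epochs, batch_size=batch_size, lr=lr,
                                      gamma1=gamma1, gamma2=gamma2, random_state=seed,
                                      **kwargs)
    return est.fit(X, y, A=A, X_val=Xv, y_val=yv)


def evaluate_categories(model: MaterialAttributeClassifier, X, y) -> tuple[float, np.ndarray]:
    """Test accuracy and K x K confusion matrix (rows = true category)."""
    y = np.asarray(y, dtype=np.int64)
    if len(y) == 0:
        raise ConfigurationError("empty test set")
    pred = model.predict(np.asarray(X, dtype=np.float64))
    k = len(model.classes_)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    return float((pred == y).mean()), confusion
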