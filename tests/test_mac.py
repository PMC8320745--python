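"""Category+attribute network: clipped-linear head, three-term loss, training contracts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from medmat import nn
from medmat.attributes import default_grid, kde_density
from medmat.errors import ConfigurationError
from medmat.mac import (MacNet, MaterialAttributeClassifier, clipped_linear,
                        evaluate_categories, mac_loss)


class TestClippedLinear:
    def test_piecewise_values(self):
        assert clipped_linear(-1.0) == 0.0
        assert clipped_linear(0.3) == pytest.approx(0.3)
        assert clipped_linear(2.0) == 1.0

    def test_idempotent(self, rng):
        x = rng.normal(scale=3, size=100)
        np.testing.assert_array_equal(clipped_linear(clipped_linear(x)), clipped_linear(x))

    def test_elementwise_on_vectors(self):
        np.testing.assert_allclose(clipped_linear(np.array([-0.5, 0.25, 1.5])),
                                   [0.0, 0.25, 1.0])


def _hand_nll(logits: np.ndarray, y_onehot: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-(y_onehot * log_p).sum() / len(y_onehot))


class TestMacLoss:
    def test_bare_nll_decomposition(self, rng):
        logits = rng.normal(size=(6, 4))
        attrs = rng.random((6, 3))
        y1h = np.eye(4)[rng.integers(0, 4, 6)]
        loss = mac_loss(logits, attrs, y1h, A=None, gamma1=0.0, gamma2=0.0)
        assert float(loss.data) == pytest.approx(_hand_nll(logits, y1h), abs=1e-10)

    def test_confident_correct_predictions_cost_nothing(self):
        y1h = np.eye(3)[[0, 1, 2]]
        logits = 50.0 * y1h
        loss = mac_loss(logits, np.full((3, 2), 0.5), y1h, gamma1=0.0, gamma2=0.0)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_consistency_term_vanishes_when_means_match_rows(self, rng):
        A = rng.random((2, 3))
        y1h = np.eye(2)[[0, 0, 1, 1]]
        attrs = np.concatenate([np.tile(A[0], (2, 1)), np.tile(A[1], (2, 1))])
        logits = 50.0 * y1h
        loss = mac_loss(logits, attrs, y1h, A=A, gamma1=0.0, gamma2=5.0)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_single_sample_batch_matches_hand_evaluated_terms(self):
        logits = np.array([[2.0, -1.0, 0.5]])
        attrs = np.array([[0.3, 0.7]])
        y1h = np.array([[0.0, 1.0, 0.0]])
        A = np.array([[0.1, 0.9], [0.6, 0.2], [0.4, 0.4]])
        gamma1, gamma2, h = 0.05, 2.0, 0.1
        grid = default_grid(31)
        nll = _hand_nll(logits, y1h)
        beta_p = stats.beta.pdf(grid, 0.5, 0.5)
        q = np.maximum(kde_density(grid, attrs, h), 1e-12)
        kl = (beta_p * (np.log(beta_p) - np.log(q))).sum()
        consistency = ((A[1] - attrs[0]) ** 2).sum()     # only category 1 in batch
        expected = nll + gamma1 * kl + gamma2 * consistency
        loss = mac_loss(logits, attrs, y1h, A=A, gamma1=gamma1, gamma2=gamma2,
                        grid=grid, h=h)
        assert float(loss.data) == pytest.approx(expected, rel=1e-10)

    def test_empty_batch_rejected(self):
        with pytest.raises(ConfigurationError):
            mac_loss(np.empty((0, 2)), np.empty((0, 2)), np.empty((0, 2)))

    def test_consistency_weight_without_matrix_rejected(self, rng):
        y1h = np.eye(2)[[0, 1]]
        with pytest.raises(ConfigurationError, match="attribute matrix"):
            mac_loss(rng.normal(size=(2, 2)), rng.random((2, 2)), y1h,
                     A=None, gamma1=0.0, gamma2=1.0)


class TestForward:
    @pytest.fixture
    def net(self, rng):
        return MacNet(n_categories=3, n_attributes=4, backbone="tiny", rng=rng)

    def test_attributes_lie_in_unit_interval(self, net, rng):
        _, attrs = net(rng.random((5, 32, 32)))
        assert attrs.data.min() >= 0.0 and attrs.data.max() <= 1.0
        assert attrs.shape == (5, 4)

    def test_double_call_is_identical(self, net, rng):
        x = rng.random((2, 32, 32))
        l1, a1 = net(x)
        l2, a2 = net(x)
        np.testing.assert_array_equal(l1.data, l2.data)
        np.testing.assert_array_equal(a1.data, a2.data)

    def test_aux_classifier_count_is_stages_plus_one(self, net):
        assert len(net.aux) == len(net.backbone.stage_dims)
        assert len(net.aux) == 5     # tiny backbone: stem pooling + 4 blocks


def _fit_kwargs(X, y, A):
    cut = int(0.75 * len(y))
    return dict(X=X[:cut], y=y[:cut], A=A, X_val=X[cut:], y_val=y[cut:])


class TestTrainingContracts:
    @pytest.fixture
    def small_data(self, rng):
        X = rng.random((48, 32, 32))
        y = np.tile(np.arange(3), 16)
        A = rng.random((3, 2))
        return X, y, A

    def test_scheduler_divides_lr_by_ten_after_val_loss_rise(self, small_data, monkeypatch):
        X, y, A = small_data
        est = MaterialAttributeClassifier(epochs=4, batch_size=12, random_state=0)
        scripted = iter([1.0, 2.0, 0.5, 0.6])
        monkeypatch.setattr(est, "_dataset_loss", lambda *a, **k: next(scripted))
        est.fit(**_fit_kwargs(X, y, A))
        lr0 = est.lr
        assert est.lr_history_ == [lr0, lr0, lr0 / 10, lr0 / 10]

    def test_checkpoint_is_epoch_with_minimum_val_loss(self, small_data, monkeypatch):
        X, y, A = small_data
        est = MaterialAttributeClassifier(epochs=4, batch_size=12, random_state=0)
        scripted = iter([1.0, 0.4, 0.9, 0.8])
        monkeypatch.setattr(est, "_dataset_loss", lambda *a, **k: next(scripted))
        est.fit(**_fit_kwargs(X, y, A))
        assert est.best_epoch_ == 1
        assert est.best_val_loss_ == 0.4

    def test_same_seed_identical_history(self, small_data):
        X, y, A = small_data
        runs = []
        for _ in range(2):
            est = MaterialAttributeClassifier(epochs=2, batch_size=12, random_state=3)
            est.fit(**_fit_kwargs(X, y, A))
            runs.append(est.history_)
        assert runs[0] == runs[1]

    def test_mismatched_attribute_matrix_rejected(self, small_data):
        X, y, _ = small_data
        bad_A = np.random.default_rng(0).random((5, 2))
        est = MaterialAttributeClassifier(epochs=1)
        with pytest.raises(ConfigurationError, match="rows"):
            est.fit(**_fit_kwargs(X, y, bad_A))


class _StubPredictor:
    def __init__(self, predictions, k):
        self._p = np.asarray(predictions)
        self.classes_ = np.arange(k)

    def predict(self, X):
        return self._p[:len(X)]


class TestEvaluateCategories:
    def test_perfect_predictions(self):
        y = np.repeat(np.arange(3), 4)
        acc, conf = evaluate_categories(_StubPredictor(y, 3), np.zeros((12, 32, 32)), y)
        assert acc == 1.0
        np.testing.assert_array_equal(conf, np.diag([4, 4, 4]))

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(9)
        n, k = 2000, 4
        y = np.tile(np.arange(k), n // k)
        preds = rng.integers(0, k, n)
        acc, conf = evaluate_categories(_StubPredictor(preds, k), np.zeros((n, 32, 32)), y)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(acc - 0.25) < 3 * se
        assert conf.sum() == n

    def test_empty_test_set_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate_categories(_StubPredictor([], 2), np.zeros((0, 32, 32)), np.array([]))
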