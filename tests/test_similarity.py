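"""Siamese pair classifier: sampling, loss, symmetry, checkpointing."""

from __future__ import annotations

import numpy as np
import pytest

from medmat import nn
from medmat.errors import ConfigurationError
from medmat.similarity import (SiameseNet, SiameseSimilarityModel, build_comparison_set,
                               dcnn_loss, pair_forward, pairwise_accuracy_matrix)


class TestComparisonSet:
    def test_each_sample_covers_every_class_once(self):
        y = np.repeat(np.arange(4), 5)
        samples = build_comparison_set(y, n_samples=10, seed=3)
        assert len(samples) == 10
        for s in samples:
            assert sorted(s.comparison_classes) == [0, 1, 2, 3]
            assert sum(lab == 0 for lab in s.labels) == 1
            same_pos = s.labels.index(0)
            assert s.comparison_classes[same_pos] == s.reference_class
            assert s.comparisons[same_pos] != s.reference

    def test_reference_classes_are_balanced(self):
        y = np.repeat(np.arange(3), 4)
        samples = build_comparison_set(y, n_samples=9, seed=0)
        refs = [s.reference_class for s in samples]
        assert np.bincount(refs, minlength=3).tolist() == [3, 3, 3]

    def test_same_seed_same_pairings(self):
        y = np.repeat(np.arange(2), 3)
        a = build_comparison_set(y, 6, seed=8)
        b = build_comparison_set(y, 6, seed=8)
        assert a == b

    def test_singleton_class_rejected(self):
        y = np.array([0, 0, 1])
        with pytest.raises(ConfigurationError, match="class 1"):
            build_comparison_set(y, 4, seed=0)


class TestPairForward:
    @pytest.fixture
    def net(self, rng):
        return SiameseNet("tiny", rng)

    def test_output_is_probability_and_deterministic(self, net, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        y1 = pair_forward(net, a, b)
        y2 = pair_forward(net, a, b)
        assert 0.0 < y1 < 1.0
        assert y1 == y2

    def test_exactly_symmetric_in_pair_order(self, net, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert pair_forward(net, a, b) == pair_forward(net, b, a)

    def test_shape_mismatch_rejected(self, net, rng):
        with pytest.raises(ConfigurationError):
            pair_forward(net, rng.random((2, 32, 32)), rng.random((3, 32, 32)))


class TestLoss:
    def test_uninformative_prediction_costs_ln_two(self):
        assert dcnn_loss([0.5], [1]) == pytest.approx(np.log(2))

    def test_correct_certain_prediction_costs_nothing(self):
        assert dcnn_loss([1.0], [1]) == pytest.approx(0.0, abs=1e-6)

    def test_batch_mean_hand_value(self):
        assert dcnn_loss([0.9, 0.1], [1, 0]) == pytest.approx(-np.log(0.9), rel=1e-9)

    def test_clamping_keeps_loss_finite(self):
        assert np.isfinite(dcnn_loss([0.0, 1.0], [1, 0]))
        assert dcnn_loss([0.0], [1]) == pytest.approx(-np.log(1e-7))


@pytest.fixture(scope="module")
def fitted(ladder_patch_data):
    X, y = ladder_patch_data
    rng = np.random.default_rng(1)
    idx = rng.permutation(len(y))
    cut = int(0.7 * len(y))
    est = SiameseSimilarityModel(epochs=3, n_train_samples=30, n_val_samples=18,
                                 random_state=4)
    est.fit(X[idx[:cut]], y[idx[:cut]], X_val=X[idx[cut:]], y_val=y[idx[cut:]])
    return est


class TestTraining:
    def test_best_val_loss_is_minimum_over_epochs(self, fitted):
        losses = [h["val_loss"] for h in fitted.history_]
        assert fitted.best_val_loss_ == pytest.approx(min(losses))
        assert fitted.best_epoch_ == int(np.argmin(losses))

    def test_distance_matrix_contracts(self, fitted):
        d = fitted.distance_matrix_.values
        assert d.shape == (3, 3)
        assert (np.diag(d) == 0).all() and d.min() >= 0 and d.max() <= 1
        dp = fitted.profile_distance_matrix_.values
        np.testing.assert_allclose(dp, dp.T)

    def test_missing_validation_set_rejected(self, ladder_patch_data):
        X, y = ladder_patch_data
        with pytest.raises(ConfigurationError, match="validation"):
            SiameseSimilarityModel().fit(X, y)

    def test_same_seed_identical_history(self, ladder_patch_data):
        X, y = ladder_patch_data
        rng = np.random.default_rng(2)
        idx = rng.permutation(len(y))
        cut = int(0.7 * len(y))
        kw = dict(epochs=2, n_train_samples=18, n_val_samples=12, random_state=7)
        runs = []
        for _ in range(2):
            est = SiameseSimilarityModel(**kw)
            est.fit(X[idx[:cut]], y[idx[:cut]], X_val=X[idx[cut:]], y_val=y[idx[cut:]])
            runs.append(est.history_)
        assert runs[0] == runs[1]


class _OracleNet:
    """Stand-in comparison network deciding from patch means.

    Patches are constant-valued with the class encoded in the level, so
    equal means imply the same class; used to test the accuracy-matrix
    bookkeeping with known-perfect decisions.
    """

    def __call__(self, ref, cmp):
        same = np.isclose(ref.mean(axis=(1, 2)), cmp.mean(axis=(1, 2)))
        return nn.Tensor(np.where(same, 0.05, 0.95))


class _CoinFlipNet:
    def __init__(self, seed):
        self.rng = np.random.default_rng(seed)

    def __call__(self, ref, cmp):
        return nn.Tensor(self.rng.choice([0.05, 0.95], size=len(ref)))


def _constant_patch_pool(k=3, per_class=6):
    X = np.stack([np.full((32, 32), (c + 1) / (k + 1))
                  for c in range(k) for _ in range(per_class)])
    y = np.repeat(np.arange(k), per_class)
    return X, y


class TestAccuracyMatrix:
    def test_perfect_decisions_fill_matrix_with_ones(self):
        X, y = _constant_patch_pool()
        model = SiameseSimilarityModel()
        model.net_ = _OracleNet()
        acc = pairwise_accuracy_matrix(model, X, y, n_samples=30, seed=0)
        np.testing.assert_allclose(acc, 1.0)

    def test_coin_flips_hover_near_half(self):
        X, y = _constant_patch_pool(k=2, per_class=10)
        model = SiameseSimilarityModel()
        model.net_ = _CoinFlipNet(seed=5)
        n = 400
        acc = pairwise_accuracy_matrix(model, X, y, n_samples=n, seed=1)
        n_per_cell = n / 2        # K cells per reference class, refs balanced
        se = np.sqrt(0.25 / n_per_cell)
        assert (np.abs(acc - 0.5) < 3 * se + 1e-12).all()

    def test_unseen_class_pair_reported_missing(self):
        X, y = _constant_patch_pool(k=3)
        model = SiameseSimilarityModel()
        model.net_ = _OracleNet()
        acc = pairwise_accuracy_matrix(model, X, y, n_samples=2, seed=0)
        assert np.isnan(acc[2]).all()   # only refs 0 and 1 drawn
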