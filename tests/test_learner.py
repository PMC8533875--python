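"""LSTM weak learner: separability, determinism, gradients, sequence
semantics, and normalization hygiene."""

import dataclasses

import numpy as np
import pytest

from neuroauth.features import FeatureMatrix
from neuroauth.learner import (LabeledSet, LearnerConfig, _backward,
                               _forward, load_learner, numerical_gradient,
                               predict, save_learner, train_learner)
from neuroauth.synth import ValidationError


def toy_matrix(rng, offset, rows=6, frames=12, noise=0.3):
    return FeatureMatrix(P=rng.normal(offset, noise, size=(rows, frames)),
                         row_labels=[], mode="toy")


def toy_set(rng, n_per_class=6, sep=4.0, rows=6, frames=12):
    feats, labels = [], []
    for y in (0, 1):
        for _ in range(n_per_class):
            feats.append(toy_matrix(rng, sep if y else -sep, rows, frames))
            labels.append(y)
    return LabeledSet(features=feats, labels=np.array(labels))


FAST = LearnerConfig(hidden_units=8, epochs=30, batch_size=12,
                     learning_rate=1e-2, seed=1)


class TestTraining:
    def test_separable_classes_reach_perfect_training_accuracy(
            self, separable_set, fast_learner_cfg):
        learner = train_learner(separable_set, fast_learner_cfg)
        correct = [predict(learner, f)[1] == y
                   for f, y in zip(separable_set.features,
                                   separable_set.labels)]
        assert np.mean(correct) == 1.0

    def test_shuffled_labels_give_chance_heldout_accuracy(self):
        """Permutation-null oracle: with labels drawn independently of the
        features, held-out accuracy averages ~0.5."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            feats = [toy_matrix(rng, rng.normal()) for _ in range(24)]
            labels = rng.permutation([0, 1] * 12)
            train = LabeledSet(features=feats[:16], labels=labels[:16])
            cfg = dataclasses.replace(FAST, seed=seed)
            try:
                learner = train_learner(train, cfg)
            except ValidationError:
                continue  # single-class draw
            accs.append(np.mean([predict(learner, f)[1] == y
                                 for f, y in zip(feats[16:], labels[16:])]))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.15)

    def test_same_seed_same_predictions_bitwise(self, separable_set):
        probe = separable_set.features[0]
        p1 = predict(train_learner(separable_set, FAST), probe)
        p2 = predict(train_learner(separable_set, FAST), probe)
        assert p1 == p2  # exact float equality

    def test_single_class_data_rejected(self):
        rng = np.random.default_rng(0)
        data = LabeledSet(features=[toy_matrix(rng, 1.0)] * 4,
                          labels=np.ones(4, dtype=int))
        with pytest.raises(ValidationError, match="both classes"):
            train_learner(data, FAST)

    def test_inconsistent_shapes_rejected(self):
        rng = np.random.default_rng(0)
        data = LabeledSet(
            features=[toy_matrix(rng, 1.0, rows=6),
                      toy_matrix(rng, -1.0, rows=7)],
            labels=np.array([1, 0]))
        with pytest.raises(ValidationError, match="shape"):
            train_learner(data, FAST)


class TestPredict:
    def test_softmax_outputs_sum_to_one(self, separable_set):
        learner = train_learner(separable_set, FAST)
        from neuroauth.learner import _forward
        X = learner.normalize(separable_set.features[0].P)[None]
        p = _forward(learner.params, X)[0]
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p >= 0)

    def test_threshold_convention_accepts_at_threshold(self, separable_set):
        learner = train_learner(separable_set, FAST)
        learner.config = dataclasses.replace(
            learner.config, decision_threshold=0.5)
        p_yes, decision = predict(learner, separable_set.features[-1])
        assert decision == int(p_yes >= 0.5)

    def test_shape_mismatch_rejected(self, separable_set):
        learner = train_learner(separable_set, FAST)
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError, match="shape"):
            predict(learner, toy_matrix(rng, 0.0, rows=3, frames=5))


class TestGradients:
    def test_bptt_matches_numerical_gradient(self):
        """Central-difference oracle over every parameter of a small net."""
        rng = np.random.default_rng(4)
        from neuroauth.learner import _init_params
        params = _init_params(rng, d=3, h=4)
        X = rng.normal(size=(5, 6, 3))
        y = np.array([0, 1, 1, 0, 1])
        p, cache = _forward(params, X, cache=True)
        analytic = _backward(params, X, y, p, cache)
        numeric = numerical_gradient(params, X, y)
        for ga, gn in zip(analytic.flat(), numeric.flat()):
            assert np.allclose(ga, gn, atol=1e-6), np.abs(ga - gn).max()


class TestSequenceSemantics:
    def test_frame_permutation_changes_output(self, separable_set):
        """The LSTM is order-sensitive: permuting the time frames of a
        non-degenerate input changes the predicted probability."""
        rng = np.random.default_rng(9)
        data = toy_set(rng, sep=1.0)
        learner = train_learner(data, FAST)
        fm = data.features[0]
        perm = rng.permutation(fm.P.shape[1])
        shuffled = FeatureMatrix(P=fm.P[:, perm], row_labels=[], mode="toy")
        assert predict(learner, fm)[0] != predict(learner, shuffled)[0]

    def test_consistent_permutation_of_constant_sequences_is_harmless(self):
        """On time-constant inputs an identical train/test frame shuffle
        cannot change training accuracy."""
        rng = np.random.default_rng(10)
        feats, labels = [], []
        for y in (0, 1):
            for _ in range(6):
                col = rng.normal(3.0 if y else -3.0, 0.2, size=(6, 1))
                feats.append(FeatureMatrix(P=np.repeat(col, 12, axis=1),
                                           row_labels=[], mode="toy"))
                labels.append(y)
        data = LabeledSet(features=feats, labels=np.array(labels))

        def train_acc(ds):
            learner = train_learner(ds, FAST)
            return np.mean([predict(learner, f)[1] == y
                            for f, y in zip(ds.features, ds.labels)])

        perm = rng.permutation(12)
        permuted = LabeledSet(
            features=[FeatureMatrix(P=f.P[:, perm], row_labels=[],
                                    mode="toy") for f in feats],
            labels=np.array(labels))
        assert train_acc(data) == train_acc(permuted) == 1.0


class TestNormalization:
    def test_stats_computed_on_training_data_only(self, separable_set):
        learner = train_learner(separable_set, FAST)
        flat = np.concatenate([f.P.T for f in separable_set.features])
        assert np.allclose(learner.norm_mean, flat.mean(axis=0))
        # retraining after observing any "test" data changes nothing
        again = train_learner(separable_set, FAST)
        assert np.array_equal(learner.norm_mean, again.norm_mean)

    def test_none_normalization_is_identity(self, separable_set):
        cfg = dataclasses.replace(FAST, normalization="none")
        learner = train_learner(separable_set, cfg)
        assert np.all(learner.norm_mean == 0) and np.all(learner.norm_std == 1)


class TestSerialization:
    def test_save_load_round_trip(self, separable_set, tmp_path):
        learner = train_learner(separable_set, FAST)
        path = tmp_path / "model.npz"
        save_learner(learner, path)
        back = load_learner(path)
        probe = separable_set.features[3]
        assert predict(back, probe) == predict(learner, probe)
        assert back.config == learner.config
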