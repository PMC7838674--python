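"""Training protocol: split arithmetic, loss closed forms, LR plateau, loop."""

import numpy as np
import pytest

from dms_eeg import (NetworkSpec, TrainConfig, build_network,
                     cross_entropy_loss, lr_trace, reduce_lr_on_plateau,
                     split_train_val, train_model)
from dms_eeg.selfcheck import TOY_SPEC


class TestSplit:
    def test_stated_fractions_280_trials(self):
        y = np.array([0, 1] * 140)
        train, val = split_train_val(y, 0.3, seed=0)
        assert val.size == 84 and train.size == 196
        assert (y[val] == 0).sum() == 42 and (y[val] == 1).sum() == 42

    def test_half_split_of_four(self):
        y = np.array([0, 0, 1, 1])
        train, val = split_train_val(y, 0.5, seed=1)
        assert sorted(np.concatenate([train, val])) == [0, 1, 2, 3]
        assert (y[val] == 0).sum() == 1 and (y[val] == 1).sum() == 1

    def test_same_seed_same_split(self):
        y = np.array([0, 1] * 20)
        assert all(np.array_equal(a, b) for a, b in
                   zip(split_train_val(y, 0.3, 7), split_train_val(y, 0.3, 7)))

    def test_disjoint_and_exhaustive(self):
        y = np.array([0] * 13 + [1] * 9)
        train, val = split_train_val(y, 0.3, seed=2)
        combined = np.sort(np.concatenate([train, val]))
        assert np.array_equal(combined, np.arange(22))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_val(np.array([0, 1, 1, 1]), 0.3, seed=0)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(p, [0, 1]) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_is_ln2(self):
        p = np.full((4, 2), 0.5)
        assert cross_entropy_loss(p, [0, 1, 0, 1]) == pytest.approx(
            np.log(2), abs=1e-12)

    def test_single_row_closed_form(self):
        assert cross_entropy_loss(np.array([[0.9, 0.1]]), [0]) == pytest.approx(
            -np.log(0.9), abs=1e-12)

    def test_zero_probability_clamped_not_infinite(self):
        loss = cross_entropy_loss(np.array([[0.0, 1.0]]), [0])
        assert np.isfinite(loss) and loss == pytest.approx(-np.log(1e-7))

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([[0.9, 0.3]]), [0])


class TestPlateauSchedule:
    CFG = TrainConfig()

    def test_ten_stale_epochs_halve_the_rate(self):
        history = [0.5] + [0.4] * 10
        assert reduce_lr_on_plateau(history, self.CFG) == pytest.approx(1.5e-4)

    def test_rate_clamps_at_floor(self):
        history = [0.5] + [0.4] * 20
        assert reduce_lr_on_plateau(history, self.CFG) == pytest.approx(1e-4)
        history = [0.5] + [0.4] * 50
        assert reduce_lr_on_plateau(history, self.CFG) == pytest.approx(1e-4)

    def test_improvement_resets_counter(self):
        # 9 stale epochs, an improvement, then 9 more stale: no reduction
        history = [0.5] + [0.4] * 9 + [0.6] + [0.5] * 9
        assert reduce_lr_on_plateau(history, self.CFG) == pytest.approx(3e-4)

    def test_trace_non_increasing_and_floored(self, rng):
        accs = rng.uniform(0.4, 0.6, size=60)
        trace = lr_trace(accs, self.CFG)
        assert all(a >= b for a, b in zip(trace, trace[1:]))
        assert min(trace) >= self.CFG.lr_min

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_min=1e-3, lr_init=1e-4)
        with pytest.raises(ValueError):
            TrainConfig(val_fraction=1.5)


class TestTrainModel:
    def _toy_data(self, n=16, seed=0):
        """Linearly separable toy features in the network's input shape."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 15, 21, 2)) * 0.1
        y = np.array([0, 1] * (n // 2))
        X[y == 0, 2:5, :, 0] += 2.0
        X[y == 1, 8:11, :, 0] += 2.0
        return X, y

    def test_zero_epochs_returns_initial_weights(self):
        X, y = self._toy_data()
        model = build_network(TOY_SPEC, seed=0)
        before = model.get_weights()
        model, history = train_model(model, X, y,
                                     TrainConfig(max_epochs=0, seed=0))
        assert history.n_epochs() == 0
        for a, b in zip(before, model.get_weights()):
            assert np.array_equal(a, b)

    def test_loss_decreases_on_separable_data(self):
        X, y = self._toy_data(n=16)
        model = build_network(TOY_SPEC, seed=1)
        _, history = train_model(model, X, y,
                                 TrainConfig(max_epochs=6, seed=1,
                                             val_fraction=0.25))
        assert history.loss[-1] < history.loss[0]

    def test_best_checkpoint_reproduces_recorded_accuracy(self):
        X, y = self._toy_data(n=16)
        model = build_network(TOY_SPEC, seed=2)
        cfg = TrainConfig(max_epochs=5, seed=2, val_fraction=0.25)
        train_idx, val_idx = split_train_val(y, cfg.val_fraction, cfg.seed)
        model, history = train_model(model, X, y, cfg,
                                     split=(train_idx, val_idx))
        preds = model.predict(X[val_idx])
        acc = (preds == y[val_idx]).mean()
        assert acc == pytest.approx(history.best_val_accuracy)

    def test_lr_history_non_increasing(self):
        X, y = self._toy_data(n=12)
        model = build_network(TOY_SPEC, seed=3)
        _, history = train_model(model, X, y,
                                 TrainConfig(max_epochs=8, seed=3,
                                             val_fraction=0.25))
        lrs = history.learning_rate
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert min(lrs) >= 1e-4

    def test_mismatched_labels_rejected(self):
        X, y = self._toy_data(n=8)
        model = build_network(TOY_SPEC, seed=0)
        with pytest.raises(ValueError):
            train_model(model, X, y[:-1], TrainConfig(max_epochs=1))
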