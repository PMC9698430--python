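"""Partitioning, class weighting, early stopping and the grid space."""

import numpy as np
import pytest
from sklearn.utils.class_weight import compute_class_weight

from locomode.networks import NetworkSpec
from locomode.training import (
    EncodedDataset,
    GridSpace,
    TrainConfig,
    class_weights,
    grid_search,
    partition,
    train_model,
)


def _dataset(n=1000, n_classes=4, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([f"A{i}" for i in rng.integers(0, n_classes, n)], dtype=object)
    return EncodedDataset(
        x=rng.normal(size=(n, 2, 10, 50)).astype(np.float32),
        activity=labels,
        level1=labels.copy(),
        phase=np.array([None] * n, dtype=object),
    )


class TestPartition:
    def test_split_sizes_640_160_200(self):
        train, val, inner = partition(_dataset(1000), seed=0)
        assert (train.n, val.n, inner.n) == (640, 200, 160)

    def test_disjoint_and_covering(self):
        ds = _dataset(500)
        # tag windows by a unique value to track identity
        ds.x[:, 0, 0, 0] = np.arange(500)
        train, val, inner = partition(ds, seed=1)
        ids = np.concatenate([
            train.x[:, 0, 0, 0], val.x[:, 0, 0, 0], inner.x[:, 0, 0, 0]
        ]).astype(int)
        assert sorted(ids) == list(range(500))

    def test_stratification_preserves_proportions(self):
        ds = _dataset(1000, n_classes=5, seed=3)
        train, val, inner = partition(ds, seed=2)
        global_frac = {
            c: np.mean(ds.activity == c) for c in np.unique(ds.activity.astype(str))
        }
        for split in (train, val, inner):
            for c, frac in global_frac.items():
                got = np.mean(split.activity == c)
                # proportions within one window of the global share
                assert abs(got * split.n - frac * split.n) <= 1 + frac * 2

    def test_rare_class_kept_in_train_with_warning(self):
        ds = _dataset(200, n_classes=2, seed=4)
        ds.activity[:2] = "RARE"
        ds.level1[:2] = "RARE"
        with pytest.warns(UserWarning, match="RARE"):
            train, val, inner = partition(ds, seed=0)
        assert np.sum(train.activity == "RARE") == 2
        assert np.sum(val.activity == "RARE") == 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            partition(_dataset(0), seed=0)


class TestClassWeights:
    def test_two_class_example(self):
        w = class_weights({"A": 10, "B": 30})
        assert w["A"] == pytest.approx(2.0)
        assert w["B"] == pytest.approx(2 / 3)

    def test_equal_counts_give_unit_weights(self):
        w = class_weights({"A": 7, "B": 7, "C": 7})
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_single_class_weight_one(self):
        assert class_weights({"A": 42}) == {"A": pytest.approx(1.0)}

    def test_zero_count_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero-count"):
            w = class_weights({"A": 10, "B": 0})
        assert "B" not in w

    def test_matches_sklearn_balanced_mode(self):
        counts = {"A": 13, "B": 37, "C": 5}
        y = sum(([c] * n for c, n in counts.items()), [])
        sk = compute_class_weight("balanced", classes=np.array(["A", "B", "C"]), y=y)
        ours = class_weights(counts)
        np.testing.assert_allclose([ours["A"], ours["B"], ours["C"]], sk)


class TestTrainModel:
    def _separable(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        x = 0.5 + 0.05 * rng.normal(size=(n, 2, 10, 50))
        y = rng.integers(0, 2, n)
        x[y == 1, :, :5, :] += 0.3
        return np.clip(x, 0, 1).astype(np.float32), y

    def test_separable_data_reaches_full_accuracy(self):
        # elu: a 4-filter relu conv can die outright on unlucky seeds
        x, y = self._separable()
        spec = NetworkSpec(variant="cnn_lstm", n_classes=2, n_channels=2,
                           conv_filters=(4, 8), recurrent_units=(8, 6), dense_sizes=(6,),
                           activation="elu")
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=50, seed=1)
        model, hist = train_model(spec, cfg, (x[:90], y[:90]), (x[90:], y[90:]), ["a", "b"])
        assert max(hist["val_accuracy"]) == 1.0
        assert hist["stopped_epoch"] + 1 <= 50

    def test_infinite_min_delta_stops_after_patience_plus_one(self):
        x, y = self._separable(60)
        spec = NetworkSpec(variant="cnn", n_classes=2, n_channels=2, conv_filters=(2, 4),
                           dense_sizes=(8,))
        cfg = TrainConfig(max_epochs=100, early_stop_patience=3,
                          early_stop_min_delta=np.inf, seed=2)
        _, hist = train_model(spec, cfg, (x[:40], y[:40]), (x[40:], y[40:]), ["a", "b"])
        assert hist["stopped_epoch"] + 1 == 4  # patience + 1 epochs

    def test_same_seed_reproduces_history(self):
        x, y = self._separable(80)
        spec = NetworkSpec(variant="cnn_gru", n_classes=2, n_channels=2,
                           conv_filters=(3, 6), recurrent_units=(6, 4), dense_sizes=(5,))
        cfg = TrainConfig(learning_rate=5e-4, max_epochs=5, seed=7)
        _, h1 = train_model(spec, cfg, (x[:60], y[:60]), (x[60:], y[60:]), ["a", "b"])
        _, h2 = train_model(spec, cfg, (x[:60], y[:60]), (x[60:], y[60:]), ["a", "b"])
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_early_stopping_restores_best_validation_weights(self):
        from locomode.training import _forward_in_batches
        from locomode.nn import softmax_cross_entropy
        x, y = self._separable(100, seed=5)
        spec = NetworkSpec(variant="cnn", n_classes=2, n_channels=2, conv_filters=(2, 4),
                           dense_sizes=(8,))
        cfg = TrainConfig(learning_rate=2e-3, max_epochs=12, early_stop_patience=3, seed=3)
        model, hist = train_model(spec, cfg, (x[:70], y[:70]), (x[70:], y[70:]), ["a", "b"])
        logits = _forward_in_batches(model.model, x[70:], 64)
        final_loss, _ = softmax_cross_entropy(logits, y[70:])
        assert final_loss <= min(hist["val_loss"]) + 1e-6

    def test_empty_training_set_rejected(self):
        spec = NetworkSpec(variant="cnn", n_classes=2, n_channels=2, conv_filters=(2, 4))
        with pytest.raises(ValueError):
            train_model(spec, TrainConfig(), (np.zeros((0, 2, 10, 50)), np.zeros(0, int)),
                        None, ["a", "b"])


class TestGridSpace:
    def test_default_grid_has_48_points(self):
        points = GridSpace().enumerate()
        assert len(points) == 48 == 3 * 2 * 2 * 2 * 2
        assert len({tuple(sorted(p.items(), key=str)) for p in points}) == 48

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            GridSpace(activations=())

    def test_single_point_grid_returned_as_best(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 2, 10, 50)).astype(np.float32)
        y = rng.integers(0, 2, 60)
        x[y == 1, :, :4, :] += 0.5
        grid = GridSpace(activations=("relu",), learning_rates=(1e-3,),
                         optimizers=("adam",), hidden_profiles=((2, 4, 4, 3, 3),),
                         dropouts=(0.25,))
        base = TrainConfig(max_epochs=2, seed=0)
        best, results = grid_search("cnn_lstm", grid, x, y, ["a", "b"], k=2,
                                    base_config=base)
        assert len(results) == 1
        assert best["activation"] == "relu"
        assert best["n_folds"] == 2

    def test_single_class_dataset_rejected(self):
        x = np.zeros((20, 2, 10, 50), dtype=np.float32)
        y = np.zeros(20, int)
        with pytest.raises(ValueError):
            grid_search("cnn", GridSpace(), x, y, ["a"], k=2)
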