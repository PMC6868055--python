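"""CNN architecture, dataset splitting and training mechanics."""

import numpy as np
import pytest

from kinetoforge import (CNNConfig, SplitSpec, TrainConfig, balance_classes,
                         build_cnn, evaluate, images_to_tensor, predict,
                         split_dataset, train_cnn)
from kinetoforge.cnn import _softmax


def toy_set(n_per_class=20, n_classes=2, seed=0):
    """Trivially separable images: class k has a bright block in region k."""
    rng = np.random.default_rng(seed)
    x = rng.random((n_per_class * n_classes, 3, 50, 50)).astype(np.float32) * 0.1
    y = np.repeat(np.arange(n_classes), n_per_class)
    for k in range(n_classes):
        rows = slice(5 + 10 * k, 15 + 10 * k)
        x[y == k, 0, rows, 10:40] += 0.6
    return x, y


class TestBuildCnn:
    def test_softmax_output_is_probability_vector(self):
        model = build_cnn(CNNConfig(n_classes=4), seed=0)
        x = np.random.default_rng(1).random((5, 3, 50, 50)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (5, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_same_seed_gives_identical_weights(self):
        a = build_cnn(CNNConfig(n_classes=3), seed=5)
        b = build_cnn(CNNConfig(n_classes=3), seed=5)
        np.testing.assert_array_equal(a.layers[0].w, b.layers[0].w)
        np.testing.assert_array_equal(a.layers[-1].w, b.layers[-1].w)

    def test_spatial_sizes_halve_then_floor(self):
        model = build_cnn(CNNConfig(n_classes=2), seed=0)
        x = np.zeros((1, 3, 50, 50), dtype=np.float32)
        out = model.layers[3].forward(
            model.layers[2].forward(
                model.layers[1].forward(
                    model.layers[0].forward(x, False), False), False), False)
        assert out.shape == (1, 8, 25, 25)
        # 25 -> 12 under the second pool (floor)
        assert model.layers[-1].w.shape[0] == 32 * 12 * 12

    def test_filter_counts_are_fixed(self):
        with pytest.raises(ValueError, match="filter"):
            CNNConfig(filters=(4, 8, 16))

    def test_softmax_on_extreme_logits(self):
        probs = _softmax(np.array([[1000.0, -1000.0, 0.0]]))
        assert np.isfinite(probs).all()
        np.testing.assert_allclose(probs.sum(), 1.0)


class TestSplitDataset:
    def test_hundred_items_split_56_24_20(self):
        labels = np.zeros(100, dtype=int)
        tr, va, te = split_dataset(labels, SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (56, 24, 20)

    @pytest.mark.parametrize("n", [50, 137, 1024, 4999])
    def test_partitions_disjoint_and_exhaustive(self, n):
        rng = np.random.default_rng(n)
        labels = rng.integers(0, 3, size=n)
        tr, va, te = split_dataset(labels, SplitSpec(seed=2))
        combined = np.concatenate([tr, va, te])
        assert len(combined) == n
        assert len(np.unique(combined)) == n

    def test_same_seed_same_split(self):
        labels = np.repeat([0, 1], 50)
        a = split_dataset(labels, SplitSpec(seed=3))
        b = split_dataset(labels, SplitSpec(seed=3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_stratification_preserves_class_shares(self):
        labels = np.repeat([0, 1, 2, 3], 100)
        tr, va, te = split_dataset(labels, SplitSpec(seed=4))
        for part, frac in ((tr, 0.56), (va, 0.24), (te, 0.20)):
            counts = np.bincount(labels[part], minlength=4)
            np.testing.assert_array_equal(counts, int(frac * 100))

    def test_tiny_class_rejected(self):
        labels = np.array([0] * 50 + [1])
        with pytest.raises(ValueError, match="1"):
            split_dataset(labels, SplitSpec(seed=5))


class TestBalanceClasses:
    def test_downsamples_to_smallest_class(self):
        labels = np.array([0] * 5920 + [1] * 4416)
        keep = balance_classes(labels, seed=1)
        counts = np.bincount(labels[keep])
        np.testing.assert_array_equal(counts, [4416, 4416])

    def test_already_balanced_keeps_counts(self):
        labels = np.repeat([0, 1, 2], 30)
        keep = balance_classes(labels, seed=2)
        np.testing.assert_array_equal(np.bincount(labels[keep]), [30, 30, 30])

    def test_seeded_selection_reproducible(self):
        labels = np.array([0] * 100 + [1] * 60)
        np.testing.assert_array_equal(balance_classes(labels, seed=3),
                                      balance_classes(labels, seed=3))


class TestTraining:
    def test_overfits_toy_set(self):
        x, y = toy_set()
        model = build_cnn(CNNConfig(n_classes=2), seed=1)
        tconfig = TrainConfig(batch_size=8, max_epochs=15, seed=2)
        history = train_cnn(model, x, y, (np.arange(40), np.arange(40)),
                            tconfig)
        assert history["final_validation_accuracy"] == 1.0

    def test_validation_history_every_30_iterations(self):
        x, y = toy_set()
        model = build_cnn(CNNConfig(n_classes=2), seed=1)
        tconfig = TrainConfig(batch_size=4, max_epochs=7, seed=3)
        history = train_cnn(model, x, y, (np.arange(40), np.arange(40)),
                            tconfig)
        iters = history["iterations"]   # 10 batches x 7 epochs = 70
        periodic = [i for i, _ in history["val_checks"]
                    if i % tconfig.validation_frequency == 0]
        assert periodic == [30, 60]     # iters // 30 scheduled checks
        # plus one closing validation pass at the last iteration
        assert history["val_checks"][-1][0] == iters

    def test_fixed_seeds_reproduce_training(self):
        x, y = toy_set(n_per_class=8)
        accs = []
        for _ in range(2):
            model = build_cnn(CNNConfig(n_classes=2), seed=4)
            history = train_cnn(model, x, y, (np.arange(16), np.arange(16)),
                                TrainConfig(batch_size=8, max_epochs=3, seed=5))
            accs.append(history["loss"])
        np.testing.assert_array_equal(accs[0], accs[1])


class TestEvaluatePredict:
    @pytest.fixture(scope="class")
    def trained(self):
        x, y = toy_set()
        model = build_cnn(CNNConfig(n_classes=2), seed=6)
        train_cnn(model, x, y, (np.arange(40), np.arange(40)),
                  TrainConfig(batch_size=8, max_epochs=15, seed=7))
        return model, x, y

    def test_confusion_matrix_row_sums_and_accuracy(self, trained):
        model, x, y = trained
        cm = evaluate(model, x, y, ["a", "b"])
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [20, 20])
        # brute-force recount of the accuracy
        pred = model.predict_labels(x)
        assert cm.accuracy == pytest.approx((pred == y).mean())

    def test_perfect_predictor_gives_diagonal(self, trained):
        model, x, y = trained
        cm = evaluate(model, x, y, ["a", "b"])
        if cm.accuracy == 1.0:
            assert np.allclose(cm.counts, np.diag(np.diag(cm.counts)))

    def test_predict_counts_sum_to_n(self, trained):
        model, x, _ = trained
        labels, counts = predict(model, x, ["a", "b"])
        assert sum(counts.values()) == len(x)

    def test_all_zero_image_gets_some_class(self, trained):
        model, _, _ = trained
        img = np.zeros((1, 50, 50, 3), dtype=np.uint16)
        labels, counts = predict(model, img, ["a", "b"])
        assert labels[0] in (0, 1)

    def test_save_load_round_trip(self, trained, tmp_path):
        from kinetoforge.cnn import load_model, save_model
        model, x, _ = trained
        path = tmp_path / "weights.npz"
        save_model(model, path, class_names=["a", "b"])
        back, names = load_model(path)
        assert names == ["a", "b"]
        np.testing.assert_array_equal(back.predict_proba(x),
                                      model.predict_proba(x))

    def test_images_to_tensor_contract(self):
        img = np.full((2, 50, 50, 3), 65535, dtype=np.uint16)
        t = images_to_tensor(img)
        assert t.shape == (2, 3, 50, 50)
        assert t.max() == pytest.approx(1.0)
        with pytest.raises(ValueError, match="images"):
            images_to_tensor(np.zeros((2, 50, 50)))
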