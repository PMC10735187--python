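"""Splitting, augmentation, the optimization schedule, and hold-out scoring."""

import numpy as np
import pytest

import nanobarcode as nb
from nanobarcode.masking import PixelDataset
from nanobarcode.network import NetworkConfig, build_classifier
from nanobarcode.training import augment_contrast, learning_rate_at, split_dataset


def _dataset(n_per_class: int, n_classes: int = 2, seed: int = 0) -> PixelDataset:
    rng = np.random.default_rng(seed)
    feats = rng.random((n_per_class * n_classes, 10)).astype(np.float32)
    labels = np.repeat(np.arange(n_classes), n_per_class)
    return PixelDataset(feats, labels, [f"c{i}" for i in range(n_classes)])


def test_split_1000_gives_800_100_100():
    ds = _dataset(500, 2)
    tr, va, te = split_dataset(ds, (0.8, 0.1, 0.1), seed=0)
    assert (len(tr), len(va), len(te)) == (800, 100, 100)


def test_split_ten_members_gives_8_1_1():
    ds = _dataset(10, 1)
    tr, va, te = split_dataset(ds, (0.8, 0.1, 0.1), seed=0)
    assert (len(tr), len(va), len(te)) == (8, 1, 1)


def test_split_is_a_stratified_partition():
    ds = _dataset(200, 3, seed=1)
    tr, va, te = split_dataset(ds, (0.8, 0.1, 0.1), seed=2)
    # disjoint union reconstructs the dataset exactly
    all_feats = np.concatenate([tr.features, va.features, te.features])
    order = np.lexsort(all_feats.T)
    base = np.lexsort(ds.features.T)
    np.testing.assert_array_equal(all_feats[order], ds.features[base])
    # stratification: each split carries every class at the right share
    for part, frac in ((tr, 0.8), (va, 0.1), (te, 0.1)):
        counts = part.class_counts()
        assert np.all(np.abs(counts - frac * 200) <= 1)


def test_split_tiny_class_goes_to_train():
    feats = np.random.default_rng(0).random((12, 10)).astype(np.float32)
    labels = np.array([0] * 10 + [1] * 2)
    ds = PixelDataset(feats, labels, ["a", "b"])
    with pytest.warns(UserWarning, match="cannot stratify"):
        tr, va, te = split_dataset(ds, (0.8, 0.1, 0.1), seed=0)
    assert (tr.labels == 1).sum() == 2
    assert not (va.labels == 1).any() and not (te.labels == 1).any()


def test_augment_degenerate_range_is_identity():
    x = np.random.default_rng(1).random((20, 10)).astype(np.float32)
    out = augment_contrast(x, (1.0, 1.0), np.random.default_rng(0))
    np.testing.assert_array_equal(out, x)


def test_augment_bounded_by_default_range():
    x = np.abs(np.random.default_rng(2).random((50, 10))).astype(np.float32) + 0.1
    out = augment_contrast(x, (0.5, 1.5), np.random.default_rng(3))
    ratio = out / x
    assert ratio.min() >= 0.5 - 1e-6 and ratio.max() <= 1.5 + 1e-6
    # the input batch is left unmodified
    assert not np.array_equal(out, x)


def test_augment_reproducible_under_fixed_rng():
    x = np.random.default_rng(4).random((10, 10)).astype(np.float32)
    a = augment_contrast(x, (0.5, 1.5), np.random.default_rng(9))
    b = augment_contrast(x, (0.5, 1.5), np.random.default_rng(9))
    np.testing.assert_array_equal(a, b)


def test_augment_rejects_nonpositive_bounds():
    with pytest.raises(ValueError):
        augment_contrast(np.ones((2, 2)), (0.0, 1.0))


def test_learning_rate_schedule():
    cfg = nb.TrainConfig()
    assert learning_rate_at(0, cfg) == pytest.approx(5e-4)
    assert learning_rate_at(19, cfg) == pytest.approx(5e-4)
    assert learning_rate_at(20, cfg) == pytest.approx(4.5e-4)
    assert learning_rate_at(40, cfg) == pytest.approx(5e-4 * 0.81)
    # full sequence matches the closed form
    for e in range(100):
        assert learning_rate_at(e, cfg) == pytest.approx(5e-4 * 0.9 ** (e // 20))


def _separable_dataset(seed=0):
    rng = np.random.default_rng(seed)
    a = np.zeros(10); a[2] = 1.0
    b = np.zeros(10); b[7] = 1.0
    feats = np.vstack([a + rng.normal(0, 0.01, (500, 10)),
                       b + rng.normal(0, 0.01, (500, 10))]).astype(np.float32)
    return PixelDataset(feats, np.repeat([0, 1], 500), ["a", "b"])


def test_separable_toy_trains_to_high_validation_accuracy():
    ds = _separable_dataset()
    splits = split_dataset(ds, (0.8, 0.1, 0.1), seed=0)
    cfg = NetworkConfig(input_dim=10, n_classes=2, width=16, branch_count=1,
                        blocks_per_branch=1)
    model = build_classifier(cfg, seed=0)
    tc = nb.TrainConfig(max_epochs=20, batch_size=64, seed=0, early_stop_patience=20)
    model, history = nb.train(model, splits, tc)
    assert history.n_epochs <= 20
    assert max(history.val_accuracy) >= 0.99


def test_training_returns_best_validation_checkpoint():
    ds = _separable_dataset(seed=1)
    splits = split_dataset(ds, (0.8, 0.1, 0.1), seed=1)
    cfg = NetworkConfig(input_dim=10, n_classes=2, width=8, branch_count=1,
                        blocks_per_branch=1)
    model = build_classifier(cfg, seed=1)
    tc = nb.TrainConfig(max_epochs=12, batch_size=64, seed=1, early_stop_patience=4)
    model, history = nb.train(model, splits, tc)
    from nanobarcode.training import _accuracy
    returned_val = _accuracy(model, splits[1].features, splits[1].labels)
    assert returned_val == pytest.approx(max(history.val_accuracy), abs=1e-9)
    assert returned_val >= history.val_accuracy[-1] - 1e-9
    assert history.best_epoch == int(np.argmax(history.val_accuracy))


def test_training_respects_max_epoch_budget():
    ds = _separable_dataset(seed=2)
    splits = split_dataset(ds, (0.8, 0.1, 0.1), seed=2)
    model = build_classifier(NetworkConfig(input_dim=10, n_classes=2, width=8,
                                           branch_count=1, blocks_per_branch=1), seed=2)
    tc = nb.TrainConfig(max_epochs=5, batch_size=128, seed=2)
    _, history = nb.train(model, splits, tc)
    assert history.n_epochs <= 5


def test_training_reproducible_to_four_decimals():
    ds = _separable_dataset(seed=3)
    splits = split_dataset(ds, (0.8, 0.1, 0.1), seed=3)
    cfg = NetworkConfig(input_dim=10, n_classes=2, width=8, branch_count=1,
                        blocks_per_branch=1)
    tc = nb.TrainConfig(max_epochs=6, batch_size=64, seed=3)
    _, h1 = nb.train(build_classifier(cfg, seed=3), splits, tc)
    _, h2 = nb.train(build_classifier(cfg, seed=3), splits, tc)
    np.testing.assert_allclose(h1.val_accuracy, h2.val_accuracy, atol=1e-4)
    np.testing.assert_allclose(h1.train_loss, h2.train_loss, atol=1e-4)


def test_evaluate_holdout_matches_brute_force(tiny_trained):
    """Independent confusion-matrix oracle: recount raw (prediction, target)
    pairs in pure Python."""
    model, _, splits = tiny_trained
    test = splits[2]
    report = nb.evaluate_holdout(model, test)
    preds = nb.forward(model, test.features).argmax(axis=1)
    n = model.config.n_classes
    brute = np.zeros((n, n), dtype=int)
    for t, p in zip(test.labels, preds):
        brute[t, p] += 1
    np.testing.assert_array_equal(report.confusion, brute)
    assert report.accuracy == pytest.approx(np.trace(brute) / brute.sum())


def test_evaluate_holdout_perfect_predictions():
    feats = np.eye(10, dtype=np.float32)[:, :10]
    ds = PixelDataset(feats[:4], np.arange(4) % 2, ["a", "b"])
    cfg = NetworkConfig(input_dim=10, n_classes=2, branch_count=1,
                        blocks_per_branch=0, post_merge_layers=0, batch_norm=False)
    model = build_classifier(cfg, seed=0)
    # force predictions equal to targets via a constructed linear map
    model.head.W[...] = 0
    model.head.b[...] = 0
    for i in range(4):
        model.head.W[i, ds.labels[i]] = 10.0
    report = nb.evaluate_holdout(model, ds)
    assert report.accuracy == 1.0
    assert np.all(report.f1[np.isfinite(report.f1)] == 1.0)
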