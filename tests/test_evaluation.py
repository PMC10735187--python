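"""Metric formulas, false-call shares, ablation mechanics, embeddings."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nanobarcode as nb
from nanobarcode.evaluation import (
    compute_metrics,
    confusion_from_pairs,
    embed_pixels,
    false_call_shares,
    nearest_centroid_accuracy,
)


def test_perfect_diagonal_confusion():
    report = compute_metrics(np.diag([5, 7, 9]))
    assert report.accuracy == 1.0
    np.testing.assert_array_equal(report.precision, 1.0)
    np.testing.assert_array_equal(report.recall, 1.0)
    np.testing.assert_array_equal(report.f1, 1.0)


def test_metric_formulas_hand_computed_case():
    """One-vs-rest class with TP=8, FP=2, FN=2, TN=88 scores exactly
    precision 0.8, recall 0.8, F1 0.8, accuracy 0.96."""
    cm = np.zeros((3, 3), dtype=int)
    cm[0, 0] = 8           # TP for class 0
    cm[1, 0] = 2           # FP into class 0
    cm[0, 1] = 2           # FN out of class 0
    cm[1, 1] = 30
    cm[2, 2] = 58          # remaining negatives
    report = compute_metrics(cm)
    assert report.precision[0] == pytest.approx(0.8)
    assert report.recall[0] == pytest.approx(0.8)
    assert report.f1[0] == pytest.approx(0.8)
    assert report.per_class_accuracy[0] == pytest.approx(0.96)


@given(st.integers(0, 2**31 - 1))
def test_f1_equals_harmonic_mean_identity(seed):
    rng = np.random.default_rng(seed)
    cm = rng.integers(0, 30, size=(5, 5))
    report = compute_metrics(cm)
    for p, r, f in zip(report.precision, report.recall, report.f1):
        if np.isfinite(f) and (p + r) > 0:
            assert f == pytest.approx(2 * p * r / (p + r), rel=1e-12)


@given(st.integers(0, 2**31 - 1))
def test_metrics_agree_with_brute_force_recount(seed):
    rng = np.random.default_rng(seed)
    n, k = 200, 4
    targets = rng.integers(0, k, n)
    preds = rng.integers(0, k, n)
    cm = confusion_from_pairs(targets, preds, k)
    # brute-force recount, one-vs-rest per class
    for c in range(k):
        tp = int(((targets == c) & (preds == c)).sum())
        fp = int(((targets != c) & (preds == c)).sum())
        fn = int(((targets == c) & (preds != c)).sum())
        report = compute_metrics(cm)
        if tp + fp:
            assert report.precision[c] == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert report.recall[c] == pytest.approx(tp / (tp + fn))
    assert compute_metrics(cm).accuracy == pytest.approx((targets == preds).mean())


def test_accuracy_is_trace_over_total():
    cm = np.array([[3, 1], [2, 4]])
    assert compute_metrics(cm).accuracy == pytest.approx(7 / 10)


def test_undefined_metrics_marked_not_zeroed():
    cm = np.array([[5, 0, 0], [3, 0, 0], [0, 0, 2]])  # class 1 never predicted
    report = compute_metrics(cm)
    assert np.isnan(report.precision[1])
    assert report.recall[1] == 0.0


def test_compute_metrics_rejects_bad_input():
    with pytest.raises(ValueError):
        compute_metrics(np.ones((2, 3), dtype=int))
    with pytest.raises(ValueError):
        compute_metrics(np.array([[1, -1], [0, 2]]))


def test_false_call_shares_single_error():
    cm = np.diag([5, 5, 5]); cm[0, 2] = 3
    fp, fn = false_call_shares(cm)
    assert fp[2] == pytest.approx(100.0) and fn[0] == pytest.approx(100.0)
    assert fp[0] == 0 and fn[2] == 0


def test_false_call_shares_split_evenly():
    cm = np.diag([5, 5, 5]); cm[0, 1] = 4; cm[2, 0] = 4
    fp, fn = false_call_shares(cm)
    assert fp[1] == pytest.approx(50.0) and fp[0] == pytest.approx(50.0)
    assert fn[0] == pytest.approx(50.0) and fn[2] == pytest.approx(50.0)


@given(st.integers(0, 2**31 - 1))
def test_false_call_shares_sum_to_100(seed):
    rng = np.random.default_rng(seed)
    cm = rng.integers(0, 10, size=(6, 6))
    fp, fn = false_call_shares(cm)
    off = cm.sum() - np.trace(cm)
    if off:
        assert fp.sum() == pytest.approx(100.0, abs=1e-9)
        assert fn.sum() == pytest.approx(100.0, abs=1e-9)
    else:
        assert np.isnan(fp).all() and np.isnan(fn).all()


def test_embeddings_shapes_and_methods(signature_dataset):
    rng = np.random.default_rng(0)
    idx = rng.choice(len(signature_dataset), 120, replace=False)
    feats = signature_dataset.features[idx]
    for method in ("isomap", "kernel-pca", "t-sne", "spectral"):
        res = embed_pixels(feats, method=method, dims=2, seed=0)
        assert res.coords.shape == (120, 2)
        assert np.isfinite(res.coords).all()
        assert res.method == method
    with pytest.raises(ValueError):
        embed_pixels(feats, method="umap-but-wrong")


def test_kernel_pca_linear_matches_classical_pca_scores():
    rng = np.random.default_rng(5)
    data = rng.normal(0, 1, (80, 6)) * np.array([4, 2, 1, 0.5, 0.2, 0.1])
    res = embed_pixels(data, method="kernel-pca", dims=2, seed=0, kernel="linear")
    centered = data - data.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    classic = centered @ vt[:2].T
    for k in range(2):
        corr = np.corrcoef(res.coords[:, k], classic[:, k])[0, 1]
        assert abs(abs(corr) - 1) < 1e-6


def test_two_cluster_toy_separates_in_every_embedding(response_matrix):
    """GFP-only signature vs blank: every shallow method separates the two
    clusters (positive silhouette)."""
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(2)
    gfp = nb.barcode_signature(nb.Barcode.from_label("0100"), response_matrix)
    feats = np.vstack([gfp + rng.normal(0, 0.02, (60, 10)),
                       rng.normal(0, 0.02, (60, 10))])
    labels = np.repeat([1, 0], 60)
    for method in ("isomap", "kernel-pca", "t-sne", "spectral"):
        res = embed_pixels(feats, method=method, dims=2, seed=1)
        assert silhouette_score(res.coords, labels) > 0


def test_nearest_centroid_scores_partition():
    rng = np.random.default_rng(3)
    coords = np.vstack([rng.normal(0, 0.1, (50, 2)), rng.normal(3, 0.1, (50, 2))])
    labels = np.repeat([0, 1], 50)
    assert nearest_centroid_accuracy(coords, labels, seed=0) == 1.0


def _small_scene_dataset(response_matrix, n_classes=6, seed=0):
    from nanobarcode.pipeline import build_training_dataset

    barcodes = nb.enumerate_barcodes(4)[:n_classes]
    sim = nb.SimConfig(height=48, width=48)
    return build_training_dataset(barcodes, response_matrix, sim, images_per_class=1,
                                  cap=250, blank_ratio=1 / n_classes,
                                  use_ground_truth=True, seed=seed)


def test_ablation_run_count_and_exclusion(response_matrix):
    ds = _small_scene_dataset(response_matrix)
    net = nb.NetworkConfig(n_classes=ds.n_classes, width=16, branch_count=1,
                           blocks_per_branch=1)
    tc = nb.TrainConfig(max_epochs=6, batch_size=128, early_stop_patience=3)
    baseline, runs = nb.ablation_study(ds, net, tc, master_seed=0)
    assert len(runs) == ds.n_classes - 1
    assert {r.left_out for r in runs} == set(ds.class_names[1:])
    for r in runs:
        assert not r.failed
        # left-out class appears in no run's confusion matrix
        assert r.report.confusion.shape == (ds.n_classes - 1, ds.n_classes - 1)


def test_ablation_deterministic_under_master_seed(response_matrix):
    ds = _small_scene_dataset(response_matrix, n_classes=3, seed=4)
    net = nb.NetworkConfig(n_classes=ds.n_classes, width=8, branch_count=1,
                           blocks_per_branch=1)
    tc = nb.TrainConfig(max_epochs=4, batch_size=128, early_stop_patience=3)
    b1, r1 = nb.ablation_study(ds, net, tc, master_seed=9)
    b2, r2 = nb.ablation_study(ds, net, tc, master_seed=9)
    assert b1.accuracy == pytest.approx(b2.accuracy, abs=1e-4)
    for a, b in zip(r1, r2):
        assert a.report.accuracy == pytest.approx(b.report.accuracy, abs=1e-4)
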