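"""Metrics, confusion analysis, class-ablation study, and shallow baselines.

Per-class metrics use the one-vs-rest reduction of the multiclass confusion
matrix:

    accuracy = (TP + TN) / (TP + TN + FP + FN)      precision = TP / (TP + FP)
    recall   = TP / (TP + FN)                       F1 = 2 / (1/precision + 1/recall)

False-positive and false-negative *shares* express each class's
contribution as a percentage of all false predictions.  Shallow
2-D embeddings (Isomap, kernel PCA, t-SNE, spectral) serve as baselines
showing that the barcode classes are not linearly/manifold-separable enough
for nearest-centroid reading, which motivates the deep classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .masking import PixelDataset
from .network import NetworkConfig, build_classifier

#: marker for metrics whose denominator is empty (no positives predicted/present)
UNDEFINED = float("nan")


@dataclass
class MetricsReport:
    """Confusion matrix (rows = target, columns = prediction) and derived metrics."""

    confusion: np.ndarray
    class_names: list[str] | None = None
    accuracy: float = field(init=False)
    per_class_accuracy: np.ndarray = field(init=False)
    precision: np.ndarray = field(init=False)
    recall: np.ndarray = field(init=False)
    f1: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        cm = np.asarray(self.confusion)
        if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (cm < 0).any() or not np.issubdtype(cm.dtype, np.integer):
            raise ValueError("confusion matrix must hold non-negative integers")
        self.confusion = cm
        total = cm.sum()
        tp = np.diag(cm).astype(float)
        fp = cm.sum(axis=0) - tp
        fn = cm.sum(axis=1) - tp
        tn = total - tp - fp - fn
        self.accuracy = float(tp.sum() / total) if total else UNDEFINED
        with np.errstate(invalid="ignore", divide="ignore"):
            self.per_class_accuracy = (tp + tn) / total if total else np.full_like(tp, UNDEFINED)
            self.precision = np.where(tp + fp > 0, tp / (tp + fp), UNDEFINED)
            self.recall = np.where(tp + fn > 0, tp / (tp + fn), UNDEFINED)
            pr_sum = self.precision + self.recall
            self.f1 = np.where(
                np.isfinite(pr_sum) & (pr_sum > 0),
                2 * self.precision * self.recall / pr_sum,
                UNDEFINED,
            )

    def macro(self, metric: str = "f1", include_blank: bool = False) -> float:
        """Mean of a per-class metric; blank (class 0) excluded by default."""
        values = getattr(self, metric)
        if not include_blank:
            values = values[1:]
        values = values[np.isfinite(values)]
        return float(values.mean()) if len(values) else UNDEFINED


def confusion_from_pairs(targets, predictions, n_classes: int) -> np.ndarray:
    """Count (target, prediction) pairs into an n x n confusion matrix."""
    targets = np.asarray(targets, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if targets.shape != predictions.shape:
        raise ValueError("targets and predictions must align")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (targets, predictions), 1)
    return cm


def compute_metrics(confusion, class_names: Sequence[str] | None = None) -> MetricsReport:
    """Per-class one-vs-rest metrics from a confusion matrix.

    Classes with an empty denominator (e.g. never predicted) carry NaN as an
    explicit undefined marker rather than 0.
    """
    return MetricsReport(np.asarray(confusion), list(class_names) if class_names else None)


def false_call_shares(confusion) -> tuple[np.ndarray, np.ndarray]:
    """Per-class FP% and FN% of all false predictions.

    FP share of class c: off-diagonal mass of column c over all off-diagonal
    mass, in percent; FN share analogous over rows.  Each vector sums to 100
    when any false prediction exists; all-NaN otherwise.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any():
        raise ValueError("confusion matrix must be square and non-negative")
    off = cm.copy()
    np.fill_diagonal(off, 0)
    total = off.sum()
    if total == 0:
        n = len(cm)
        return np.full(n, UNDEFINED), np.full(n, UNDEFINED)
    return off.sum(axis=0) / total * 100.0, off.sum(axis=1) / total * 100.0


@dataclass
class AblationRun:
    left_out: str
    report: MetricsReport | None
    failed: bool = False


def ablation_study(
    ds: PixelDataset,
    net_config: NetworkConfig,
    train_config,
    master_seed: int = 0,
) -> tuple[MetricsReport, list[AblationRun]]:
    """Leave-one-class-out retraining: the class-ablation study.

    Each non-blank class is removed in turn from *all* partitions, a fresh
    classifier is fully trained on the remainder, and hold-out metrics are
    collected next to the full-model baseline.  Per-run seeds derive
    deterministically from the master seed; a failed run is recorded and
    the study continues.
    """
    from .training import TrainConfig, evaluate_holdout, split_dataset, train

    n_barcode_classes = ds.n_classes - 1
    if n_barcode_classes < 3:
        raise ValueError("ablation needs at least 3 barcode classes")
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(master_seed).spawn(n_barcode_classes + 1)]

    def _run(dataset: PixelDataset, seed: int) -> MetricsReport:
        cfg = NetworkConfig(**{**net_config.__dict__, "n_classes": dataset.n_classes})
        model = build_classifier(cfg, seed=seed, class_names=dataset.class_names)
        tc = TrainConfig(**{**train_config.__dict__, "seed": seed})
        splits = split_dataset(dataset, tc.split_fractions, seed=seed)
        model, _ = train(model, splits, tc)
        return evaluate_holdout(model, splits[2])

    baseline = _run(ds, seeds[0])
    runs: list[AblationRun] = []
    for cls in range(1, ds.n_classes):
        name = ds.class_names[cls]
        try:
            report = _run(ds.drop_class(cls), seeds[cls])
            runs.append(AblationRun(name, report))
        except Exception:  # noqa: BLE001 - a failed run must not stop the study
            runs.append(AblationRun(name, None, failed=True))
    return baseline, runs


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    method: str
    dims: int
    seed: int | None


_EMBED_METHODS = ("isomap", "kernel-pca", "t-sne", "spectral")


def embed_pixels(
    features: np.ndarray,
    method: str = "kernel-pca",
    dims: int = 2,
    seed: int | None = 0,
    **kwargs,
) -> EmbeddingResult:
    """Shallow 2-D embedding baselines over pixel feature vectors."""
    features = np.asarray(features, dtype=float)
    if len(features) < dims + 1:
        raise ValueError("need at least dims + 1 samples")
    if method == "isomap":
        from sklearn.manifold import Isomap

        coords = Isomap(n_components=dims, **kwargs).fit_transform(features)
    elif method == "kernel-pca":
        from sklearn.decomposition import KernelPCA

        kwargs.setdefault("kernel", "rbf")
        coords = KernelPCA(n_components=dims, random_state=seed, **kwargs).fit_transform(features)
    elif method == "t-sne":
        from sklearn.manifold import TSNE

        kwargs.setdefault("perplexity", min(30.0, (len(features) - 1) / 3))
        kwargs.setdefault("init", "pca")
        coords = TSNE(n_components=dims, random_state=seed, **kwargs).fit_transform(features)
    elif method == "spectral":
        from sklearn.manifold import SpectralEmbedding

        coords = SpectralEmbedding(n_components=dims, random_state=seed, **kwargs).fit_transform(features)
    else:
        raise ValueError(f"unknown embedding method {method!r}; choose from {_EMBED_METHODS}")
    if not np.isfinite(coords).all():
        raise RuntimeError(f"{method} produced non-finite coordinates")
    return EmbeddingResult(np.asarray(coords), method, dims, seed)


def nearest_centroid_accuracy(
    coords: np.ndarray, labels: np.ndarray, seed: int = 0, train_fraction: float = 0.8
) -> float:
    """Accuracy of nearest-centroid classification in an embedding space.

    Used to quantify how far a shallow 2-D embedding falls short of the
    deep classifier on the same pixels.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    order = rng.permutation(len(coords))
    n_train = int(train_fraction * len(coords))
    tr, te = order[:n_train], order[n_train:]
    classes = np.unique(labels[tr])
    centroids = np.stack([coords[tr][labels[tr] == c].mean(axis=0) for c in classes])
    d = ((coords[te][:, None, :] - centroids[None]) ** 2).sum(axis=-1)
    preds = classes[d.argmin(axis=1)]
    return float((preds == labels[te]).mean())
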