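"""Foreground/background separation and labeled pixel gathering.

Training data for the pixel classifier come from images of single
transfects with a known barcode.  Foreground (fluorescing) pixels are
separated from background by kernel PCA with a single retained component,
fitted on a random subsample of pixels, followed by a *relative* threshold
at a fixed fraction (default 0.8) of the range of the transformed values.
Per case, up to a cap (default 10,000) of foreground pixels are gathered,
plus blank pixels at a configurable blank:foreground ratio to teach the
classifier the background noise floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import KernelPCA


class DegenerateInputError(ValueError):
    """Raised when the pixel sample carries no variance to decompose."""


class DegenerateRangeError(ValueError):
    """Raised when transformed values span a zero range (no threshold exists)."""


@dataclass
class MaskingModel:
    """Fitted single-component kernel-PCA pixel scorer.

    ``orientation_sign`` fixes the arbitrary sign of the component so that
    larger oriented scores correspond to brighter pixels (larger mean total
    fluorescence), making the relative threshold well-posed.
    """

    kpca: KernelPCA
    kernel: str
    orientation_sign: int
    relative_threshold: float = 0.8
    fit_sample_size: int = 4000
    n_fit_pixels: int = 0
    seed: int | None = None

    def transform(self, pixels: np.ndarray, chunk: int = 8192) -> np.ndarray:
        """Oriented component scores for (N, channels) pixel vectors."""
        pixels = np.asarray(pixels, dtype=float)
        parts = [
            self.kpca.transform(pixels[i : i + chunk])[:, 0]
            for i in range(0, len(pixels), chunk)
        ]
        return self.orientation_sign * np.concatenate(parts)


@dataclass
class ForegroundMask:
    mask: np.ndarray
    threshold: float
    n_retained: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.n_retained = int(self.mask.sum())


@dataclass
class PixelDataset:
    """Labeled per-pixel intensity vectors; class 0 is blank."""

    features: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    provenance: np.ndarray | None = None  # (N, 3) item index, row, col

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, idx: np.ndarray) -> "PixelDataset":
        prov = None if self.provenance is None else self.provenance[idx]
        return PixelDataset(self.features[idx], self.labels[idx], list(self.class_names), prov)

    def drop_class(self, class_index: int) -> "PixelDataset":
        """Remove one non-blank class and compact the label indices."""
        if class_index == 0:
            raise ValueError("the blank class cannot be dropped")
        keep = self.labels != class_index
        labels = self.labels[keep].copy()
        labels[labels > class_index] -= 1
        names = [n for i, n in enumerate(self.class_names) if i != class_index]
        prov = None if self.provenance is None else self.provenance[keep]
        return PixelDataset(self.features[keep], labels, names, prov)

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("features", data=self.features)
            fh.create_dataset("labels", data=self.labels)
            fh.create_dataset(
                "class_names", data=np.array(self.class_names, dtype=h5py.string_dtype())
            )
            if self.provenance is not None:
                fh.create_dataset("provenance", data=self.provenance)

    @classmethod
    def load(cls, path) -> "PixelDataset":
        with h5py.File(path, "r") as fh:
            prov = fh["provenance"][:] if "provenance" in fh else None
            return cls(
                fh["features"][:],
                fh["labels"][:],
                [s.decode() if isinstance(s, bytes) else s for s in fh["class_names"][:]],
                prov,
            )


def _median_heuristic_gamma(sample: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise distance of the fit sample."""
    sub = sample if len(sample) <= 1000 else sample[:: len(sample) // 1000][:1000]
    med = np.median(pdist(sub))
    if med == 0:
        raise DegenerateInputError("pixel sample has zero median pairwise distance")
    return 1.0 / (2.0 * med**2)


def fit_masking_model(
    stacks: Sequence,
    sample_size: int = 4000,
    kernel: str = "rbf",
    gamma: float | None = None,
    relative_threshold: float = 0.8,
    seed: int | None = None,
) -> MaskingModel:
    """Fit the single-component kernel-PCA scorer on a random pixel subsample.

    Exactly ``min(sample_size, available)`` pixels are drawn uniformly
    without replacement across all stacks.  One model is intended per case
    (one barcode and expression-time window), mirroring the acquisition
    protocol.
    """
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    if not (0 < relative_threshold < 1):
        raise ValueError("relative_threshold must be in (0, 1)")
    pools = [s.pixels() if hasattr(s, "pixels") else np.asarray(s, dtype=float) for s in stacks]
    allpix = np.concatenate([p.reshape(-1, p.shape[-1]) for p in pools])
    if len(allpix) < 2:
        raise ValueError("need at least 2 pixels to fit")
    rng = np.random.default_rng(seed)
    n_fit = min(sample_size, len(allpix))
    idx = rng.choice(len(allpix), size=n_fit, replace=False)
    sample = allpix[idx]
    if np.allclose(sample.std(axis=0), 0):
        raise DegenerateInputError("pixel sample is constant; nothing to decompose")

    if kernel == "rbf" and gamma is None:
        gamma = _median_heuristic_gamma(sample)
    kpca = KernelPCA(n_components=1, kernel=kernel, gamma=gamma, random_state=seed)
    scores = kpca.fit_transform(sample)[:, 0]
    # orient so high scores mean bright pixels
    total = sample.sum(axis=1)
    corr = np.corrcoef(scores, total)[0, 1]
    sign = -1 if corr < 0 else 1
    return MaskingModel(
        kpca=kpca,
        kernel=kernel,
        orientation_sign=sign,
        relative_threshold=relative_threshold,
        fit_sample_size=sample_size,
        n_fit_pixels=n_fit,
        seed=seed,
    )


def compute_mask(model: MaskingModel, stack) -> ForegroundMask:
    """Threshold the oriented component at ``relative_threshold`` of its range.

    A pixel is foreground iff its transformed value is at least
    ``min + relative_threshold * (max - min)`` where min/max are taken over
    this stack's transformed values.
    """
    pixels = stack.pixels() if hasattr(stack, "pixels") else np.asarray(stack, dtype=float)
    shape = stack.shape if hasattr(stack, "shape") else pixels.shape[:-1]
    flat = pixels.reshape(-1, pixels.shape[-1])
    scores = model.transform(flat)
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        raise DegenerateRangeError("transformed values span zero range")
    threshold = lo + model.relative_threshold * (hi - lo)
    mask = (scores >= threshold).reshape(shape[:2] if len(shape) > 1 else shape)
    return ForegroundMask(mask, threshold)


def gather_pixels(
    items: Sequence[tuple],
    cap: int = 10_000,
    blank_ratio: float = 10.0,
    seed: int | None = None,
    class_names: Sequence[str] | None = None,
    blank_items: Sequence | None = None,
) -> PixelDataset:
    """Build a labeled pixel dataset from masked (or ground-truth) images.

    ``items`` holds ``(stack, mask, class_label)`` triples where ``mask`` is
    a :class:`ForegroundMask`, a boolean array, or a ground-truth object
    with a ``label_map``.  Per class, up to ``cap`` foreground pixels are
    sampled uniformly without replacement, pooled across that class's
    images; blank pixels are gathered at ``blank_ratio`` times the
    per-class foreground yield, capped by availability.  By default blanks
    come from outside the masks of ``items``; pass ``blank_items`` (stacks
    acquired in the absence of any nanobarcode) to draw the blank class
    from dedicated blank fields instead — out-of-mask pixels of protein
    images can still contain dim true signal below the mask threshold.
    Classes whose masks are empty are reported via warning.
    """
    if not items:
        raise ValueError("at least one (stack, mask, label) item is required")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if blank_ratio < 0:
        raise ValueError("blank_ratio must be >= 0")
    rng = np.random.default_rng(seed)

    def _boolmask(m):
        if hasattr(m, "label_map"):
            return np.asarray(m.label_map) > 0
        if hasattr(m, "mask"):
            return np.asarray(m.mask, dtype=bool)
        return np.asarray(m, dtype=bool)

    labels_seen = []
    for _, _, lab in items:
        if lab not in labels_seen:
            labels_seen.append(lab)
    if class_names is None:
        class_names = ["blank"] + sorted(labels_seen)
    class_index = {name: i for i, name in enumerate(class_names)}

    def _image(stack):
        if hasattr(stack, "pixels"):
            return stack.pixels().reshape(stack.shape + (-1,))
        arr = np.asarray(stack, dtype=np.float32)
        return arr

    images = [_image(stack) for stack, _, _ in items]
    per_class_coords: dict[str, list] = {lab: [] for lab in labels_seen}
    blank_coords: list = []
    for item_idx, (_, mask, lab) in enumerate(items):
        bm = _boolmask(mask)
        fg = np.argwhere(bm)
        if len(fg):
            per_class_coords[lab].append(np.column_stack([np.full(len(fg), item_idx), fg]))
        if blank_items is None:
            bg = np.argwhere(~bm)
            if len(bg):
                blank_coords.append(np.column_stack([np.full(len(bg), item_idx), bg]))
    if blank_items is not None:
        for j, stack in enumerate(blank_items):
            img = _image(stack)
            images.append(img)
            rows, cols = np.indices(img.shape[:2])
            coords = np.column_stack([
                np.full(img.shape[0] * img.shape[1], len(items) + j),
                rows.ravel(), cols.ravel(),
            ])
            blank_coords.append(coords)

    def _extract(sel: np.ndarray) -> np.ndarray:
        out = np.empty((len(sel), images[0].shape[-1]), dtype=np.float32)
        for i in np.unique(sel[:, 0]):
            rows = sel[:, 0] == i
            out[rows] = images[i][sel[rows, 1], sel[rows, 2]]
        return out

    feats, labs, prov = [], [], []
    blank_target = 0.0
    for lab in labels_seen:
        pool = per_class_coords[lab]
        if not pool:
            warnings.warn(f"class {lab!r}: no foreground pixels under its masks; class absent")
            continue
        pool = np.concatenate(pool)
        take = min(cap, len(pool))
        sel = pool[rng.choice(len(pool), size=take, replace=False)]
        feats.append(_extract(sel))
        labs.append(np.full(take, class_index[lab], dtype=np.int64))
        prov.append(sel)
        blank_target += blank_ratio * take

    if blank_coords and blank_target > 0:
        bg_pool = np.concatenate(blank_coords)
        take = min(int(round(blank_target)), len(bg_pool))
        sel = bg_pool[rng.choice(len(bg_pool), size=take, replace=False)]
        feats.append(_extract(sel))
        labs.append(np.zeros(take, dtype=np.int64))
        prov.append(sel)

    if not feats:
        raise ValueError("no pixels gathered")
    return PixelDataset(
        np.concatenate(feats).astype(np.float32),
        np.concatenate(labs),
        list(class_names),
        np.concatenate(prov),
    )
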