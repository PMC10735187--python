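"""End-to-end experiment pipelines over the module surfaces.

These are the same flows a user drives from the command line: simulate
single-transfect fields per barcode, separate foreground by kernel PCA per
case, gather a labeled pixel dataset, train the classifier, and score
whole-image inference with test-time contrast adaptation.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .barcodes import Barcode, SpectralResponseMatrix
from .inference import (
    UndefinedPrecisionError,
    classify_image,
    fit_contrast_modifier,
    image_precision,
)
from .masking import PixelDataset, compute_mask, fit_masking_model, gather_pixels
from .network import NetworkConfig, ResidualClassifier, build_classifier
from .simulate import SimConfig, simulate_blank_image, simulate_dataset, simulate_image
from .training import TrainConfig, TrainingHistory, evaluate_holdout, split_dataset, train


def build_training_dataset(
    barcodes: Sequence[Barcode],
    matrix: SpectralResponseMatrix,
    sim_config: SimConfig,
    images_per_class: int = 2,
    cap: int = 10_000,
    blank_ratio: float = 10.0,
    mask_sample_size: int = 4000,
    use_ground_truth: bool = False,
    n_blank_images: int | None = None,
    seed: int = 0,
) -> PixelDataset:
    """Simulate single-transfect images and gather a labeled pixel dataset.

    One kernel-PCA masking model is fitted per case (per barcode), as in
    the acquisition protocol.  Blank training samples come from dedicated
    blank fields (no nanobarcode expressed), ``n_blank_images`` of them
    (default ``images_per_class``), so the blank class captures the pure
    background noise floor.  ``use_ground_truth`` bypasses masking and
    labels pixels from the simulator's truth instead (oracle mode for
    diagnostics).
    """
    ss = np.random.SeedSequence(seed)
    sim_seed, mask_seed, gather_seed, blank_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4))
    collection = simulate_dataset(barcodes, images_per_class, matrix, sim_config, sim_seed)
    if n_blank_images is None:
        n_blank_images = images_per_class
    blank_items = [
        simulate_blank_image(matrix, sim_config, np.random.default_rng(s))[0]
        for s in np.random.SeedSequence(blank_seed).spawn(n_blank_images)
    ] if n_blank_images else None

    items = []
    by_label: dict[str, list] = {}
    for stack, truth, label in collection:
        by_label.setdefault(label, []).append((stack, truth))
    for case_idx, (label, pairs) in enumerate(sorted(by_label.items())):
        if use_ground_truth:
            items.extend((stack, truth, label) for stack, truth in pairs)
        else:
            model = fit_masking_model(
                [stack for stack, _ in pairs],
                sample_size=mask_sample_size,
                seed=mask_seed + case_idx,
            )
            items.extend((stack, compute_mask(model, stack), label) for stack, _ in pairs)
    class_names = ["blank"] + sorted(b.label for b in barcodes)
    return gather_pixels(items, cap=cap, blank_ratio=blank_ratio, seed=gather_seed,
                         class_names=class_names, blank_items=blank_items)


def train_pixel_classifier(
    ds: PixelDataset,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[ResidualClassifier, TrainingHistory, tuple[PixelDataset, ...]]:
    """Split, build and train a classifier on a gathered pixel dataset."""
    if net_config is None:
        net_config = NetworkConfig(n_classes=ds.n_classes)
    elif net_config.n_classes != ds.n_classes:
        net_config = replace(net_config, n_classes=ds.n_classes)
    if train_config is None:
        train_config = TrainConfig(seed=seed)
    splits = split_dataset(ds, train_config.split_fractions, seed=train_config.seed)
    model = build_classifier(net_config, seed=seed, class_names=ds.class_names)
    model, history = train(model, splits, train_config)
    return model, history, splits


def holdout_accuracy(model: ResidualClassifier, test: PixelDataset) -> float:
    return evaluate_holdout(model, test).accuracy


def image_precision_experiment(
    model: ResidualClassifier,
    barcodes: Sequence[Barcode],
    matrix: SpectralResponseMatrix,
    sim_config: SimConfig,
    n_images: int = 20,
    adapt_steps: int = 50,
    seed: int = 0,
) -> list[dict]:
    """Per-image precision of whole-image inference on fresh single-barcode fields.

    Images cycle through the barcode classes; each is classified after
    ``adapt_steps`` entropy-minimization steps of its own contrast modifier.
    Images with no non-blank prediction are recorded with ``None`` precision.
    """
    label_to_class = {name: i for i, name in enumerate(model.class_names)}
    seeds = np.random.SeedSequence(seed).spawn(n_images)
    results = []
    for k in range(n_images):
        barcode = barcodes[k % len(barcodes)]
        rng = np.random.default_rng(seeds[k])
        stack, _ = simulate_image(barcode, matrix, sim_config, rng)
        modifier = fit_contrast_modifier(model, stack, steps=adapt_steps)
        pmap = classify_image(model, stack, modifier)
        known = label_to_class[barcode.label]
        try:
            precision, n_nonblank = image_precision(pmap, known)
        except UndefinedPrecisionError:
            precision, n_nonblank = None, 0
        results.append({
            "barcode": barcode.label,
            "precision": precision,
            "n_nonblank": n_nonblank,
            "entropy_trace": modifier.entropy_trace,
        })
    return results


def hyperparameter_search(
    ds: PixelDataset,
    space: dict[str, Sequence],
    train_config: TrainConfig,
    mode: str = "grid",
    n_random: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Plain grid/random search over architecture and optimizer settings.

    ``space`` maps parameter names (``width``, ``branch_count``,
    ``blocks_per_branch``, ``batch_size``, ``learning_rate``) to candidate
    values; each candidate is trained and scored on the validation split.
    """
    import itertools

    keys = sorted(space)
    if mode == "grid":
        candidates = [dict(zip(keys, vals)) for vals in itertools.product(*(space[k] for k in keys))]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        candidates = [{k: space[k][rng.integers(len(space[k]))] for k in keys}
                      for _ in range(n_random)]
    else:
        raise ValueError("mode must be 'grid' or 'random'")

    net_keys = {"width", "branch_count", "blocks_per_branch", "post_merge_layers"}
    results = []
    for cand in candidates:
        net_cfg = NetworkConfig(
            n_classes=ds.n_classes,
            **{k: v for k, v in cand.items() if k in net_keys},
        )
        tc_fields = {k: v for k, v in cand.items() if k not in net_keys}
        tc = TrainConfig(**{**train_config.__dict__, **tc_fields})
        model, history, splits = train_pixel_classifier(ds, net_cfg, tc, seed=seed)
        results.append({
            **cand,
            "val_accuracy": max(history.val_accuracy) if history.val_accuracy else None,
            "epochs": history.n_epochs,
        })
    return sorted(results, key=lambda r: -(r["val_accuracy"] or 0))
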