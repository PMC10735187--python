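"""Shared fixtures: response matrix, synthetic pixel sets, trained models.

The expensive fixtures are session-scoped so the full-protocol classifier
(15 barcodes + blank, 2,500 pixels/class, width 64) is trained exactly once
and reused by the hold-out, image-precision and baseline-comparison tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nanobarcode as nb
from nanobarcode.masking import PixelDataset
from nanobarcode.pipeline import build_training_dataset, train_pixel_classifier

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def response_matrix() -> nb.SpectralResponseMatrix:
    return nb.default_response_matrix()


@pytest.fixture(scope="session")
def barcodes15() -> list[nb.Barcode]:
    return nb.enumerate_barcodes(4)


def make_signature_dataset(
    matrix: nb.SpectralResponseMatrix,
    n_per_class: int = 300,
    noise: float = 0.02,
    amplitude: float = 1.0,
    seed: int = 0,
) -> PixelDataset:
    """Fast labeled pixel set drawn directly from barcode signatures.

    Class 0 is blank (noise only); classes 1..15 are the four-epitope
    barcodes at fixed amplitude with additive Gaussian noise.  Bypasses the
    imaging pipeline for cheap classifier tests.
    """
    rng = np.random.default_rng(seed)
    barcodes = nb.enumerate_barcodes(matrix.response.shape[0])
    feats, labels = [], []
    for cls, b in enumerate([None] + barcodes):
        sig = np.zeros(matrix.n_channels) if b is None else nb.barcode_signature(b, matrix, amplitude)
        feats.append(sig + rng.normal(0, noise, size=(n_per_class, matrix.n_channels)))
        labels.append(np.full(n_per_class, cls))
    names = ["blank"] + [b.label for b in barcodes]
    return PixelDataset(np.concatenate(feats).astype(np.float32),
                        np.concatenate(labels), names)


@pytest.fixture(scope="session")
def signature_dataset(response_matrix) -> PixelDataset:
    return make_signature_dataset(response_matrix)


@pytest.fixture(scope="session")
def tiny_trained(response_matrix, signature_dataset):
    """Small classifier trained on the signature pixel set (fast, accurate)."""
    net = nb.NetworkConfig(n_classes=16, width=32, branch_count=2, blocks_per_branch=1)
    tc = nb.TrainConfig(max_epochs=25, batch_size=256, early_stop_patience=8, seed=3)
    model, history, splits = train_pixel_classifier(signature_dataset, net, tc, seed=3)
    return model, history, splits


@pytest.fixture(scope="session")
def scene_model(response_matrix, barcodes15):
    """Classifier trained on simulated scenes (64x64) for inference tests."""
    sim = nb.SimConfig(height=64, width=64)
    ds = build_training_dataset(barcodes15, response_matrix, sim,
                                images_per_class=1, cap=400, blank_ratio=1 / 15, seed=21)
    net = nb.NetworkConfig(n_classes=ds.n_classes, width=32, branch_count=2,
                           blocks_per_branch=1)
    tc = nb.TrainConfig(max_epochs=25, batch_size=256, early_stop_patience=8, seed=21)
    model, history, splits = train_pixel_classifier(ds, net, tc, seed=21)
    return model, sim


@pytest.fixture(scope="session")
def full_protocol(response_matrix, barcodes15):
    """The full desk-scale protocol: 15 barcodes + blank, 2,500 pixels/class,
    kernel-PCA masking, width-64 classifier, <=40 epochs.  Trained once."""
    sim = nb.SimConfig()  # 128x128 defaults
    ds = build_training_dataset(barcodes15, response_matrix, sim,
                                images_per_class=2, cap=2500, blank_ratio=0.4,
                                n_blank_images=4, seed=11)
    net = nb.NetworkConfig(n_classes=ds.n_classes, width=64)
    tc = nb.TrainConfig(max_epochs=40, seed=11)
    model, history, splits = train_pixel_classifier(ds, net, tc, seed=11)
    report = nb.evaluate_holdout(model, splits[2])
    return {"model": model, "dataset": ds, "splits": splits, "history": history,
            "report": report, "sim": sim}
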