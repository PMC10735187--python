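"""Kernel-PCA foreground separation and labeled pixel gathering."""

import numpy as np
import pytest

import nanobarcode as nb
from nanobarcode.masking import (
    DegenerateInputError,
    DegenerateRangeError,
    MaskingModel,
    compute_mask,
    fit_masking_model,
    gather_pixels,
)


def _stacks_with_pixels(n_pixels: int, seed: int = 0, channels: int = 3):
    """Plain arrays (H, W, C) stand in for stacks in masking unit tests."""
    rng = np.random.default_rng(seed)
    side = int(np.sqrt(n_pixels))
    assert side * side == n_pixels
    return rng.random((side, side, channels))


def test_fit_uses_exactly_4000_when_more_available():
    stacks = [_stacks_with_pixels(10_000, seed=i) for i in range(2)]
    model = fit_masking_model(stacks, seed=0)
    assert model.n_fit_pixels == 4000


def test_fit_uses_all_when_fewer_available():
    model = fit_masking_model([_stacks_with_pixels(100)], sample_size=4000, seed=0)
    assert model.n_fit_pixels == 100


def test_fit_rejects_constant_pixels():
    with pytest.raises(DegenerateInputError):
        fit_masking_model([np.ones((20, 20, 3))], seed=0)


def test_linear_kernel_matches_classical_pca():
    """Eigendecomposition oracle: linear-kernel scores equal the first
    principal component of the centered sample, up to sign."""
    rng = np.random.default_rng(1)
    data = rng.normal(0, 1, (50, 4)) * np.array([3.0, 1.0, 0.5, 0.1])
    model = fit_masking_model([data.reshape(5, 10, 4)], sample_size=50, kernel="linear", seed=0)
    scores = model.transform(data)
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / len(data)
    w, v = np.linalg.eigh(cov)
    pc1 = centered @ v[:, -1]
    corr = np.corrcoef(scores, pc1)[0, 1]
    assert abs(abs(corr) - 1) < 1e-8


class _RampModel(MaskingModel):
    """Transform stub: the oriented score is the first channel itself."""

    def __init__(self, relative_threshold=0.8):
        # bypass kPCA fitting entirely
        object.__setattr__(self, "kpca", None)
        self.kernel = "stub"
        self.orientation_sign = 1
        self.relative_threshold = relative_threshold
        self.fit_sample_size = 0
        self.n_fit_pixels = 0
        self.seed = None

    def transform(self, pixels, chunk=8192):
        return np.asarray(pixels, dtype=float)[:, 0]


def test_relative_threshold_retains_top_fraction_of_ramp():
    """A uniform ramp of transformed values over [0, 1] with the 0.8 rule
    keeps exactly the top 20% of pixels."""
    n = 1000
    ramp = np.linspace(0, 1, n).reshape(10, 100, 1)
    mask = compute_mask(_RampModel(0.8), ramp)
    assert mask.n_retained == 200
    kept_values = ramp.reshape(-1)[mask.mask.reshape(-1)]
    assert kept_values.min() >= 0.8 - 1e-12
    np.testing.assert_allclose(mask.threshold, 0.8)


def test_constant_transform_raises_degenerate_range():
    with pytest.raises(DegenerateRangeError):
        compute_mask(_RampModel(), np.full((5, 5, 1), 0.3))


def test_threshold_invariant_to_affine_rescaling():
    """The relative rule depends only on the score's rank geometry: any
    positive affine map of the transformed values gives the same mask."""
    rng = np.random.default_rng(3)
    img = rng.random((20, 20, 1))
    base = compute_mask(_RampModel(), img).mask
    for a, b in [(3.7, -2.0), (0.01, 5.0)]:
        scaled = compute_mask(_RampModel(), img * a + b).mask
        np.testing.assert_array_equal(scaled, base)


def test_mask_matches_truth_on_separated_populations(response_matrix, barcodes15):
    """Bright blobs over dim background: mask agrees with ground truth on
    >= 99% of pixels."""
    cfg = nb.SimConfig(height=64, width=64, amplitude_median=200.0,
                       amplitude_sigma_log=0.1, read_noise_sigma=1.0)
    stack, truth = nb.simulate_image(barcodes15[6], response_matrix, cfg, seed=8)
    model = fit_masking_model([stack], seed=8)
    mask = compute_mask(model, stack)
    assert (mask.mask == (truth.label_map > 0)).mean() >= 0.99


def test_mask_agreement_across_noise_grid(response_matrix, barcodes15):
    """Sweep of 3 read-noise levels x 3 seeds: mask/ground-truth agreement
    >= 95% across the grid.  Individual fields can dip slightly when a very
    bright cell stretches the transformed range and a dim cell falls under
    the 0.8 relative cut, so the 95% bound is on the sweep-wide agreement
    with a 90% floor per field."""
    agreements = []
    for noise in (1.0, 2.0, 4.0):
        for seed in (0, 1, 2):
            cfg = nb.SimConfig(height=64, width=64, read_noise_sigma=noise)
            stack, truth = nb.simulate_image(barcodes15[9], response_matrix, cfg,
                                             seed=seed)
            model = fit_masking_model([stack], seed=seed)
            mask = compute_mask(model, stack)
            agreements.append((mask.mask == (truth.label_map > 0)).mean())
    assert min(agreements) >= 0.90
    assert np.mean(agreements) >= 0.95


def _gather_items(n_fg: int, side: int = 200, seed: int = 0):
    rng = np.random.default_rng(seed)
    img = rng.random((side, side, 3))
    mask = np.zeros((side, side), dtype=bool)
    flat = rng.choice(side * side, size=n_fg, replace=False)
    mask[np.unravel_index(flat, (side, side))] = True
    return img, mask


def test_gather_caps_at_10000():
    img, mask = _gather_items(25_000)
    ds = gather_pixels([(img, mask, "1100")], blank_ratio=0, seed=0)
    assert int((ds.labels > 0).sum()) == 10_000


def test_gather_takes_all_when_below_cap():
    img, mask = _gather_items(500)
    ds = gather_pixels([(img, mask, "1100")], blank_ratio=0, seed=0)
    assert int((ds.labels > 0).sum()) == 500


def test_gather_blank_ratio():
    """1,000 foreground and ample background at ratio 10 -> 10,000 blanks."""
    img, mask = _gather_items(1000, side=200)
    ds = gather_pixels([(img, mask, "0001")], cap=10_000, blank_ratio=10, seed=0)
    assert int((ds.labels > 0).sum()) == 1000
    assert int((ds.labels == 0).sum()) == 10_000


def test_gather_no_duplicate_coordinates():
    img, mask = _gather_items(3000, side=100)
    ds = gather_pixels([(img, mask, "0001")], cap=2500, blank_ratio=1, seed=1)
    prov = ds.provenance
    coords = {tuple(row) for row in prov}
    assert len(coords) == len(prov)


def test_gather_reports_empty_class():
    img, mask = _gather_items(100)
    empty = np.zeros_like(mask)
    with pytest.warns(UserWarning, match="absent"):
        ds = gather_pixels([(img, mask, "a"), (img, empty, "b")], blank_ratio=0, seed=0)
    assert "b" in ds.class_names  # registry keeps it; no pixels carry it
    assert not (ds.labels == ds.class_names.index("b")).any()


def test_gather_determinism():
    img, mask = _gather_items(2000)
    a = gather_pixels([(img, mask, "x")], cap=500, blank_ratio=2, seed=5)
    b = gather_pixels([(img, mask, "x")], cap=500, blank_ratio=2, seed=5)
    np.testing.assert_array_equal(a.features, b.features)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_gather_blank_items_source():
    img, mask = _gather_items(1000)
    blank_img = np.random.default_rng(9).random((50, 50, 3))
    ds = gather_pixels([(img, mask, "x")], cap=500, blank_ratio=1, seed=0,
                       blank_items=[blank_img])
    blanks = ds.features[ds.labels == 0]
    assert len(blanks) == 500
    # every blank row must come from the dedicated blank field
    pool = blank_img.reshape(-1, 3)
    assert all(np.isclose(pool, row, atol=1e-6).all(axis=1).any() for row in blanks[:20])


def test_pixel_dataset_hdf5_round_trip(tmp_path, signature_dataset):
    path = tmp_path / "px.h5"
    signature_dataset.save(path)
    back = nb.PixelDataset.load(path)
    np.testing.assert_array_equal(back.features, signature_dataset.features)
    np.testing.assert_array_equal(back.labels, signature_dataset.labels)
    assert back.class_names == signature_dataset.class_names
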