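"""Synthetic multichannel confocal image generator with ground truth.

Emulates the 11-frame acquisition used for barcode readout: 10 fluorescence
frames (4 excitation lines crossed with the emission windows red-shifted of
each line) plus one brightfield frame.  Cells are blob-shaped regions drawn
from a thresholded smoothed random field; each cell expresses one barcode at
a log-normal amplitude (transfection-level variability).  Detected intensity
per channel follows the standard confocal noise decomposition

    I = gain * Poisson(amplitude * signature_c) + N(0, sigma_read) + background

clipped at zero.  The brightfield frame is a smoothed cell-density map used
only for overlay rendering, never as classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .barcodes import Barcode, SpectralResponseMatrix, barcode_signature

#: Emission window bounds in nm for the four detection channels.
EMISSION_WINDOWS: dict[str, tuple[int, int]] = {
    "CH1": (416, 485),
    "CH2": (494, 554),
    "CH3": (572, 632),
    "CH4": (641, 730),
}

BRIGHTFIELD = "brightfield"


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered 11-frame acquisition plan: excitation x emission window.

    ``frames`` lists 11 descriptors: ``(excitation_nm, window_name)`` tuples
    for fluorescence frames and the string ``"brightfield"`` for the single
    transmitted-light frame.
    """

    excitations: tuple[int, ...] = (405, 488, 561, 633)
    emission_windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(EMISSION_WINDOWS)
    )
    frames: tuple = (
        (405, "CH1"), (405, "CH2"), (405, "CH3"), (405, "CH4"),
        BRIGHTFIELD,
        (488, "CH2"), (488, "CH3"), (488, "CH4"),
        (561, "CH3"), (561, "CH4"),
        (633, "CH4"),
    )

    def __post_init__(self) -> None:
        n_bf = sum(1 for f in self.frames if f == BRIGHTFIELD)
        if n_bf != 1:
            raise ValueError(f"scheme must contain exactly one brightfield frame, got {n_bf}")
        for f in self.frames:
            if f == BRIGHTFIELD:
                continue
            exc, win = f
            lo, _ = self.emission_windows[win]
            if lo <= exc:
                raise ValueError(
                    f"emission window {win} ({lo} nm) must be red-shifted of excitation {exc} nm"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def fluorescence_frames(self) -> tuple:
        return tuple(f for f in self.frames if f != BRIGHTFIELD)

    @property
    def n_fluorescence(self) -> int:
        return len(self.fluorescence_frames)

    @property
    def brightfield_index(self) -> int:
        return self.frames.index(BRIGHTFIELD)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(f"{exc}/{win}" for exc, win in self.fluorescence_frames)

    def to_dict(self) -> dict:
        return {
            "excitations": list(self.excitations),
            "emission_windows": {k: list(v) for k, v in self.emission_windows.items()},
            "frames": [f if f == BRIGHTFIELD else list(f) for f in self.frames],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AcquisitionScheme":
        return cls(
            excitations=tuple(doc["excitations"]),
            emission_windows={k: tuple(v) for k, v in doc["emission_windows"].items()},
            frames=tuple(
                f if f == BRIGHTFIELD else (int(f[0]), str(f[1])) for f in doc["frames"]
            ),
        )


def default_scheme() -> AcquisitionScheme:
    return AcquisitionScheme()


@dataclass
class ChannelStack:
    """One field of view: H x W x 10 fluorescence plus optional brightfield."""

    fluorescence: np.ndarray
    brightfield: np.ndarray | None = None
    scheme: AcquisitionScheme = field(default_factory=default_scheme)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=np.float32)
        if self.fluorescence.ndim != 3:
            raise ValueError("fluorescence must be H x W x channels")
        if self.fluorescence.shape[2] != self.scheme.n_fluorescence:
            raise ValueError(
                f"stack has {self.fluorescence.shape[2]} channels, scheme expects "
                f"{self.scheme.n_fluorescence}"
            )
        if (self.fluorescence < 0).any():
            raise ValueError("fluorescence intensities must be non-negative")
        if self.brightfield is not None:
            self.brightfield = np.asarray(self.brightfield, dtype=np.float32)
            if self.brightfield.shape != self.fluorescence.shape[:2]:
                raise ValueError("brightfield dimensions must match fluorescence")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fluorescence.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.fluorescence.shape[2]

    def pixels(self) -> np.ndarray:
        """Flattened (H*W, channels) view of intensities, scaled to [0, ~1].

        Intensities are divided by the full-scale value of the recorded bit
        depth so network inputs are resolution- and detector-independent.
        """
        scale = float(2**self.bit_depth - 1)
        return (self.fluorescence.reshape(-1, self.n_channels) / scale).astype(np.float32)


@dataclass
class GroundTruth:
    """Per-pixel class index (0 = blank) and expression amplitude."""

    label_map: np.ndarray
    amplitude_map: np.ndarray

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=np.int32)
        self.amplitude_map = np.asarray(self.amplitude_map, dtype=np.float32)
        if self.label_map.shape != self.amplitude_map.shape:
            raise ValueError("label and amplitude maps must share dimensions")
        if (self.amplitude_map[self.label_map == 0] != 0).any():
            raise ValueError("amplitude must be zero on blank pixels")


@dataclass
class SimConfig:
    """Study conditions for one simulated field of view.

    Amplitudes are in expected-photon units at the matched frame of each
    fluorophore (response rows peak at 1.0): ``amplitude_median`` is the
    log-normal median, ``amplitude_sigma_log`` the log-space spread across
    cells.  ``background`` and ``read_noise_sigma`` are in detector counts.
    """

    height: int = 128
    width: int = 128
    foreground_fraction: float = 0.15
    blob_sigma: float = 6.0
    amplitude_median: float = 120.0
    amplitude_sigma_log: float = 0.5
    gain: float = 1.0
    poisson: bool = True
    read_noise_sigma: float = 2.0
    background: float = 5.0
    barcodes_per_image: int = 1
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image size must be positive")
        if not (0 <= self.foreground_fraction < 1):
            raise ValueError("foreground fraction must be in [0, 1)")
        for name in ("amplitude_median", "amplitude_sigma_log", "gain",
                     "read_noise_sigma", "background", "blob_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _cell_field(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Blob-shaped foreground mask from a thresholded smoothed random field."""
    if cfg.foreground_fraction == 0:
        return np.zeros((cfg.height, cfg.width), dtype=bool)
    noise = rng.standard_normal((cfg.height, cfg.width))
    smooth = ndimage.gaussian_filter(noise, cfg.blob_sigma, mode="wrap")
    cut = np.quantile(smooth, 1 - cfg.foreground_fraction)
    return smooth > cut


def simulate_image(
    barcode: Barcode | Sequence[Barcode],
    matrix: SpectralResponseMatrix,
    cfg: SimConfig = SimConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[ChannelStack, GroundTruth]:
    """Simulate one field of view expressing one or several barcodes.

    Each connected blob is one cell: it is assigned a barcode (cyclically by
    blob when several barcodes share the scene, emulating mixed cultures)
    and a single log-normal expression amplitude.  Identical inputs and seed
    give bit-identical output.
    """
    barcodes = [barcode] if isinstance(barcode, Barcode) else list(barcode)
    if not barcodes:
        raise ValueError("at least one barcode is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mask = _cell_field(cfg, rng)
    cells, n_cells = ndimage.label(mask)

    label_map = np.zeros((cfg.height, cfg.width), dtype=np.int32)
    amplitude_map = np.zeros((cfg.height, cfg.width), dtype=np.float32)
    signatures = [barcode_signature(b, matrix) for b in barcodes]

    # assign barcodes per cell: shuffled cyclic draw keeps classes balanced
    order = rng.permutation(len(barcodes))
    for cell_id in range(1, n_cells + 1):
        cls = int(order[(cell_id - 1) % len(barcodes)]) + 1
        amp = cfg.amplitude_median * np.exp(cfg.amplitude_sigma_log * rng.standard_normal())
        inside = cells == cell_id
        label_map[inside] = cls
        amplitude_map[inside] = amp

    expected = np.zeros((cfg.height, cfg.width, matrix.n_channels), dtype=float)
    for cls in range(1, len(barcodes) + 1):
        inside = label_map == cls
        if inside.any():
            expected[inside] = amplitude_map[inside, None] * signatures[cls - 1][None, :]

    if cfg.poisson:
        signal = cfg.gain * rng.poisson(expected).astype(float)
    else:
        signal = cfg.gain * expected
    if cfg.read_noise_sigma > 0:
        signal = signal + rng.normal(0.0, cfg.read_noise_sigma, size=signal.shape)
    fluor = np.clip(signal + cfg.background, 0, None)

    density = ndimage.gaussian_filter(mask.astype(float), max(cfg.blob_sigma / 2, 1.0))
    brightfield = np.clip(
        100.0 - 40.0 * density + rng.normal(0.0, 1.0, size=density.shape), 0, None
    )

    stack = ChannelStack(fluor, brightfield, bit_depth=cfg.bit_depth)
    return stack, GroundTruth(label_map, amplitude_map)


def simulate_blank_image(
    matrix: SpectralResponseMatrix,
    cfg: SimConfig = SimConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[ChannelStack, GroundTruth]:
    """Field with no nanobarcode expression: background noise only.

    Untransfected cells carry no fluorophores, so their fluorescence frames
    are indistinguishable from background; the brightfield still shows
    cells.  Used to gather clean blank training samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _cell_field(cfg, rng)
    zeros = np.zeros((cfg.height, cfg.width, matrix.n_channels), dtype=float)
    signal = cfg.gain * rng.poisson(zeros).astype(float) if cfg.poisson else zeros
    if cfg.read_noise_sigma > 0:
        signal = signal + rng.normal(0.0, cfg.read_noise_sigma, size=signal.shape)
    fluor = np.clip(signal + cfg.background, 0, None)
    density = ndimage.gaussian_filter(mask.astype(float), max(cfg.blob_sigma / 2, 1.0))
    brightfield = np.clip(
        100.0 - 40.0 * density + rng.normal(0.0, 1.0, size=density.shape), 0, None
    )
    shape = (cfg.height, cfg.width)
    truth = GroundTruth(np.zeros(shape, dtype=np.int32), np.zeros(shape, dtype=np.float32))
    return ChannelStack(fluor, brightfield, bit_depth=cfg.bit_depth), truth


def simulate_dataset(
    barcodes: Sequence[Barcode],
    images_per_class: int,
    matrix: SpectralResponseMatrix,
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
) -> list[tuple[ChannelStack, GroundTruth, str]]:
    """Single-transfect image collection: one barcode per image, with labels.

    Returns ``len(barcodes) * images_per_class`` items ``(stack, truth,
    barcode_label)``; deterministic under a fixed seed.
    """
    if not barcodes:
        raise ValueError("barcode list must be non-empty")
    if images_per_class < 1:
        raise ValueError("images_per_class must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(len(barcodes) * images_per_class)
    out = []
    k = 0
    for b in barcodes:
        for _ in range(images_per_class):
            rng = np.random.default_rng(seeds[k])
            k += 1
            stack, truth = simulate_image(b, matrix, cfg, rng)
            out.append((stack, truth, b.label))
    return out


def single_pixel_config(**overrides) -> SimConfig:
    """Noise-free config with deterministic amplitude, handy for oracles."""
    base = SimConfig(
        poisson=False, read_noise_sigma=0.0, background=0.0,
        amplitude_sigma_log=0.0, gain=1.0,
    )
    return replace(base, **overrides)
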