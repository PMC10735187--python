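"""Stack and configuration I/O honoring the 11-frame acquisition layout.

Stacks are exchanged as multi-page TIFF with pages in the exact acquisition
order (frames 1-4: 405 nm excitation, frame 5: brightfield, frames 6-8:
488 nm, frames 9-10: 561 nm, frame 11: 633 nm under the default scheme).
Frame 5 is routed to the brightfield slot on read and never reaches the 10
classifier input channels.  A JSON sidecar carries the scheme, bit depth
and, for simulated data, a pointer to the ground-truth arrays.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .network import NetworkConfig
from .simulate import AcquisitionScheme, ChannelStack, GroundTruth, SimConfig, default_scheme
from .training import TrainConfig


class StackFormatError(ValueError):
    """Raised when a file does not match the expected frame layout."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ChannelStack, path, ground_truth: GroundTruth | None = None) -> Path:
    """Write a stack as a multi-page TIFF in scheme frame order, plus sidecar."""
    path = Path(path)
    scheme = stack.scheme
    pages = []
    ch = 0
    for frame in scheme.frames:
        if frame == "brightfield":
            bf = stack.brightfield
            pages.append(np.zeros(stack.shape, dtype=np.float32) if bf is None else bf)
        else:
            pages.append(stack.fluorescence[:, :, ch])
            ch += 1
    tifffile.imwrite(path, np.stack(pages).astype(np.float32), metadata={"axes": "QYX"})

    sidecar = {
        "scheme": scheme.to_dict(),
        "bit_depth": stack.bit_depth,
    }
    if ground_truth is not None:
        gt_path = path.with_name(path.stem + "_gt.npz")
        np.savez(gt_path, label_map=ground_truth.label_map,
                 amplitude_map=ground_truth.amplitude_map)
        sidecar["ground_truth"] = gt_path.name
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def read_stack(path, scheme: AcquisitionScheme | None = None) -> ChannelStack:
    """Read an 11-page stack, routing the brightfield frame out of the channels."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    bit_depth = 16
    if scheme is None:
        if sidecar_file.exists():
            with open(sidecar_file) as fh:
                doc = json.load(fh)
            scheme = AcquisitionScheme.from_dict(doc["scheme"])
            bit_depth = int(doc.get("bit_depth", 16))
        else:
            scheme = default_scheme()
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise StackFormatError(f"cannot read {path} as a multi-page TIFF: {exc}") from exc
    pages = np.atleast_3d(pages)
    if pages.ndim != 3 or pages.shape[0] != scheme.n_frames:
        raise StackFormatError(
            f"{path} has {pages.shape[0]} page(s); the acquisition scheme expects "
            f"{scheme.n_frames} frames ({scheme.n_fluorescence} fluorescence + 1 brightfield)"
        )
    fluor, brightfield = [], None
    for frame, page in zip(scheme.frames, pages):
        if frame == "brightfield":
            brightfield = page
        else:
            fluor.append(page)
    return ChannelStack(
        np.stack(fluor, axis=-1), brightfield, scheme=scheme, bit_depth=bit_depth
    )


def read_ground_truth(path) -> GroundTruth | None:
    """Load the ground-truth arrays referenced by a stack's sidecar, if any."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        return None
    with open(sidecar_file) as fh:
        doc = json.load(fh)
    if "ground_truth" not in doc:
        return None
    data = np.load(path.with_name(doc["ground_truth"]))
    return GroundTruth(data["label_map"], data["amplitude_map"])


@dataclasses.dataclass
class RunConfig:
    """Composite configuration for one reproducible pipeline run."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)
    training: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    mask_sample_size: int = 4000
    mask_relative_threshold: float = 0.8
    gather_cap: int = 10_000
    blank_ratio: float = 10.0
    adapt_steps: int = 50
    master_seed: int = 0
    log_level: str = "INFO"

    def seeds(self, n: int) -> list[int]:
        """Per-component seeds derived deterministically from the master seed."""
        return [int(s.generate_state(1)[0] % (2**31))
                for s in np.random.SeedSequence(self.master_seed).spawn(n)]

    def save(self, path) -> None:
        doc = {
            "sim": dataclasses.asdict(self.sim),
            "network": dataclasses.asdict(self.network),
            "training": dataclasses.asdict(self.training),
            "mask_sample_size": self.mask_sample_size,
            "mask_relative_threshold": self.mask_relative_threshold,
            "gather_cap": self.gather_cap,
            "blank_ratio": self.blank_ratio,
            "adapt_steps": self.adapt_steps,
            "master_seed": self.master_seed,
            "log_level": self.log_level,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        def _tup(d, key):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        tr = doc.get("training", {})
        _tup(tr, "split_fractions")
        _tup(tr, "contrast_range")
        return cls(
            sim=SimConfig(**doc.get("sim", {})),
            network=NetworkConfig(**doc.get("network", {})),
            training=TrainConfig(**tr),
            **{k: doc[k] for k in (
                "mask_sample_size", "mask_relative_threshold", "gather_cap",
                "blank_ratio", "adapt_steps", "master_seed", "log_level",
            ) if k in doc},
        )
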