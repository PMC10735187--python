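"""Combinatorial epitope barcodes and their expected spectral signatures.

A *nanobarcode* is an on/off combination of epitope tags fused to a protein
of interest.  Each epitope slot is detected by a nanobody carrying one
fluorophore, so a barcode of ``n`` epitopes is one of ``2**n - 1`` nonempty
on/off patterns (the all-zero pattern is background, not a barcode).  With
the default 4 slots this gives the familiar 15 distinguishable codes.

The expected multichannel intensity of a barcode is a linear superposition
of the per-fluorophore spectral responses, including bleed-through into
off-target excitation/emission frames.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

#: Epitope slot order used throughout: one fluorophore-conjugated nanobody
#: per slot, listed left to right as the code strings are printed.
EPITOPE_SLOTS: tuple[str, ...] = ("mCherry(Y71L)", "GFP(Y66L)", "syn87", "syn2")

#: Fluorophores matched 1:1 to the epitope slots.
FLUOROPHORES: tuple[str, ...] = ("DyLight405", "Atto488", "Atto565", "Star635P")


@dataclass(frozen=True)
class Barcode:
    """One nonempty on/off epitope combination.

    Parameters
    ----------
    bits
        Binary vector over epitope slots, slot order as in
        :data:`EPITOPE_SLOTS`.  At least one bit must be set.
    protein_name
        Optional free-text name of the tagged protein; ignored for equality.
    """

    bits: tuple[int, ...]
    protein_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"barcode bits must be 0/1, got {self.bits!r}")
        if not any(bits):
            raise ValueError("a valid barcode has at least one epitope set")
        object.__setattr__(self, "bits", bits)

    @property
    def label(self) -> str:
        """Code string, e.g. ``'1100'``: bits concatenated in slot order."""
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_label(cls, label: str, protein_name: str | None = None) -> "Barcode":
        if not label or set(label) - {"0", "1"}:
            raise ValueError(f"barcode label must be a nonempty 0/1 string, got {label!r}")
        return cls(tuple(int(c) for c in label), protein_name)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_barcodes(n_epitopes: int) -> list[Barcode]:
    """All ``2**n_epitopes - 1`` valid barcodes, in lexicographic label order.

    The all-zero pattern is excluded: it is the blank/background class,
    which is represented outside :class:`Barcode`.
    """
    if not isinstance(n_epitopes, (int, np.integer)) or n_epitopes < 1:
        raise ValueError(f"n_epitopes must be a positive integer, got {n_epitopes!r}")
    out = []
    for value in range(1, 2**n_epitopes):
        label = format(value, f"0{n_epitopes}b")
        out.append(Barcode.from_label(label))
    return out


@dataclass(frozen=True)
class SpectralResponseMatrix:
    """Expected per-channel intensity of one unit of each fluorophore.

    ``response[i, c]`` is the intensity that one abundance unit of
    ``fluorophores[i]`` contributes to fluorescence channel ``c``.  Rows are
    scaled so the matched excitation/emission frame carries the maximum;
    off-frame entries model bleed-through.  A rank-4 matrix guarantees that
    all 15 four-epitope barcodes have distinct noise-free signatures.
    """

    fluorophores: tuple[str, ...]
    channels: tuple[str, ...]
    response: np.ndarray

    def __post_init__(self) -> None:
        resp = np.asarray(self.response, dtype=float)
        if resp.shape != (len(self.fluorophores), len(self.channels)):
            raise ValueError(
                f"response shape {resp.shape} does not match "
                f"{len(self.fluorophores)} fluorophores x {len(self.channels)} channels"
            )
        if (resp < 0).any():
            raise ValueError("spectral responses must be non-negative")
        resp.flags.writeable = False
        object.__setattr__(self, "response", resp)
        object.__setattr__(self, "fluorophores", tuple(self.fluorophores))
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.response))

    def to_yaml(self, path) -> None:
        doc = {
            "fluorophores": list(self.fluorophores),
            "channels": list(self.channels),
            "response": {f: [float(v) for v in row] for f, row in zip(self.fluorophores, self.response)},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "SpectralResponseMatrix":
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                doc = yaml.safe_load(fh)
        fluors = tuple(doc["fluorophores"])
        channels = tuple(doc["channels"])
        resp = np.array([doc["response"][f] for f in fluors], dtype=float)
        return cls(fluors, channels, resp)


def default_response_matrix() -> SpectralResponseMatrix:
    """The versioned reference response matrix shipped with the package."""
    ref = importlib.resources.files("nanobarcode.data") / "response_matrix.yaml"
    with ref.open() as fh:
        return SpectralResponseMatrix.from_yaml(fh)


def barcode_signature(
    barcode: Barcode | Sequence[int],
    matrix: SpectralResponseMatrix,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Expected noise-free channel intensities of ``amplitude`` units of a barcode.

    Linear superposition: the sum of the response rows of the set epitope
    slots, scaled by ``amplitude``.  A raw bit sequence is accepted so the
    degenerate all-zero pattern (blank) can be evaluated to the zero vector.
    """
    bits = barcode.bits if isinstance(barcode, Barcode) else tuple(int(b) for b in barcode)
    if len(bits) != matrix.response.shape[0]:
        raise ValueError(
            f"barcode has {len(bits)} slots but response matrix has "
            f"{matrix.response.shape[0]} fluorophores"
        )
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    sig = np.zeros(matrix.n_channels, dtype=float)
    for bit, row in zip(bits, matrix.response):
        if bit:
            sig += row
    return amplitude * sig


def signature_table(
    barcodes: Iterable[Barcode], matrix: SpectralResponseMatrix
) -> np.ndarray:
    """Stacked unit-amplitude signatures, one row per barcode."""
    return np.stack([barcode_signature(b, matrix) for b in barcodes])
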