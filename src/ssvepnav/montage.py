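"""Schematic scalp montage for the 32-channel 10-20 layout.

Coordinates are 2-D schematic positions on a unit disc (head radius 1,
nose up: +y anterior, +x right), obtained by azimuthal-equidistant
projection of the standard 10-20 spherical electrode positions. They are
used only to parameterise the simulator's spatial gain maps and for
topography plotting conventions, not for source modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "standard_montage_32", "STANDARD_32_POSITIONS"]

# BioSemi-style 32-channel 10-20 set. x: left(-)/right(+), y: posterior(-)/anterior(+).
STANDARD_32_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.281, 0.921),
    "AF3": (-0.282, 0.754),
    "F7": (-0.772, 0.633),
    "F3": (-0.396, 0.534),
    "FC1": (-0.231, 0.277),
    "FC5": (-0.704, 0.312),
    "T7": (-0.993, 0.000),
    "C3": (-0.480, 0.032),
    "CP1": (-0.221, -0.189),
    "CP5": (-0.683, -0.258),
    "P7": (-0.744, -0.581),
    "P3": (-0.380, -0.441),
    "Pz": (0.000, -0.399),
    "PO3": (-0.286, -0.646),
    "O1": (-0.264, -0.835),
    "Oz": (0.000, -0.842),
    "O2": (0.251, -0.839),
    "PO4": (0.276, -0.654),
    "P4": (0.382, -0.437),
    "P8": (0.741, -0.586),
    "CP6": (0.687, -0.251),
    "CP2": (0.226, -0.188),
    "C4": (0.482, 0.038),
    "T8": (0.995, 0.012),
    "FC6": (0.701, 0.321),
    "FC2": (0.225, 0.284),
    "F4": (0.394, 0.546),
    "F8": (0.766, 0.643),
    "AF4": (0.278, 0.752),
    "Fp2": (0.264, 0.926),
    "Fz": (0.000, 0.504),
    "Cz": (0.000, 0.041),
}


@dataclass(frozen=True)
class Montage:
    """An ordered set of EEG channels with schematic 2-D scalp positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channel_names), 2):
            raise ValueError(
                f"positions must be ({len(self.channel_names)}, 2), got {pos.shape}"
            )
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        """Index of channel *name*; raises ``KeyError`` for unknown labels."""
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel label: {name!r}") from None

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]


def standard_montage_32() -> Montage:
    """The default 32-channel 10-20 montage used by the simulator."""
    names = tuple(STANDARD_32_POSITIONS)
    pos = np.array([STANDARD_32_POSITIONS[n] for n in names])
    return Montage(channel_names=names, positions=pos)
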