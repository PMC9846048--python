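"""In-memory container for a multi-channel 2-D fluorescence section.

A section is a set of named single-channel rasters sharing one pixel grid,
as produced by splitting a multi-channel micrograph (e.g. a GAD reference
channel plus one or more immunomarker channels). Coordinates are row-major
with the origin at the top-left pixel; the ventral-to-dorsal anatomical axis
maps to increasing column index by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

from .errors import ConfigError

__all__ = ["MultiChannelImage"]


@dataclass
class MultiChannelImage:
    """Named 2-D intensity rasters on one pixel grid.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"GAD"``, ``"C3"``) to a 2-D array.
        All arrays must share one shape.
    bit_depth
        Nominal acquisition bit depth (8 or 16); used to locate the
        saturation ceiling ``2**bit_depth - 1``.
    """

    channels: Dict[str, np.ndarray]
    bit_depth: int = 16
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigError("a MultiChannelImage needs at least one channel")
        if self.bit_depth not in (8, 16):
            raise ConfigError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ConfigError(f"channels must be 2-D rasters, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ConfigError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.channels)

    @property
    def saturation_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)
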