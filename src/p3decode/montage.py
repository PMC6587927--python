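"""64-channel extended 10-20 montage with a packaged 2-D head-disk layout."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .constants import ROI_CHANNELS


@dataclass(frozen=True)
class MontageSpec:
    """A fixed electrode layout: names plus 2-D positions on the unit head disk."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(self.channel_names) != 64:
            raise ValueError(f"montage must have exactly 64 channels, got {len(self.channel_names)}")
        if self.positions.shape != (64, 2):
            raise ValueError(f"positions must be (64, 2), got {self.positions.shape}")
        missing = [ch for ch in ROI_CHANNELS if ch not in self.channel_names]
        if missing:
            raise ValueError(f"montage lacks ROI channels: {missing}")
        if len({tuple(p) for p in np.round(self.positions, 9)}) != 64:
            raise ValueError("electrode positions must be unique")

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def roi_indices(self, roi: tuple[str, ...] = ROI_CHANNELS) -> np.ndarray:
        return np.array([self.index(ch) for ch in roi])


def standard_montage() -> MontageSpec:
    """Load the packaged 64-channel layout (no download required)."""
    path = resources.files("p3decode.data").joinpath("montage64.tsv")
    names: list[str] = []
    pos: list[tuple[float, float]] = []
    with path.open() as fh:
        next(fh)  # header
        for line in fh:
            name, x, y = line.rstrip("\n").split("\t")
            names.append(name)
            pos.append((float(x), float(y)))
    return MontageSpec(tuple(names), np.asarray(pos, dtype=float))
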