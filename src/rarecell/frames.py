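"""Scan-grid geometry and in-memory frame containers for fluorescent whole-slide images.

A slide is scanned as a rectangular grid of stage positions; at every position one
image is acquired per immunofluorescence channel. The four channels are DAPI (D,
nuclear), cytokeratin (CK, epithelial), Vimentin (V, mesenchymal) and the combined
CD45/CD31 leukocyte/endothelial channel (CD). A full-scale slide uses a 48 x 48
grid (2304 positions), i.e. 9216 frames of view per slide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order used throughout the package.
CHANNELS: tuple[str, ...] = ("D", "CK", "V", "CD")

#: Full-scale scan grid (2304 stage positions).
FULL_GRID = (48, 48)


@dataclass(frozen=True)
class FrameGrid:
    """Rectangular scan grid of stage positions with a fixed channel list.

    Frame positions are indexed either linearly (row-major ``pos``) or as
    ``(row, col)``; a *frame of view* is one (position, channel) pair.
    """

    rows: int
    cols: int
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if len(self.channels) < 1 or len(set(self.channels)) != len(self.channels):
            raise ValueError("channels must be a non-empty unique list")

    @property
    def n_positions(self) -> int:
        return self.rows * self.cols

    @property
    def n_frames(self) -> int:
        """Total frames of view: positions x channels."""
        return self.n_positions * len(self.channels)

    def position_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"position ({row}, {col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def position_rc(self, pos: int) -> tuple[int, int]:
        if not 0 <= pos < self.n_positions:
            raise IndexError(f"position {pos} outside grid of {self.n_positions}")
        return divmod(pos, self.cols)

    def enumerate_frames(self) -> list[tuple[int, int, str]]:
        """Enumerate every frame of view as ``(row, col, channel)``."""
        return [
            (r, c, ch)
            for r in range(self.rows)
            for c in range(self.cols)
            for ch in self.channels
        ]


@dataclass
class FrameStack:
    """One slide's frames in memory.

    ``data`` has shape ``(n_positions, n_channels, height, width)`` with dtype
    uint16 (arbitrary fluorescence counts).
    """

    grid: FrameGrid
    data: np.ndarray
    slide_id: str = "slide"
    _chan_idx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        expect = (self.grid.n_positions, len(self.grid.channels))
        if self.data.ndim != 4 or self.data.shape[:2] != expect:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid "
                f"({expect[0]} positions x {expect[1]} channels)"
            )
        self._chan_idx = {ch: i for i, ch in enumerate(self.grid.channels)}

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def frame(self, pos: int, channel: str) -> np.ndarray:
        return self.data[pos, self._chan_idx[channel]]

    def channel_index(self, channel: str) -> int:
        return self._chan_idx[channel]
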