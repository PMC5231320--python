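"""In-memory containers for per-cell multi-channel image data.

An imaging flow cytometer captures several spatially registered grayscale
images (bright-field, dark-field/side-scatter, optional fluorescence) for
every cell in flow.  These containers hold one channel frame
(:class:`ChannelImage`), one cell (:class:`CellRecord`), a population
(:class:`ImageSet`) and a tiled grid of cell frames (:class:`Montage`).

Intensities are floating point in [0, 1] in memory; on disk they are
16-bit unsigned (see :mod:`ifcml.imageset_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed cell-cycle class order used everywhere downstream.
PHASES: tuple[str, ...] = ("Int", "Pro", "Meta", "Ana", "Telo")

#: Sentinel for an unoccupied montage slot.
EMPTY = ""


@dataclass
class ChannelImage:
    """One channel of one cell: a 2-D grid of intensities in [0, 1]."""

    channel_label: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError(
                f"channel {self.channel_label!r}: pixels must be a non-empty 2-D array"
            )
        if np.nanmin(self.pixels) < 0 or np.nanmax(self.pixels) > 1:
            raise ValueError(
                f"channel {self.channel_label!r}: intensities must lie in [0, 1]"
            )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class CellRecord:
    """One cell: an ordered mapping of channel label -> ChannelImage.

    ``label`` is the optional ground-truth cell-cycle phase, one of
    :data:`PHASES`, or ``None`` when unannotated.
    """

    cell_id: str
    channels: dict[str, ChannelImage]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError(f"cell {self.cell_id!r}: at least one channel required")
        shapes = {im.pixels.shape for im in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(
                f"cell {self.cell_id!r}: channels are not spatially registered "
                f"(shapes {sorted(shapes)})"
            )
        if self.label is not None and self.label not in PHASES:
            raise ValueError(
                f"cell {self.cell_id!r}: unknown phase label {self.label!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.pixels.shape


@dataclass
class ImageSet:
    """An ordered collection of cells sharing one channel layout."""

    cells: list[CellRecord]
    channel_labels: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cell in self.cells:
            if cell.cell_id in seen:
                raise ValueError(f"duplicate cell_id {cell.cell_id!r} in ImageSet")
            seen.add(cell.cell_id)
            if list(cell.channels) != list(self.channel_labels):
                raise ValueError(
                    f"cell {cell.cell_id!r}: channels {list(cell.channels)} != "
                    f"ImageSet channel_labels {list(self.channel_labels)}"
                )

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def labels(self) -> dict[str, str | None]:
        return {c.cell_id: c.label for c in self.cells}


@dataclass
class Montage:
    """A row-major grid of equally sized cell frames for one channel.

    ``slot_map`` maps slot index (row-major) to cell_id, or :data:`EMPTY`
    for unoccupied slots.  Frame padding offsets are recorded separately in
    the slot table (see :func:`ifcml.imageset_io.pack_montages`).
    """

    channel_label: str
    grid_rows: int
    grid_cols: int
    cell_h: int
    cell_w: int
    pixels: np.ndarray
    slot_map: dict[int, str]
    pad_value: float = 0.0
    tile_index: int = 0

    def __post_init__(self) -> None:
        expected = (self.grid_rows * self.cell_h, self.grid_cols * self.cell_w)
        if tuple(self.pixels.shape) != expected:
            raise ValueError(
                f"montage pixels shape {self.pixels.shape} != expected {expected}"
            )
        occupied = [cid for cid in self.slot_map.values() if cid != EMPTY]
        if len(occupied) != len(set(occupied)):
            raise ValueError("montage slot_map contains a duplicate cell_id")
        if len(self.slot_map) > self.grid_rows * self.grid_cols:
            raise ValueError("more slots than grid positions")

    def slot_view(self, slot: int) -> np.ndarray:
        """Return the pixel block of one slot (no copy)."""
        r, c = divmod(slot, self.grid_cols)
        if not (0 <= r < self.grid_rows):
            raise IndexError(f"slot {slot} outside {self.grid_rows}x{self.grid_cols} grid")
        return self.pixels[
            r * self.cell_h : (r + 1) * self.cell_h,
            c * self.cell_w : (c + 1) * self.cell_w,
        ]
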