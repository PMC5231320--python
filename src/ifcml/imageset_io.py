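"""Portable on-disk container and montage packing for per-cell image sets.

Layout written by :func:`write_imageset`::

    <dir>/manifest.csv          cell_id,file,label   (one row per cell)
    <dir>/container.json        channel order, bit depth, quantization scale
    <dir>/cells/<cell_id>.tif   multi-page 16-bit TIFF, one page per channel

Montages pack many cell frames into one grid image per channel per tile,
mirroring the tiled-image protocol used to batch-process ~1000 cells per
image.  Packing is lossless: each cell's original frame size and centering
offset are recorded in a slot table so :func:`unpack_montages` restores the
original pixels exactly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import EMPTY, CellRecord, ChannelImage, ImageSet, Montage

#: On-disk quantization scale (16-bit unsigned).
QUANT_SCALE = 65535


def _to_uint16(pixels: np.ndarray) -> np.ndarray:
    return np.round(np.clip(pixels, 0.0, 1.0) * QUANT_SCALE).astype(np.uint16)


def _from_uint16(raw: np.ndarray, scale: int = QUANT_SCALE) -> np.ndarray:
    return raw.astype(np.float64) / float(scale)


def write_imageset(imageset: ImageSet, path: str | Path) -> Path:
    """Write an ImageSet as per-cell multi-page TIFFs plus a CSV manifest.

    Returns the manifest path.  Raises ``ValueError`` on duplicate cell ids
    (enforced by :class:`ImageSet` construction) and ``OSError`` when the
    target is not writable.
    """
    path = Path(path)
    cells_dir = path / "cells"
    cells_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for cell in imageset:
        fname = f"cells/{cell.cell_id}.tif"
        pages = np.stack(
            [_to_uint16(cell.channels[ch].pixels) for ch in imageset.channel_labels]
        )
        tifffile.imwrite(path / fname, pages, photometric="minisblack")
        rows.append(
            {"cell_id": cell.cell_id, "file": fname, "label": cell.label or ""}
        )
    manifest = path / "manifest.csv"
    pd.DataFrame(rows, columns=["cell_id", "file", "label"]).to_csv(
        manifest, index=False
    )
    meta = {
        "channel_labels": list(imageset.channel_labels),
        "bit_depth": 16,
        "quantization_scale": QUANT_SCALE,
        "provenance": imageset.provenance,
    }
    (path / "container.json").write_text(json.dumps(meta, indent=2))
    return manifest


def read_imageset(path: str | Path) -> ImageSet:
    """Read a container written by :func:`write_imageset`.

    Cells are returned in manifest row order; phase labels are parsed when
    present.  A manifest row whose TIFF is missing raises ``IOError`` naming
    the cell_id; a page-count mismatch raises ``ValueError``.
    """
    path = Path(path)
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise IOError(f"no manifest.csv under {path}")
    meta = json.loads((path / "container.json").read_text())
    channel_labels = list(meta["channel_labels"])
    scale = int(meta.get("quantization_scale", QUANT_SCALE))

    table = pd.read_csv(manifest, dtype=str, keep_default_na=False)
    cells: list[CellRecord] = []
    for row in table.itertuples(index=False):
        fpath = path / row.file
        if not fpath.exists():
            raise IOError(f"cell {row.cell_id!r}: image file {row.file} is missing")
        pages = tifffile.imread(fpath)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != len(channel_labels):
            raise ValueError(
                f"cell {row.cell_id!r}: {pages.shape[0]} pages != "
                f"{len(channel_labels)} channels"
            )
        channels = {
            ch: ChannelImage(ch, _from_uint16(pages[i], scale))
            for i, ch in enumerate(channel_labels)
        }
        label = row.label if row.label else None
        cells.append(CellRecord(row.cell_id, channels, label))
    return ImageSet(cells, channel_labels, provenance=meta.get("provenance", ""))


# ---------------------------------------------------------------------------
# Montage packing
# ---------------------------------------------------------------------------

SLOT_COLUMNS = ["tile", "slot", "cell_id", "orig_h", "orig_w", "off_r", "off_c"]


def _grid_shape(n: int) -> tuple[int, int]:
    cols = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / cols))
    return rows, cols


def _border_median(pixels: np.ndarray) -> float:
    if pixels.shape[0] < 3 or pixels.shape[1] < 3:
        return float(np.median(pixels))
    border = np.concatenate(
        [pixels[0], pixels[-1], pixels[1:-1, 0], pixels[1:-1, -1]]
    )
    return float(np.median(border))


def _pad_value_for(channel_label: str, pixels: np.ndarray) -> float:
    # BF background is bright and non-zero; padding with the border median
    # avoids an artificial dark rim.  Dark-field-like channels pad with 0.
    if channel_label == "BF":
        return _border_median(pixels)
    return 0.0


def pack_montages(
    imageset: ImageSet, tile_capacity: int
) -> tuple[list[Montage], pd.DataFrame]:
    """Tile an ImageSet into grid montages, one per channel per tile.

    Cells are taken in manifest order, at most ``tile_capacity`` per tile;
    the grid is square-ish (``cols = ceil(sqrt(n))``).  Within a tile every
    frame is centered in a slot of the tile's maximum frame size, and the
    original size/offset is recorded in the returned slot table so that
    unpacking is pixel-exact.
    """
    if tile_capacity < 1:
        raise ValueError("tile_capacity must be >= 1")
    if len(imageset) == 0:
        raise ValueError("cannot pack an empty ImageSet")

    montages: list[Montage] = []
    slot_rows: list[dict] = []
    cells = list(imageset.cells)
    n_tiles = math.ceil(len(cells) / tile_capacity)
    for t in range(n_tiles):
        tile_cells = cells[t * tile_capacity : (t + 1) * tile_capacity]
        n = len(tile_cells)
        rows, cols = _grid_shape(n)
        cell_h = max(c.shape[0] for c in tile_cells)
        cell_w = max(c.shape[1] for c in tile_cells)

        offsets = {}
        for slot, cell in enumerate(tile_cells):
            h, w = cell.shape
            off_r, off_c = (cell_h - h) // 2, (cell_w - w) // 2
            offsets[slot] = (h, w, off_r, off_c)
            slot_rows.append(
                {
                    "tile": t,
                    "slot": slot,
                    "cell_id": cell.cell_id,
                    "orig_h": h,
                    "orig_w": w,
                    "off_r": off_r,
                    "off_c": off_c,
                }
            )

        for ch in imageset.channel_labels:
            pad_values = [
                _pad_value_for(ch, cell.channels[ch].pixels) for cell in tile_cells
            ]
            tile_pad = float(np.median(pad_values))
            canvas = np.full((rows * cell_h, cols * cell_w), tile_pad, dtype=np.float64)
            slot_map: dict[int, str] = {
                s: EMPTY for s in range(rows * cols)
            }
            for slot, cell in enumerate(tile_cells):
                h, w, off_r, off_c = offsets[slot]
                gr, gc = divmod(slot, cols)
                block = np.full((cell_h, cell_w), pad_values[slot], dtype=np.float64)
                block[off_r : off_r + h, off_c : off_c + w] = cell.channels[ch].pixels
                canvas[
                    gr * cell_h : (gr + 1) * cell_h, gc * cell_w : (gc + 1) * cell_w
                ] = block
                slot_map[slot] = cell.cell_id
            montages.append(
                Montage(
                    channel_label=ch,
                    grid_rows=rows,
                    grid_cols=cols,
                    cell_h=cell_h,
                    cell_w=cell_w,
                    pixels=canvas,
                    slot_map=slot_map,
                    pad_value=tile_pad,
                    tile_index=t,
                )
            )
    slot_table = pd.DataFrame(slot_rows, columns=SLOT_COLUMNS)
    return montages, slot_table


def unpack_montages(
    montages: list[Montage],
    slot_table: pd.DataFrame,
    labels: dict[str, str | None] | None = None,
    provenance: str = "",
) -> ImageSet:
    """Invert :func:`pack_montages`, restoring original per-cell frames.

    Cells come back in (tile, slot) order.  Raises ``ValueError`` on a slot
    table inconsistent with the montage grids or containing duplicate ids.
    """
    if slot_table["cell_id"].duplicated().any():
        dup = slot_table.loc[slot_table["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"slot table contains duplicate cell_id {dup!r}")
    by_tile: dict[int, dict[str, Montage]] = {}
    for m in montages:
        by_tile.setdefault(m.tile_index, {})[m.channel_label] = m
    channel_labels: list[str] | None = None
    for tile_montages in by_tile.values():
        labels_here = list(tile_montages)
        if channel_labels is None:
            channel_labels = labels_here
        elif labels_here != channel_labels:
            raise ValueError("tiles disagree on channel layout")
    if channel_labels is None:
        return ImageSet([], [], provenance=provenance)

    cells: list[CellRecord] = []
    for row in slot_table.sort_values(["tile", "slot"]).itertuples(index=False):
        tile_montages = by_tile.get(int(row.tile))
        if tile_montages is None:
            raise ValueError(f"slot table references missing tile {row.tile}")
        channels = {}
        for ch in channel_labels:
            m = tile_montages[ch]
            if int(row.slot) >= m.grid_rows * m.grid_cols:
                raise ValueError(
                    f"slot {row.slot} outside montage grid of tile {row.tile}"
                )
            if m.slot_map.get(int(row.slot), EMPTY) != row.cell_id:
                raise ValueError(
                    f"slot map mismatch at tile {row.tile} slot {row.slot}: "
                    f"expected {row.cell_id!r}"
                )
            block = m.slot_view(int(row.slot))
            frame = block[
                int(row.off_r) : int(row.off_r) + int(row.orig_h),
                int(row.off_c) : int(row.off_c) + int(row.orig_w),
            ]
            channels[ch] = ChannelImage(ch, frame.copy())
        label = labels.get(row.cell_id) if labels else None
        cells.append(CellRecord(row.cell_id, channels, label))
    return ImageSet(cells, channel_labels, provenance=provenance)


def write_montages(
    montages: list[Montage], slot_table: pd.DataFrame, path: str | Path
) -> Path:
    """Persist montages as 16-bit TIFFs plus a slot-map CSV; returns the CSV path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = []
    for m in montages:
        fname = f"tile{m.tile_index:04d}_{m.channel_label}.tif"
        tifffile.imwrite(path / fname, _to_uint16(m.pixels), photometric="minisblack")
        meta.append(
            {
                "file": fname,
                "tile": m.tile_index,
                "channel": m.channel_label,
                "grid_rows": m.grid_rows,
                "grid_cols": m.grid_cols,
                "cell_h": m.cell_h,
                "cell_w": m.cell_w,
                "pad_value": m.pad_value,
            }
        )
    slot_csv = path / "slot_map.csv"
    slot_table.to_csv(slot_csv, index=False)
    pd.DataFrame(meta).to_csv(path / "montages.csv", index=False)
    return slot_csv


def read_montages(path: str | Path) -> tuple[list[Montage], pd.DataFrame]:
    """Read montages written by :func:`write_montages`."""
    path = Path(path)
    meta = pd.read_csv(path / "montages.csv")
    slot_table = pd.read_csv(
        path / "slot_map.csv", dtype={"cell_id": str}, keep_default_na=False
    )
    montages = []
    for row in meta.itertuples(index=False):
        pixels = _from_uint16(tifffile.imread(path / row.file))
        n_slots = int(row.grid_rows) * int(row.grid_cols)
        slot_map = {s: EMPTY for s in range(n_slots)}
        sel = slot_table[slot_table["tile"] == row.tile]
        for srow in sel.itertuples(index=False):
            slot_map[int(srow.slot)] = srow.cell_id
        montages.append(
            Montage(
                channel_label=row.channel,
                grid_rows=int(row.grid_rows),
                grid_cols=int(row.grid_cols),
                cell_h=int(row.cell_h),
                cell_w=int(row.cell_w),
                pixels=pixels,
                slot_map=slot_map,
                pad_value=float(row.pad_value),
                tile_index=int(row.tile),
            )
        )
    return montages, slot_table
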