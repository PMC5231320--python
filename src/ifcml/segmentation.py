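"""Bright-field cell segmentation: one primary object mask per frame.

The container convention fixes bright-field polarity (cells darker than
background), so the frame is inverted, thresholded globally by Otsu's
criterion, closed with a small disk (bridges thin telophase necks), holes
are filled, and the largest 8-connected component is kept.  Frames with no
component of at least ``min_area`` pixels yield an EMPTY mask, signalled
as ``None`` — the caller gates such cells out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ChannelImage, ImageSet


@dataclass
class SegmentationParams:
    min_area: int = 9
    closing_radius: int = 2
    invert: bool = True  # bright-field: cells darker than background


def segment_cell_frame(
    bf: ChannelImage | np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray | None:
    """Segment one bright-field frame; returns a boolean mask or ``None``
    (EMPTY) when nothing of at least ``min_area`` px is found."""
    params = params or SegmentationParams()
    pixels = bf.pixels if isinstance(bf, ChannelImage) else np.asarray(bf, float)
    work = -pixels if params.invert else pixels
    if np.ptp(work) <= 1e-12:
        return None
    thr = threshold_otsu(work)
    binary = work > thr
    if params.closing_radius > 0:
        binary = ndimage.binary_closing(
            binary, structure=disk(params.closing_radius)
        )
    binary = ndimage.binary_fill_holes(binary)

    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best_area = areas.max()
    if best_area < params.min_area:
        return None
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # deterministic tie-break: component owning the top-most, left-most pixel
        keep = None
        flat = labels.ravel()
        for lab in flat:
            if lab in candidates:
                keep = lab
                break
    return labels == keep


def segment_imageset(
    imageset: ImageSet, params: SegmentationParams | None = None
) -> dict[str, np.ndarray | None]:
    """Segment every cell's BF frame; EMPTY masks are returned as ``None``."""
    params = params or SegmentationParams()
    out: dict[str, np.ndarray | None] = {}
    for cell in imageset:
        if "BF" not in cell.channels:
            raise ValueError(f"cell {cell.cell_id!r} has no BF channel")
        out[cell.cell_id] = segment_cell_frame(cell.channels["BF"], params)
    return out


class CellSegmenter(TransformerMixin, BaseEstimator):
    """Stateless transformer: ImageSet -> {cell_id: mask or None}."""

    def __init__(self, min_area: int = 9, closing_radius: int = 2, invert: bool = True):
        self.min_area = min_area
        self.closing_radius = closing_radius
        self.invert = invert

    def fit(self, X: ImageSet, y=None):
        return self

    def transform(self, X: ImageSet) -> dict[str, np.ndarray | None]:
        params = SegmentationParams(self.min_area, self.closing_radius, self.invert)
        return segment_imageset(X, params)
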