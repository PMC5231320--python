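"""Per-cell, per-channel morphological and intensity feature bank.

Implements the feature families of CellProfiler-style image cytometry
profiling on a single masked cell frame:

* **AreaShape** — area, boundary-chain perimeter, moment-based axis
  lengths and eccentricity, compactness, max Feret diameter, distance-
  transform radii, orientation, and rotation-invariant Zernike moment
  magnitudes up to order 9.
* **Intensity** — integrated/mean/lower-quartile intensity, edge
  intensities over the 8-connected inner boundary, mass displacement.
* **RadialDistribution** — FracAtD / MeanFrac / RadialCV over 4
  concentric rings defined by the normalized interior distance transform
  (robust for non-star-shaped dumbbells) and 8 angular wedges.
* **Granularity** — the spectrum of intensity removed by grayscale
  openings of increasing disk radius, as a percentage of the background-
  corrected total; element 1 captures fine-grained texture.
* **Texture** — Haralick information measure of correlation 2 (InfoMeas2)
  from a symmetric gray-level co-occurrence matrix at a fixed offset.

Feature names follow the ``{CHN}_{Family}_{Name}[_{image}][_{suffix}]``
convention, with the bright-field channel prefixed ``BF_`` and the
dark-field/side-scatter channel ``SSC_`` (image tag ``DF_image``), e.g.
``SSC_Granularity_1_DF_image`` and ``BF_Texture_InfoMeas2_BF_image_3_0``.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import disk, opening
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CellRecord, ChannelImage, ImageSet

__all__ = [
    "measure_area_shape",
    "zernike_magnitudes",
    "measure_intensity",
    "measure_radial_distribution",
    "granularity_spectrum",
    "glcm_infomeas2",
    "extract_features",
    "extract_features_table",
    "build_registry",
    "FeatureExtractor",
]

#: Name fragments excluded from classification by default (positional or
#: orientational, carry no phenotype information).
DEFAULT_EXCLUDED_FRAGMENTS = ("Orientation", "Location", "Center")


def _require_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return mask


# ---------------------------------------------------------------------------
# AreaShape
# ---------------------------------------------------------------------------

_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _chain_perimeter(mask: np.ndarray) -> float:
    """Boundary chain length via Moore-neighbor tracing (sqrt(2) per
    diagonal step).  Single-pixel masks have zero chain length."""
    coords = np.argwhere(mask)
    if coords.shape[0] == 1:
        return 0.0
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    start = tuple(coords[np.lexsort((coords[:, 1], coords[:, 0]))][0] + 1)

    def next_boundary(cur, backtrack):
        dr, dc = backtrack[0] - cur[0], backtrack[1] - cur[1]
        k = _MOORE.index((dr, dc))
        for step in range(1, 9):
            cand_off = _MOORE[(k + step) % 8]
            cand = (cur[0] + cand_off[0], cur[1] + cand_off[1])
            if padded[cand]:
                prev_off = _MOORE[(k + step - 1) % 8]
                return cand, (cur[0] + prev_off[0], cur[1] + prev_off[1])
        return None, None  # isolated pixel

    first, bt = next_boundary(start, (start[0], start[1] - 1))
    if first is None:
        return 0.0
    perimeter = math.hypot(first[0] - start[0], first[1] - start[1])
    cur, prev = first, start
    limit = 4 * coords.shape[0] + 8
    for _ in range(limit):
        nxt, bt = next_boundary(cur, bt)
        perimeter += math.hypot(nxt[0] - cur[0], nxt[1] - cur[1])
        prev, cur = cur, nxt
        if prev == start and cur == first:
            # closed the contour; remove the duplicated first step
            perimeter -= math.hypot(first[0] - start[0], first[1] - start[1])
            break
    return perimeter


def _second_moments(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    return centered.T @ centered / coords.shape[0]


def _max_feret(coords: np.ndarray) -> float:
    pts = coords.astype(float)
    if pts.shape[0] >= 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def measure_area_shape(mask: np.ndarray) -> dict[str, float]:
    """Mask-only shape descriptors (one 8-connected object assumed)."""
    mask = _require_mask(mask)
    coords = np.argwhere(mask)
    area = float(coords.shape[0])
    perimeter = _chain_perimeter(mask)

    cov = _second_moments(coords)
    eigvals = np.sort(np.linalg.eigvalsh(cov))
    minor = 4.0 * math.sqrt(max(eigvals[0], 0.0))
    major = 4.0 * math.sqrt(max(eigvals[1], 0.0))
    ecc = math.sqrt(max(1.0 - (minor / major) ** 2, 0.0)) if major > 0 else 0.0

    dt = ndimage.distance_transform_edt(mask)
    radii = dt[mask]
    orientation = 0.5 * math.degrees(
        math.atan2(2.0 * cov[0, 1], cov[1, 1] - cov[0, 0])
    )
    return {
        "Area": area,
        "Perimeter": perimeter,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Eccentricity": ecc,
        "Compactness": perimeter**2 / (4.0 * math.pi * area),
        "MaxFeretDiameter": _max_feret(coords),
        "MeanRadius": float(radii.mean()),
        "MaximumRadius": float(radii.max()),
        "Orientation": orientation,
    }


# ---------------------------------------------------------------------------
# Zernike moments
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _zernike_radial_coeffs(n: int, m: int) -> tuple[tuple[int, float], ...]:
    """Coefficients (power, weight) of the radial polynomial R_nm."""
    terms = []
    for s in range((n - m) // 2 + 1):
        num = (-1) ** s * math.factorial(n - s)
        den = (
            math.factorial(s)
            * math.factorial((n + m) // 2 - s)
            * math.factorial((n - m) // 2 - s)
        )
        terms.append((n - 2 * s, num / den))
    return tuple(terms)


def zernike_orders(max_order: int = 9) -> list[tuple[int, int]]:
    return [
        (n, m)
        for n in range(max_order + 1)
        for m in range(n + 1)
        if (n - m) % 2 == 0
    ]


def _disk_point_count(centroid: np.ndarray, rmax: float) -> int:
    """Grid points within rmax of the (fractional) centroid, on an
    unbounded grid — independent of frame clipping."""
    r = int(math.ceil(rmax)) + 1
    ys = np.arange(math.floor(centroid[0]) - r, math.ceil(centroid[0]) + r + 1)
    xs = np.arange(math.floor(centroid[1]) - r, math.ceil(centroid[1]) + r + 1)
    dy = (ys - centroid[0])[:, None]
    dx = (xs - centroid[1])[None, :]
    return int(np.count_nonzero(dy**2 + dx**2 <= (rmax * (1 + 1e-12)) ** 2))


def zernike_magnitudes(mask: np.ndarray, max_order: int = 9) -> dict[str, float]:
    """Rotation-invariant Zernike moment magnitudes ``Zernike_n_m``.

    The mask is mapped to the unit disk centered at its centroid with
    radius equal to the farthest mask pixel; normalization is anchored so
    a solid disk gives ``Zernike_0_0 = 1``.
    """
    mask = _require_mask(mask)
    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    dist = np.hypot(rel[:, 0], rel[:, 1])
    rmax = dist.max()

    out: dict[str, float] = {}
    if rmax == 0:  # single pixel: all mass at the origin
        for n, m in zernike_orders(max_order):
            out[f"Zernike_{n}_{m}"] = 1.0 if (n, m) == (0, 0) else 0.0
        return out

    rho = dist / rmax
    theta = np.arctan2(rel[:, 0], rel[:, 1])
    n_disk = _disk_point_count(centroid, rmax)
    for n, m in zernike_orders(max_order):
        radial = np.zeros_like(rho)
        for power, weight in _zernike_radial_coeffs(n, m):
            radial += weight * rho**power
        moment = np.sum(radial * np.exp(-1j * m * theta))
        out[f"Zernike_{n}_{m}"] = float((n + 1) / n_disk * abs(moment))
    return out


# ---------------------------------------------------------------------------
# Intensity
# ---------------------------------------------------------------------------

def _inner_boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return mask & ~eroded


def measure_intensity(
    image: ChannelImage | np.ndarray, mask: np.ndarray
) -> dict[str, float]:
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image, float)
    mask = _require_mask(mask)
    if pixels.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    vals = pixels[mask]
    edge = _inner_boundary(mask)
    edge_vals = pixels[edge]

    total = float(vals.sum())
    coords = np.argwhere(mask).astype(float)
    binary_centroid = coords.mean(axis=0)
    if total > 0:
        weights = pixels[mask]
        intensity_centroid = (coords * weights[:, None]).sum(axis=0) / total
        displacement = float(np.hypot(*(intensity_centroid - binary_centroid)))
    else:
        displacement = 0.0  # zero total intensity: displacement undefined
    return {
        "IntegratedIntensity": total,
        "MeanIntensity": float(vals.mean()),
        "LowerQuartileIntensity": float(np.percentile(vals, 25)),
        "IntegratedIntensityEdge": float(edge_vals.sum()),
        "MeanIntensityEdge": float(edge_vals.mean()),
        "MinIntensityEdge": float(edge_vals.min()),
        "MassDisplacement": displacement,
    }


# ---------------------------------------------------------------------------
# Radial distribution
# ---------------------------------------------------------------------------

def measure_radial_distribution(
    image: ChannelImage | np.ndarray,
    mask: np.ndarray,
    n_rings: int = 4,
    n_wedges: int = 8,
) -> dict[str, float]:
    """FracAtD / MeanFrac / RadialCV over concentric distance-transform rings.

    Each mask pixel gets normalized radius ``r = 1 - DT/max(DT)`` (0 at the
    innermost point, 1 at the edge); ring k covers ``[(k-1)/K, k/K)`` with
    the last ring closed.  RadialCV is SD/mean of the ring's per-wedge
    mean intensities over equal angular wedges about the centroid (empty
    wedges excluded; count-normalized so rasterization of small rings does
    not masquerade as angular variation).  Empty rings yield NaN sentinels.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image, float)
    mask = _require_mask(mask)
    if pixels.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    dt = ndimage.distance_transform_edt(mask)
    dtmax = dt[mask].max()
    r = 1.0 - (dt / dtmax if dtmax > 0 else np.ones_like(dt))
    ring_idx = np.minimum((r * n_rings).astype(int), n_rings - 1)

    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    theta = np.arctan2(yy - centroid[0], xx - centroid[1])
    # half-open modular binning: each wedge owns exactly one boundary ray,
    # so symmetric objects spread boundary pixels evenly over wedges
    wedge_idx = np.floor((theta + np.pi) / (2 * np.pi) * n_wedges).astype(int) % n_wedges

    total = pixels[mask].sum()
    n_mask = mask.sum()
    out: dict[str, float] = {}
    for k in range(n_rings):
        ring = mask & (ring_idx == k)
        suffix = f"{k + 1}of{n_rings}"
        count = int(ring.sum())
        ring_sum = float(pixels[ring].sum()) if count else 0.0
        frac = ring_sum / total if total > 0 else 0.0
        out[f"FracAtD_{suffix}"] = frac
        if count == 0:
            out[f"MeanFrac_{suffix}"] = float("nan")
            out[f"RadialCV_{suffix}"] = float("nan")
            continue
        out[f"MeanFrac_{suffix}"] = frac / (count / n_mask)
        wedge_means = []
        for w in range(n_wedges):
            sel = ring & (wedge_idx == w)
            if sel.any():
                wedge_means.append(pixels[sel].mean())
        wm = np.asarray(wedge_means)
        mean = wm.mean()
        out[f"RadialCV_{suffix}"] = float(wm.std() / mean) if mean > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# Granularity
# ---------------------------------------------------------------------------

def granularity_spectrum(
    image: ChannelImage | np.ndarray,
    mask: np.ndarray,
    max_radius: int = 8,
    bg_radius: int = 10,
) -> np.ndarray:
    """Granularity spectrum ``g_1..g_max`` (percent of intensity removed
    per opening radius step, after background correction).

    The masked image (background zeroed) is background-corrected by
    subtracting its grayscale opening with a large disk; ``g_k`` is the
    percentage of the corrected total erased when the opening radius grows
    from k-1 to k.  Fine-grained texture loads onto ``g_1``.
    """
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image, float)
    mask = np.asarray(mask, dtype=bool)
    if pixels.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    img = np.where(mask, pixels, 0.0)
    background = opening(img, disk(bg_radius))
    corrected = np.clip(img - background, 0.0, None)
    s0 = corrected.sum()
    if s0 <= 0:
        return np.zeros(max_radius)
    spectrum = np.empty(max_radius)
    prev = s0
    for k in range(1, max_radius + 1):
        sk = opening(corrected, disk(k)).sum()
        spectrum[k - 1] = 100.0 * (prev - sk) / s0
        prev = sk
    return spectrum


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------

def glcm_infomeas2(
    image: ChannelImage | np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int] = (0, 3),
    levels: int = 8,
) -> float:
    """Haralick information measure of correlation 2 in [0, 1).

    Masked pixels are quantized to ``levels`` equal-width bins over the
    masked min-max range; the co-occurrence matrix accumulates symmetric
    pixel pairs at ``offset`` with both pixels inside the mask.  Constant
    regions and offsets with no valid pairs return 0 by convention.
    """
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image, float)
    mask = _require_mask(mask)
    if pixels.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    vals = pixels[mask]
    vmin, vmax = vals.min(), vals.max()
    if vmax - vmin <= 0:
        return 0.0
    quant = np.clip(
        ((pixels - vmin) / (vmax - vmin) * levels).astype(int), 0, levels - 1
    )

    dr, dc = offset
    h, w = mask.shape
    src = np.zeros_like(mask)
    src[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)] = True
    valid = mask & src
    shifted_mask = np.roll(np.roll(mask, -dr, axis=0), -dc, axis=1)
    valid &= shifted_mask
    if not valid.any():
        return 0.0
    i = quant[valid]
    j = np.roll(np.roll(quant, -dr, axis=0), -dc, axis=1)[valid]

    P = np.zeros((levels, levels))
    np.add.at(P, (i, j), 1.0)
    P = P + P.T  # symmetric accumulation
    P /= P.sum()

    nz = P[P > 0]
    hxy = -np.sum(nz * np.log2(nz))
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    outer = np.outer(px, py)
    nz_outer = outer[outer > 0]
    hxy2 = -np.sum(nz_outer * np.log2(nz_outer))
    return float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _channel_naming(label: str) -> tuple[str, str]:
    """Map a channel label to its (feature prefix, image tag)."""
    if label == "BF":
        return "BF", "BF_image"
    if label in ("DF", "SSC"):
        return "SSC", "DF_image"
    return label, f"{label}_image"


def extract_features(
    cell: CellRecord,
    mask: np.ndarray,
    channels: list[str] | None = None,
    max_zernike_order: int = 9,
    n_rings: int = 4,
    n_wedges: int = 8,
    granularity_max_radius: int = 8,
    granularity_bg_radius: int = 10,
    glcm_offset: tuple[int, int] = (0, 3),
    glcm_levels: int = 8,
) -> dict[str, float]:
    """Full named feature vector for one cell (>= 90 features for BF+DF).

    Shape features are computed once from the mask (named under the BF
    prefix, since the mask derives from bright-field); intensity, radial,
    granularity and texture features are computed per channel.
    """
    channels = list(channels) if channels is not None else list(cell.channels)
    missing = [ch for ch in channels if ch not in cell.channels]
    if missing:
        raise ValueError(f"cell {cell.cell_id!r} lacks channels {missing}")

    values: dict[str, float] = {}
    for name, v in measure_area_shape(mask).items():
        values[f"BF_AreaShape_{name}"] = v
    for name, v in zernike_magnitudes(mask, max_zernike_order).items():
        values[f"BF_AreaShape_{name}"] = v

    for ch in channels:
        prefix, tag = _channel_naming(ch)
        image = cell.channels[ch]
        for name, v in measure_intensity(image, mask).items():
            values[f"{prefix}_Intensity_{name}_{tag}"] = v
        radial = measure_radial_distribution(image, mask, n_rings, n_wedges)
        for name, v in radial.items():
            base, suffix = name.rsplit("_", 1)
            values[f"{prefix}_RadialDistribution_{base}_{tag}_{suffix}"] = v
        spectrum = granularity_spectrum(
            image, mask, granularity_max_radius, granularity_bg_radius
        )
        for k, v in enumerate(spectrum, start=1):
            values[f"{prefix}_Granularity_{k}_{tag}"] = float(v)
        infomeas2 = glcm_infomeas2(image, mask, glcm_offset, glcm_levels)
        dr, dc = glcm_offset
        scale = max(abs(dr), abs(dc))
        direction = 0 if dr == 0 else 90
        values[f"{prefix}_Texture_InfoMeas2_{tag}_{scale}_{direction}"] = infomeas2
    return values


def build_registry(feature_names: list[str]) -> pd.DataFrame:
    """Column registry: family, channel and excluded-by-default flag per
    feature (plays the role of a classifier properties file)."""
    rows = []
    for name in feature_names:
        parts = name.split("_")
        rows.append(
            {
                "feature": name,
                "channel": parts[0],
                "family": parts[1] if len(parts) > 1 else "",
                "excluded_by_default": any(
                    frag in name for frag in DEFAULT_EXCLUDED_FRAGMENTS
                ),
            }
        )
    return pd.DataFrame(rows, columns=["feature", "channel", "family", "excluded_by_default"])


def extract_features_table(
    imageset: ImageSet,
    masks: dict[str, np.ndarray],
    channels: list[str] | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table (rows = cells with a non-empty mask) plus registry.

    Cells whose mask is EMPTY (``None``) are skipped; cells with NaN
    sentinels in any feature remain in the table and are up to the caller
    to flag.
    """
    rows = {}
    for cell in imageset:
        mask = masks.get(cell.cell_id)
        if mask is None:
            continue
        rows[cell.cell_id] = extract_features(cell, mask, channels, **kwargs)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "cell_id"
    registry = build_registry(list(table.columns))
    return table, registry


class FeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer: (ImageSet, masks) -> feature DataFrame.

    ``transform`` accepts a ``(imageset, masks)`` tuple so the extractor
    can sit behind a segmentation step in a composed pipeline.
    """

    def __init__(
        self,
        channels: list[str] | None = None,
        max_zernike_order: int = 9,
        n_rings: int = 4,
        n_wedges: int = 8,
        granularity_max_radius: int = 8,
        granularity_bg_radius: int = 10,
        glcm_offset: tuple[int, int] = (0, 3),
        glcm_levels: int = 8,
    ):
        self.channels = channels
        self.max_zernike_order = max_zernike_order
        self.n_rings = n_rings
        self.n_wedges = n_wedges
        self.granularity_max_radius = granularity_max_radius
        self.granularity_bg_radius = granularity_bg_radius
        self.glcm_offset = glcm_offset
        self.glcm_levels = glcm_levels

    def fit(self, X, y=None):
        return self

    def transform(self, X: tuple[ImageSet, dict[str, np.ndarray]]) -> pd.DataFrame:
        imageset, masks = X
        table, self.registry_ = extract_features_table(
            imageset,
            masks,
            channels=self.channels,
            max_zernike_order=self.max_zernike_order,
            n_rings=self.n_rings,
            n_wedges=self.n_wedges,
            granularity_max_radius=self.granularity_max_radius,
            granularity_bg_radius=self.granularity_bg_radius,
            glcm_offset=self.glcm_offset,
            glcm_levels=self.glcm_levels,
        )
        return table
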