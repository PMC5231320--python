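"""Synthetic bright-field/dark-field cell populations with known ground truth.

Emulates the study conditions of a label-free cell-cycle experiment on an
imaging flow cytometer: five classes (interphase and the four mitotic
phases) with extreme class imbalance — thousands of interphase cells
against tens of anaphase/telophase cells — plus the contaminants a QC step
must remove (debris, doublets, defocused frames).

Phase-dependent appearance, chosen so that phases differ in the same
feature families that drive the real classification (size, elongation,
lobe count, and chromatin-condensation texture that shows up as dark-field
granularity):

====== ==========================================================
Int    near-circular disk, smooth low-amplitude texture
Pro    disk of similar size, fine-grained high-amplitude texture
       (condensed chromatin -> strong dark-field granularity)
Meta   elongated ellipse (eccentricity ~0.9, the metaphase plate)
Ana    dumbbell: two lobes with a wide neck
Telo   dumbbell with wider separation and a thin (<= 2 px) neck
====== ==========================================================

Bright-field polarity is fixed: cells are darker than the background.
Dark-field intensity is proportional to local texture energy (granular
cells scatter more).  All randomness flows from a single seeded generator,
so identical configs give byte-identical containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import PHASES, CellRecord, ChannelImage, ImageSet

BF_BACKGROUND = 0.8
BF_BODY = 0.45
DF_BACKGROUND = 0.02
DF_BODY = 0.25


@dataclass
class PhaseParams:
    """Geometry and texture parameters for one phase (all lengths in px)."""

    phase: str
    radius_mean: float
    radius_sd: float
    eccentricity_range: tuple[float, float] = (0.0, 0.25)
    lobe_separation: float = 0.0
    neck_width: float = 0.0
    texture_grain_sd: float = 2.0
    texture_amplitude: float = 0.1
    df_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")
        if self.lobe_separation < 0:
            raise ValueError("lobe_separation must be non-negative")
        if not (0.0 <= self.texture_amplitude <= 0.5):
            raise ValueError("texture_amplitude must lie in [0, 0.5]")
        lo, hi = self.eccentricity_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("eccentricity_range must be a sub-interval of [0, 1)")


def default_phase_params() -> dict[str, PhaseParams]:
    return {
        "Int": PhaseParams("Int", 8.0, 0.5, (0.0, 0.25),
                           texture_grain_sd=3.0, texture_amplitude=0.05, df_gain=0.8),
        "Pro": PhaseParams("Pro", 8.0, 0.5, (0.0, 0.25),
                           texture_grain_sd=0.9, texture_amplitude=0.30, df_gain=1.0),
        "Meta": PhaseParams("Meta", 9.5, 0.5, (0.88, 0.92),
                            texture_grain_sd=1.6, texture_amplitude=0.15, df_gain=0.9),
        "Ana": PhaseParams("Ana", 7.0, 0.5, lobe_separation=22.0, neck_width=5.0,
                           texture_grain_sd=1.6, texture_amplitude=0.15, df_gain=0.9),
        "Telo": PhaseParams("Telo", 6.5, 0.5, lobe_separation=30.0, neck_width=2.0,
                            texture_grain_sd=1.6, texture_amplitude=0.15, df_gain=0.9),
    }


#: Default per-phase counts: the printed rare-class sizes (15 anaphase,
#: 25 telophase) with the overrepresented classes scaled down ~100x.
DEFAULT_COUNTS: dict[str, int] = {"Int": 300, "Pro": 38, "Meta": 16, "Ana": 15, "Telo": 25}


@dataclass
class SimulationConfig:
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    debris_frac: float = 0.0
    doublet_frac: float = 0.0
    defocus_frac: float = 0.0
    defocus_sigma: float = 3.0
    frame_size: int = 56
    noise_sd: float = 0.01
    seed: int = 0
    phase_params: dict[str, PhaseParams] = field(default_factory=default_phase_params)

    def __post_init__(self) -> None:
        for phase, n in self.counts.items():
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r} in counts")
            if n < 0:
                raise ValueError("counts must be non-negative")
        fracs = (self.debris_frac, self.doublet_frac, self.defocus_frac)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("contaminant fractions must lie in [0, 1]")
        if sum(fracs) > 1.0:
            raise ValueError("contaminant fractions must sum to <= 1")


@dataclass
class Population:
    """A generated ImageSet with its ground truth."""

    imageset: ImageSet
    truth: pd.DataFrame  # columns: cell_id, phase, contaminant
    gt_masks: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _coord_grids(frame_size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (frame_size - 1) / 2.0
    yy, xx = np.mgrid[0:frame_size, 0:frame_size]
    return yy - c, xx - c


def _ellipse_mask(frame_size: int, a: float, b: float, theta: float) -> np.ndarray:
    yy, xx = _coord_grids(frame_size)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    v = -xx * np.sin(theta) + yy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _dumbbell_mask(
    frame_size: int, lobe_radius: float, separation: float,
    neck_width: float, theta: float,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    yy, xx = _coord_grids(frame_size)
    d = separation / 2.0
    cx, cy = d * np.cos(theta), d * np.sin(theta)
    lobe1 = (xx - cx) ** 2 + (yy - cy) ** 2 <= lobe_radius**2
    lobe2 = (xx + cx) ** 2 + (yy + cy) ** 2 <= lobe_radius**2
    mask = lobe1 | lobe2
    if neck_width > 0:
        # distance from each pixel to the segment joining the lobe centers
        axis = np.array([np.cos(theta), np.sin(theta)])
        t = np.clip(xx * axis[0] + yy * axis[1], -d, d)
        dist = np.hypot(xx - t * axis[0], yy - t * axis[1])
        mask |= dist <= neck_width / 2.0
    c = (frame_size - 1) / 2.0
    centers = [(c + cy, c + cx), (c - cy, c - cx)]
    return mask, centers


def _phase_geometry(
    phase: str, params: PhaseParams, frame_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    theta = rng.uniform(0.0, np.pi)
    r = max(2.0, rng.normal(params.radius_mean, params.radius_sd))
    c = (frame_size - 1) / 2.0
    if params.lobe_separation > 0:
        sep = max(2.0 * r * 0.8, params.lobe_separation + rng.normal(0.0, 1.0))
        extent = sep + 2 * r
        if extent > frame_size - 4:
            raise ValueError(
                f"{phase}: geometry extent {extent:.0f} px does not fit a "
                f"{frame_size} px frame"
            )
        return _dumbbell_mask(frame_size, r, sep, params.neck_width, theta)
    ecc = rng.uniform(*params.eccentricity_range)
    shrink = (1.0 - ecc**2) ** 0.25
    a, b = r / shrink, r * shrink
    if 2 * a > frame_size - 4:
        raise ValueError(
            f"{phase}: major axis {2 * a:.0f} px does not fit a {frame_size} px frame"
        )
    return _ellipse_mask(frame_size, a, b, theta), [(c, c)]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _texture_field(
    frame_size: int, grain_sd: float, rng: np.random.Generator
) -> np.ndarray:
    t = gaussian_filter(rng.standard_normal((frame_size, frame_size)), grain_sd)
    sd = t.std()
    return t / sd if sd > 0 else t


def _render(
    mask: np.ndarray, params: PhaseParams, frame_size: int,
    noise_sd: float, rng: np.random.Generator, blur_sigma: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    t = _texture_field(frame_size, params.texture_grain_sd, rng)
    # BF speckle at half the nominal amplitude: keeps the body contrast
    # segmentable while the full amplitude drives dark-field granularity
    bf_body = np.clip(BF_BODY * (1.0 + 0.5 * params.texture_amplitude * t), 0.05, 0.65)
    bf = np.where(mask, bf_body, BF_BACKGROUND)
    # dark-field: flat baseline plus positive speckle whose grain size and
    # amplitude track chromatin condensation -> granularity contrast
    df_body = params.df_gain * (DF_BODY + 0.7 * params.texture_amplitude * np.maximum(t, 0.0))
    df = np.where(mask, df_body, DF_BACKGROUND)
    if blur_sigma > 0:
        bf = gaussian_filter(bf, blur_sigma)
        df = gaussian_filter(df, blur_sigma)
    if noise_sd > 0:
        bf = bf + rng.normal(0.0, noise_sd, bf.shape)
        df = df + rng.normal(0.0, noise_sd, df.shape)
    return np.clip(bf, 0.0, 1.0), np.clip(df, 0.0, 1.0)


def generate_cell(
    phase: str,
    params: PhaseParams,
    rng: np.random.Generator,
    frame_size: int = 56,
    noise_sd: float = 0.01,
    cell_id: str = "cell00000",
    blur_sigma: float = 0.0,
) -> tuple[CellRecord, dict]:
    """Generate one labeled BF/DF cell.

    Returns the record and a ground-truth dict with the rasterized mask and
    lobe centers.  Raises ``ValueError`` when the phase geometry cannot fit
    the frame.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    mask, centers = _phase_geometry(phase, params, frame_size, rng)
    bf, df = _render(mask, params, frame_size, noise_sd, rng, blur_sigma)
    record = CellRecord(
        cell_id, {"BF": ChannelImage("BF", bf), "DF": ChannelImage("DF", df)}, phase
    )
    return record, {"mask": mask, "lobe_centers": centers}


def _debris_cell(
    cfg: SimulationConfig, rng: np.random.Generator, cell_id: str, phase: str
) -> tuple[CellRecord, dict]:
    radius = rng.uniform(1.0, 2.5)
    mask = _ellipse_mask(cfg.frame_size, radius, radius, 0.0)
    params = PhaseParams("Int", radius, 0.0, texture_amplitude=0.05, texture_grain_sd=1.0)
    bf, df = _render(mask, params, cfg.frame_size, cfg.noise_sd, rng)
    record = CellRecord(
        cell_id, {"BF": ChannelImage("BF", bf), "DF": ChannelImage("DF", df)}, phase
    )
    return record, {"mask": mask, "lobe_centers": []}


def _doublet_cell(
    cfg: SimulationConfig, rng: np.random.Generator, cell_id: str, phase: str
) -> tuple[CellRecord, dict]:
    params = cfg.phase_params["Int"]
    r = max(2.0, rng.normal(params.radius_mean, params.radius_sd))
    theta = rng.uniform(0.0, np.pi)
    mask, centers = _dumbbell_mask(cfg.frame_size, r, 2.0 * r, 0.0, theta)
    bf, df = _render(mask, params, cfg.frame_size, cfg.noise_sd, rng)
    record = CellRecord(
        cell_id, {"BF": ChannelImage("BF", bf), "DF": ChannelImage("DF", df)}, phase
    )
    return record, {"mask": mask, "lobe_centers": centers}


def generate_population(config: SimulationConfig) -> Population:
    """Generate a full population per the config; deterministic in the seed.

    Contaminants replace ``round(frac * n)`` cells each (exact counts, not
    Bernoulli draws), assigned uniformly at random across the population so
    every phase is affected proportionally in expectation; the replaced
    cell keeps its phase in the ground-truth table and gains a contaminant
    flag in {debris, doublet, defocus}.
    """
    rng = np.random.default_rng(config.seed)
    phases: list[str] = []
    for phase in PHASES:
        phases.extend([phase] * config.counts.get(phase, 0))
    order = rng.permutation(len(phases))
    phases = [phases[i] for i in order]
    n = len(phases)

    contaminant = [""] * n
    picks = rng.permutation(n)
    n_debris = round(config.debris_frac * n)
    n_doublet = round(config.doublet_frac * n)
    n_defocus = round(config.defocus_frac * n)
    for idx in picks[:n_debris]:
        contaminant[idx] = "debris"
    for idx in picks[n_debris : n_debris + n_doublet]:
        contaminant[idx] = "doublet"
    for idx in picks[n_debris + n_doublet : n_debris + n_doublet + n_defocus]:
        contaminant[idx] = "defocus"

    cells: list[CellRecord] = []
    gt_masks: dict[str, np.ndarray] = {}
    rows = []
    for i, phase in enumerate(phases):
        cell_id = f"cell{i:05d}"
        kind = contaminant[i]
        if kind == "debris":
            record, gt = _debris_cell(config, rng, cell_id, phase)
        elif kind == "doublet":
            record, gt = _doublet_cell(config, rng, cell_id, phase)
        else:
            blur = config.defocus_sigma if kind == "defocus" else 0.0
            record, gt = generate_cell(
                phase, config.phase_params[phase], rng,
                config.frame_size, config.noise_sd, cell_id, blur_sigma=blur,
            )
        cells.append(record)
        gt_masks[cell_id] = gt["mask"]
        rows.append({"cell_id": cell_id, "phase": phase, "contaminant": kind})

    imageset = ImageSet(
        cells, ["BF", "DF"], provenance=f"synthetic population, seed={config.seed}"
    )
    truth = pd.DataFrame(rows, columns=["cell_id", "phase", "contaminant"])
    return Population(imageset, truth, gt_masks)
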