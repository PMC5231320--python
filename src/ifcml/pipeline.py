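"""End-to-end orchestration: simulate/load -> tile -> QC -> segment ->
features -> train -> score -> evaluate -> rank.

Every stage writes a plain CSV/TIFF/JSON artifact under the output
directory and logs its parameters and cell counts; identical config and
seed give identical artifacts.  Each stage consumes only the previous
stage's artifacts, so the steps can be re-run individually from the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import pandas as pd

from . import classifyml, feature_bank, imageset_io, qc_gating, segmentation
from .containers import ImageSet
from .synthetic_cells import DEFAULT_COUNTS, SimulationConfig, generate_population

log = logging.getLogger("ifcml")

MODEL_FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """Flat configuration for the full pipeline; unknown keys are rejected."""

    out_dir: str = "ifcml_out"
    input_dir: str | None = None  # None -> simulate a population
    seed: int = 42
    # simulation
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    debris_frac: float = 0.0
    doublet_frac: float = 0.0
    defocus_frac: float = 0.0
    defocus_sigma: float = 3.0
    frame_size: int = 56
    noise_sd: float = 0.01
    # tiling
    tile_capacity: int = 1000
    # QC gates
    grms_min: float | str = "AUTO"
    area_min: float = 50.0
    area_max: float = 2500.0
    aspect_min: float = 0.15
    auto_percentile: float = 10.0
    # segmentation
    min_area: int = 9
    closing_radius: int = 2
    # features
    n_rings: int = 4
    n_wedges: int = 8
    glcm_offset: tuple[int, int] = (0, 3)
    glcm_levels: int = 8
    granularity_max_radius: int = 8
    granularity_bg_radius: int = 10
    max_zernike_order: int = 9
    exclude_patterns: tuple[str, ...] = classifyml.DEFAULT_EXCLUDE_PATTERNS
    # learning
    algorithm: str = "gradient_boosting"
    cap: int = 100
    k_folds: int = 10
    top_k: int = 20

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.glcm_offset, list):
            cfg.glcm_offset = tuple(cfg.glcm_offset)
        if isinstance(cfg.exclude_patterns, list):
            cfg.exclude_patterns = tuple(cfg.exclude_patterns)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def save_model(model: classifyml.PhaseClassifier, path: str | Path) -> None:
    joblib.dump(
        {"format_version": MODEL_FORMAT_VERSION,
         "params": model.get_params(), "model": model},
        path,
    )


def load_model(path: str | Path) -> classifyml.PhaseClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')}")
    return payload["model"]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a mapping of artifact name -> path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # 1. input population
    if config.input_dir is None:
        sim = SimulationConfig(
            counts=dict(config.counts),
            debris_frac=config.debris_frac,
            doublet_frac=config.doublet_frac,
            defocus_frac=config.defocus_frac,
            defocus_sigma=config.defocus_sigma,
            frame_size=config.frame_size,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        population = generate_population(sim)
        imageset = population.imageset
        truth = population.truth
        container = out / "container"
        imageset_io.write_imageset(imageset, container)
        truth.to_csv(out / "truth.csv", index=False)
        artifacts["container"] = container
        artifacts["truth"] = out / "truth.csv"
        log.info("simulate: %d cells (seed=%d)", len(imageset), config.seed)
    else:
        imageset = imageset_io.read_imageset(config.input_dir)
        labels = {
            c.cell_id: c.label for c in imageset if c.label is not None
        }
        truth = pd.DataFrame(
            [{"cell_id": cid, "phase": lab, "contaminant": ""}
             for cid, lab in labels.items()]
        )
        log.info("load: %d cells from %s", len(imageset), config.input_dir)

    # 2. tile
    montages, slot_table = imageset_io.pack_montages(imageset, config.tile_capacity)
    montage_dir = out / "montages"
    imageset_io.write_montages(montages, slot_table, montage_dir)
    artifacts["montages"] = montage_dir
    log.info("tile: %d montages (capacity=%d)", len(montages), config.tile_capacity)

    # 3. segment + QC
    seg_params = segmentation.SegmentationParams(
        min_area=config.min_area, closing_radius=config.closing_radius
    )
    masks = segmentation.segment_imageset(imageset, seg_params)
    gate_cfg = qc_gating.GateConfig(
        grms_min=config.grms_min,
        area_min=config.area_min,
        area_max=config.area_max,
        aspect_min=config.aspect_min,
        auto_percentile=config.auto_percentile,
    )
    qc = qc_gating.apply_gates(imageset, masks, gate_cfg)
    qc.as_frame().to_csv(out / "qc.csv", index=False)
    (out / "qc_thresholds.json").write_text(json.dumps(qc.thresholds_used, indent=2))
    artifacts["qc"] = out / "qc.csv"
    log.info("qc: kept %d / %d", len(qc.kept_ids), len(imageset))

    # 4. features on kept cells
    kept = set(qc.kept_ids)
    kept_set = ImageSet(
        [c for c in imageset if c.cell_id in kept],
        imageset.channel_labels,
        provenance=imageset.provenance,
    )
    table, registry = feature_bank.extract_features_table(
        kept_set,
        masks,
        n_rings=config.n_rings,
        n_wedges=config.n_wedges,
        glcm_offset=config.glcm_offset,
        glcm_levels=config.glcm_levels,
        granularity_max_radius=config.granularity_max_radius,
        granularity_bg_radius=config.granularity_bg_radius,
        max_zernike_order=config.max_zernike_order,
    )
    table.to_csv(out / "features.csv")
    registry.to_json(out / "feature_registry.json", orient="records", indent=2)
    artifacts["features"] = out / "features.csv"
    log.info("features: %d cells x %d features", *table.shape)

    # 5. train (labeled kept cells only)
    labels = truth.set_index("cell_id")["phase"]
    labeled_ids = [cid for cid in table.index if cid in labels.index]
    ts = classifyml.build_training_set(
        labels.loc[labeled_ids].to_dict(), cap=config.cap, seed=config.seed
    )
    model = classifyml.PhaseClassifier(
        algorithm=config.algorithm,
        cap=None,
        exclude_patterns=config.exclude_patterns,
        random_state=config.seed,
    ).fit(
        table.loc[ts.cell_ids],
        pd.Series([ts.labels[c] for c in ts.cell_ids], index=ts.cell_ids),
    )
    save_model(model, out / "model.joblib")
    artifacts["model"] = out / "model.joblib"
    log.info(
        "train: %s on %d cells (cap=%d): %s",
        config.algorithm, len(ts.cell_ids), config.cap, ts.counts_after,
    )

    # 6. score all non-training cells
    predictions = classifyml.score_all(model, table)
    predictions.rename_axis("cell_id").to_csv(out / "predictions.csv")
    artifacts["predictions"] = out / "predictions.csv"
    log.info("score: %d held-out cells", len(predictions))

    # 7. evaluate: cross-validate the training set; also confuse the test set
    report = classifyml.cross_validate(
        ts, table, algorithm=config.algorithm, k=config.k_folds, seed=config.seed
    )
    report.confusion.round(2).to_csv(out / "confusion.csv")
    (out / "confusion.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    artifacts["confusion"] = out / "confusion.csv"
    if len(predictions):
        test_true = labels.loc[[c for c in predictions.index if c in labels.index]]
        test_report = classifyml.confusion_matrix_pct(
            test_true.to_numpy(),
            predictions.loc[test_true.index].to_numpy(),
            note="held-out test set (all cells not in the training set)",
        )
        test_report.confusion.round(2).to_csv(out / "confusion_test.csv")
        artifacts["confusion_test"] = out / "confusion_test.csv"
    log.info("evaluate: macro TPR (CV) = %.3f", report.macro_tpr)

    # 8. feature ranking
    ranking = classifyml.rank_features(model, k=config.top_k)
    ranking.to_csv(out / "top_features.csv", index=False)
    artifacts["top_features"] = out / "top_features.csv"
    log.info("rank: top feature = %s", ranking.iloc[0]["feature"])
    return artifacts
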