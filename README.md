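# ifcml — machine learning for imaging flow cytometry

`ifcml` is an open toolkit for analysing imaging-flow-cytometry (IFC) data
with machine learning. An imaging flow cytometer captures spatially
registered grayscale images — transmitted bright-field (BF), laser
side-scatter/dark-field (DF/SSC) and optional fluorescence — for every
cell in flow, tens of thousands of cells per run. The toolkit targets the
analyst who wants to go from those per-cell images to a trained,
evaluated phenotype classifier without proprietary software: its flagship
use case is **label-free cell-cycle classification**, predicting
interphase and the four mitotic phases (prophase, metaphase, anaphase,
telophase) from BF and DF images alone, with no fluorescent stain.

The pipeline has five stages, each usable on its own:

1. **Container & tiling** (`imageset_io`) — a portable per-cell
   multi-page TIFF + CSV-manifest container, and lossless packing of
   cells into montage tiles (~10³ cells per grid image) for batch
   processing; unpacking restores every frame pixel-exactly.
2. **Quality gating** (`qc_gating`) — keep in-focus cells by a
   gradient-RMS focus score of the BF image, then keep single cells by
   mask area (removes debris and oversized objects) and mask aspect
   ratio (removes clumps/doublets).
3. **Segmentation** (`segmentation`) — one primary object mask per BF
   frame: Otsu threshold on the inverted frame, morphological closing,
   hole filling, largest 8-connected component.
4. **Feature bank** (`feature_bank`) — ~96 named features per cell for
   BF+DF under the `{CHN}_{Family}_{Name}` convention: AreaShape (area,
   boundary-chain perimeter, moment axes, eccentricity
   e = √(1−(b/a)²), compactness P²/(4πA), max Feret diameter, Zernike
   moment magnitudes |Z_nm| to order 9), Intensity (integrated, mean,
   quartile, edge statistics, mass displacement), RadialDistribution
   (FracAtD, MeanFrac, RadialCV over 4 distance-transform rings × 8
   wedges), Granularity (percent intensity removed per grayscale-opening
   radius, g₁…g₈) and Haralick texture InfoMeas2
   = √(1 − e^(−2(HXY2 − HXY))) from a symmetric GLCM.
5. **Classification** (`classifyml`) — the populations are extremely
   imbalanced (hundreds of interphase cells per anaphase cell), so
   training sets are built by undersampling majority classes to a cap;
   gradient boosting (300 depth-3 stages, learning rate 0.1) and random
   forests (500 trees, √p features/split) are trained, evaluated by
   stratified 10-fold cross-validation, row-normalized percentage
   confusion matrices whose diagonal is the per-class true positive rate
   TPRᵢ = correctᵢ / nᵢ, and top-k feature-importance rankings.

A `synthetic_cells` module generates labeled BF/DF populations with
phase-dependent morphology and texture, the study-scale class imbalance
(default counts Int 300 / Pro 38 / Meta 16 / Ana 15 / Telo 25), and QC
contaminants (debris, doublets, defocused frames), so the whole pipeline
is testable without instrument data.

## Worked example

Run the bundled end-to-end protocol (simulate → tile → QC → segment →
features → train → score → evaluate → rank):

```bash
ifcml run-all --out run1 --seed 42
```

or from Python:

```python
from ifcml import PipelineConfig, run_pipeline
artifacts = run_pipeline(PipelineConfig(out_dir="run1", seed=42))
```

The log reports each stage:

```
ifcml simulate: 394 cells (seed=42)
ifcml tile: 2 montages (capacity=1000)
ifcml qc: kept 394 / 394
ifcml features: 394 cells x 96 features
ifcml train: gradient_boosting on 194 cells (cap=100): {'Int': 100, 'Pro': 38, 'Meta': 16, 'Ana': 15, 'Telo': 25}
ifcml score: 200 held-out cells
ifcml evaluate: macro TPR (CV) = 1.000
```

`run1/confusion.csv` holds the cross-validated confusion matrix in
row-normalized percent — each row is a true class, each column a
predicted class, so the diagonal is the per-class true positive rate:

```
,Int,Pro,Meta,Ana,Telo
Int,100.0,0.0,0.0,0.0,0.0
Pro,0.0,100.0,0.0,0.0,0.0
Meta,0.0,0.0,100.0,0.0,0.0
Ana,0.0,0.0,0.0,100.0,0.0
Telo,0.0,0.0,0.0,0.0,100.0
```

On the default synthetic population the five phases are fully separable,
so every class — including the 15-cell anaphase and 25-cell telophase
minorities — is recovered at 100%; real instrument data is harder (see
`docs/methods.md`). `run1/top_features.csv` ranks features by importance;
dark-field intensity and granularity features lead, reflecting that the
DF channel carries the texture signal:

```
rank,feature,score
1,SSC_Intensity_MeanIntensity_DF_image,0.3586
2,SSC_Intensity_MinIntensityEdge_DF_image,0.1869
3,SSC_RadialDistribution_RadialCV_DF_image_1of4,0.1159
```

`run1/features.csv` is the full 394 × 96 feature table, e.g. cell00000:
`BF_AreaShape_Area` 180, `SSC_Granularity_1_DF_image` 3.83,
`BF_Texture_InfoMeas2_BF_image_3_0` 0.607.

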