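# ecmstruct

Tools for asking a specific question of solid tumours: **does the
architecture of the extracellular matrix (ECM) track the immune state of
the microenvironment, and which matrix genes move with it?** The package
is aimed at researchers working with stained tissue sections (collagen,
fibronectin, versican IHC or trichrome histochemistry), bulk RNA-seq of
the same tumours, and multiplexed immunofluorescence — typically in paired
chemotherapy-responsive / non-responsive tumour models of high-grade
serous ovarian cancer, though nothing in the code is organ-specific.

It provides, as a library with a thin CLI:

- **ECM structural metrics** from images or masks: skeleton-graph total
  fiber length, branchpoints and endpoints (raw and per unit length),
  average fiber length, multi-window chord curvature, high-density matrix
  (HDM) fraction, mean gap area (greedy maximal inscribed circles),
  gliding-box lacunarity Λ(r) = E[m²]/E[m]², box-counting fractal
  dimension, and derived fiber thickness = HDM × area / total length.
  Colour deconvolution (H-DAB / H-PAS) isolates the stain channel first.
- **Haralick texture** (contrast, correlation, energy, homogeneity,
  entropy from the gray-level co-occurrence matrix) with a
  ratio-of-control-medians correction for staining-batch drift.
- **Expression scoring**: cpm detection filter, log2-RPKM, per-sample
  ssGSEA scores for gene signatures and for the composite **anti-TME
  score** (union of M1, Th1, anti-tumour-cytokine and B-cell signatures),
  K-means gene clustering, hypergeometric set-overlap tests.
- **The structure index**: screen every metric by Spearman correlation
  against the anti-TME score (|r| ≥ 0.5, p ≤ 0.05), min–max scale the
  selected metrics and form, per sample,

  ```
  index = (mean scaled score-positive metrics + δ) / (mean scaled score-negative metrics + δ)
  ```

  then rank matrisome genes as candidate targets: associated with the
  index in the responsive model (|r| ≥ 0.5, p ≤ 0.05) but not in the
  non-responsive one (p > 0.05).
- **Spatial infiltration**: phenotype gating from marker positivity
  (CD8 T cell, B cell, TAM, CAF with fixed precedence) and cell densities
  in fixed-width distance bands outward from the tumour interface
  (default 25 × 20 µm over a 500-µm range).
- **Synthetic data** for all three modalities with known ground truth —
  fiber images with tunable curvature/thickness/fill, two-model cohorts
  with a latent anti-TME driver, planted metric correlations and
  model-specific target genes, and spatial point patterns with density
  gradients — so every stage is testable end to end.

## Worked example

`examples/structure_index.py` runs the whole integrative computation on a
synthetic cohort in which gap area and lacunarity were planted to rise
with the latent anti-TME driver (Spearman r = 0.9), HDM and total fiber
length to fall with it (r = −0.9), and genes 0300–0302 to track the driver
in model A only:

```
score-positive metrics: ['mean_gap_area_px2', 'lacunarity']
score-negative metrics: ['total_length_px', 'hdm_fraction']

structure index (model A): min 0.115, max 5.475
index vs anti-TME score  r = +0.907
index vs tumour weight   r = -0.896

gene      r_A     p_A     r_B     p_B   candidate
gene0300  +0.918  1.4e-06  +0.043  0.88  True
gene0301  +0.900  4.9e-06  -0.071  0.80  True
gene0302  +0.846  6.9e-05  +0.393  0.15  True
gene0311  -0.186  5.1e-01  -0.025  0.93  False
gene0310  -0.007  9.8e-01  +0.068  0.81  False
```

The screen recovers exactly the planted metric signs; the index built
from them tracks the anti-TME score (r = +0.91) and anticorrelates with
tumour weight (r = −0.90), and exactly the three planted model-A genes
are flagged as candidates. The other examples cover fiber metrics
(`fiber_metrics.py`), texture batch correction
(`texture_batch_correction.py`), cohort scoring
(`expression_scoring.py`) and infiltration profiling
(`spatial_infiltration.py`); each prints what it computes and what the
numbers mean.

## Command line

```bash
ecmstruct simulate  --scenario scenario.yaml --out sim/ --seed 11
ecmstruct metrics   --images sim/ --out metrics.tsv
ecmstruct texture   --images sim/ --out texture.tsv
ecmstruct normalize-texture --table texture.tsv --features haralick_contrast --out norm.tsv
ecmstruct score     --expr sim/expression.tsv --gmt sim/signatures.gmt --out scores.tsv
ecmstruct integrate --metrics sim/metrics.tsv --scores scores.tsv --out-prefix run1
ecmstruct spatial   --cells sim/cells.csv --region sim/tumor_mask.png --um-per-px 2 --out profile.tsv
```

Every stage is deterministic for a fixed seed and configuration: re-runs
produce byte-identical tables.

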