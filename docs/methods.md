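# Methods

`ecmstruct` implements a desk-scale version of an analysis that links
extracellular-matrix (ECM) architecture in stained tumour sections to the
transcriptomic state of the tumour microenvironment, and nominates matrix
genes whose expression tracks that architecture in a chemotherapy-responsive
tumour model but not in a non-responsive one. This note records the models,
parameter choices, and numerical conventions, and what the synthetic data
do and do not establish.

## Image-derived structural metrics

**Stain separation.** RGB images are converted to optical density per
channel, OD = −log10((I + 1)/256), and unmixed by inverting a 3×3 matrix of
unit stain vectors (Ruifrok–Johnston colour deconvolution). Built-in bases
are H-DAB (haematoxylin + DAB chromogen, the DAB channel carrying
collagen/fibronectin/versican IHC signal) and H-PAS (for trichrome
collagen); the third vector is the normalized cross product of the first
two. Custom 3×3 bases are accepted and must be non-singular.

**Skeleton graph.** The ECM foreground mask (fixed threshold or Otsu,
`mask = img ≥ t`) is thinned to a 1-px centerline and traced into a graph.
Node typing uses the 8-neighbourhood degree: degree 1 = fiber endpoint,
degree ≥ 3 = junction. Adjacent junction pixels are one physical
branchpoint and are clustered (8-connected components) before counting;
paths that never leave a junction cluster are junction interior and are not
counted as fibers. Closed loops without junctions are traced as cyclic
edges. Path length uses 1 for axial and √2 for diagonal steps, so a 50-px
horizontal run has length 49. Branch/endpoint counts are also reported per
unit length (divided by total length); with an empty skeleton these are NaN
(undefined), never 0, so downstream correlation screens can drop them
explicitly rather than absorb spurious zeros.

**Curvature.** Each edge of arc length ≥ 2·w is resampled at arc-length
spacing w (linear interpolation along the pixel path); the metric is the
mean absolute angle between successive chords, in degrees, averaged over
eligible edges, at windows w ∈ {10, 20, 30, 40} px. On a circle of radius
r the expected turn per chord of length w is the central angle
2·asin(w/2r), which the implementation reproduces within 10% at r = 100,
w = 10 (raster quantization accounts for the residual).

**High-density matrix (HDM).** Fraction of pixels at or above a saturation
threshold; default 140/255. The threshold is a workflow parameter with no
canonical value; it is exposed in `MetricsConfig` and recorded as an
assumption. When only a mask is available, HDM falls back to the
foreground fraction.

**Gap analysis.** Gaps are maximal non-overlapping inscribed circles in the
background, found greedily on the Euclidean distance transform: take the
global maximum, record a circle of that radius (area πr²), remove every
remaining candidate whose circle would overlap it, and repeat while the
radius is ≥ 2 px (configurable). The image border is treated as foreground
so circles stay inside the field of view. The summary is the mean recorded
circle area. Note the mean over circles is not monotone under arbitrary
hole addition (a large square hole also contributes small corner circles);
the per-gap list is exposed for callers who need totals.

**Lacunarity.** Gliding-box statistic Λ(r) = E[m²]/E[m]² of occupied-pixel
counts m over all r×r box positions (integral-image implementation, exact).
Λ = 1 for homogeneous masks and grows with gappiness. Box sizes default to
dyadic 2, 4, 8, … ≤ min(dim)/4; the summary is the mean of Λ(r) over sizes,
with per-size values also returned. Empty masks are NaN.

**Box-counting fractal dimension.** Occupied-box counts N(ε) over
non-overlapping dyadic grid partitions (ε = 1, 2, 4, … ≤ min(dim)/4);
BCFD is the least-squares slope of log N versus log(1/ε). Validated
against a filled square (2), a 1-px line (1) and a depth-6 Sierpinski
triangle (log 3 / log 2 ≈ 1.585), all within 0.05.

**Fiber thickness.** thickness = HDM × image area / total fiber length —
high-density area spread over the measured centerline length. NaN when the
skeleton is empty.

## Haralick texture and batch correction

The co-occurrence matrix quantizes intensities into 16 equal-width bins
over the analysed region's min–max range (robust to background and to
linear gain), counts ordered pixel pairs at a fixed (dy, dx) offset —
restricted to a mask when given — optionally symmetrizes by adding the
transpose, and normalizes. Five statistics are reported: contrast
Σ P(i,j)(i−j)², energy Σ P², homogeneity Σ P/(1+|i−j|), entropy
−Σ P log₂P, and the standard marginal-moment correlation (NaN when a
marginal has zero variance, e.g. constant images). The default is the mean
over the four standard directions {(0,1), (1,0), (1,1), (1,−1)}; level
count and offsets are parameters since the upstream tooling does not pin
them.

Staining rounds imaged on different days drift in intensity. The
correction rescales each feature of every batch by
median(reference controls)/median(batch controls), leaving the reference
batch (first in table order unless named) unchanged. The division is
applied before the multiplication so a control sitting exactly on its
batch median lands exactly on the reference median in floating point.
Batches without control samples are an error, named explicitly.

## Expression scoring

**Detection filter.** A gene is kept when its counts-per-million reach 1
in at least ⌈0.25 · n_samples⌉ samples — the fraction is inclusive, so
1 passing sample out of 4 keeps the gene. Filtering then subsetting
samples is not the same as subsetting then filtering; this is intentional
and tested.

**log2-RPKM.** RPKM = count·10⁹/(library size × gene length), reported as
log2(RPKM + 1).

**Per-sample scoring.** The scorer is the ssGSEA running-sum statistic:
genes ranked by descending expression within one sample (ties broken by
gene identifier), in-set genes weighted by rank^0.25, and the score is the
accumulated difference between the weighted in-set CDF and the uniform
out-of-set CDF, divided by the number of genes. The normalizing constant
is a convention; any positive constant is rank-equivalent. The score is
invariant under strictly monotone transforms of a sample's values, and 0
by convention when the set is the whole universe. **Design note:** among
the single-sample scorers in common use (GSVA's KCDF statistic, ssGSEA,
rank means), the ssGSEA statistic was chosen because it is directionally
rank-equivalent to the alternatives and verifiable by hand enumeration.
Scores from different statistics are not numerically interchangeable.

**Composite anti-TME score.** ssGSEA score of the exact union (duplicates
counted once) of the M1, Th1, anti-tumour-cytokine and B-cell signatures.
The member genes of these signatures are not redistributable here; the
package ships synthetic placeholder sets for testing and expects
user-supplied GMT files for real use. Mouse↔human orthology is a
user-supplied two-column table; no live database queries.

**Clustering and overlap.** Gene clustering is Euclidean K-means (default
k = 7) on z-scored gene profiles, best of 25 restarts, deterministic for a
seed; constant genes are dropped with a warning. Set overlap uses the
upper-tail hypergeometric test P(X ≥ |A∩B|), exact against combinatorial
enumeration for universes ≤ 12.

## Structure index and target ranking

**Spearman correlation.** Average ranks for ties; p-values are exact over
all n! pairings for n ≤ 9 (vectorized enumeration of centered rank
cross-products) and use the t approximation beyond. Fewer than 4 complete
pairs is an error; constant vectors yield NaN (undefined), not 0.
NaN-flagged metric values are dropped pairwise, which is why undefined
metrics are flagged rather than zero-coerced upstream.

**Metric screen.** Each metric column is correlated with the per-sample
anti-TME score; metrics with r ≥ 0.5 and p ≤ 0.05 are score-positive, with
r ≤ −0.5 and p ≤ 0.05 score-negative. No multiple-testing correction is
applied by default (the screen pairs a raw p threshold with an r floor);
metrics with too few pairs come back flagged, not silently dropped.

**Index.** Each selected metric is min–max scaled to [0, 1] across
samples, and per sample

  index = (mean of scaled positives + δ)/(mean of scaled negatives + δ),

δ = 0.1 by default. Design choices where the definition was genuinely
open: "scaling" is min–max (matching the radar-plot convention; z-scoring
is available behind `scaling="zscore"`); the "ratio of parameters" is the
ratio of set means (sum-based variants differ only by the constant
|positives|/|negatives| when δ = 0); δ keeps the ratio finite for the
sample scaling to 0 on all negative metrics and is reported in the result.
The index is invariant to affine rescaling of any raw metric, and
swapping the two sets maps (a+δ)/(b+δ) to (b+δ)/(a+δ) exactly.

**Target ranking.** Each matrix gene is correlated with the index within
each model; a candidate must pass |r| ≥ 0.5 and p ≤ 0.05 in the responsive
model A and stay non-significant (p > 0.05) in model B. Both association
directions are retained with their sign, because down-regulated matrix
regulators are as informative as up-regulated ones. Genes constant in a
model are flagged undefined and cannot be candidates; requested genes
missing from either expression universe are reported back rather than
silently skipped.

**Radar scaling.** Group means are scaled per metric to (v−min)/(max−min)
across groups; when all groups tie, everyone maps to 1 (full radius), so a
metric with no group differences is visually neutral rather than collapsed.

## Spatial infiltration

**Gating.** Phenotypes from marker booleans with fixed precedence, first
match wins: CD8⁺ → CD8 T cell; B220⁺ → B cell; (CD206⁺ or F4/80⁺ or
CD163⁺) and aSMA⁻ → TAM; (aSMA⁺ or S100A4⁺) and CK14⁻ and CK19⁻ and
F4/80⁻ → CAF; else "other". The precedence (lymphocytes before TAM before
CAF) resolves double-positives that the gate definitions alone leave
ambiguous; the order is a parameter. The gates are exhaustive and
mutually exclusive under this order, property-tested over all 2¹² marker
combinations.

**Distances.** The tumour interface is the outermost tumour-pixel layer of
the rasterized region (1 µm/px by default); signed Euclidean distance is 0
on that layer, positive outside the tumour, negative in the interior. A
cell sitting on the interface therefore reads exactly 0.

**Bands.** Band k collects cells at distances [k·w, (k+1)·w) outward; the
default is 25 bands of 20 µm (a 500-µm range). The coarser 12 × 40 µm
preset covers 480 µm; the two conventions coexist in the source material
and neither is asserted as canonical — both are supported and the choice
is explicit in every output. Band areas are pixel counts of the same
rasterized distance field converted to mm², so banded areas sum to the
shell area by construction and banded counts conserve the in-range cell
count exactly. Densities are counts per mm². Areas are computed over the
provided tissue raster only; no adipose exclusion is attempted.

## Synthetic data: what it emulates, and what it does not

All generators derive every random draw from one integer seed through
splittable `numpy` generators; identical ground truth gives bit-identical
outputs.

**Fiber images** are biased random walks: per 1-px step the heading gains
a Gaussian increment with standard deviation `curvature_param` (radians),
giving directly tunable curvature; walks end at the frame (no reflection
kinks), retrying early exits so fibers reach a usable length; polylines
are dilated to the target thickness with a disk (odd widths exact, even
widths approximate); the gray image is two-level (220 foreground / 20
background ± uniform noise of 10) so thresholding at 128 reproduces the
mask exactly. `fill_fraction` sets the target foreground area fraction
and determines the per-fiber walk length. These images exercise every
structural metric with recoverable ordering (e.g. higher
`curvature_param` ⇒ higher measured curvature), but they do not mimic real
chromogen appearance, fiber bundling, or imaging noise — passing tests
demonstrate correctness of the measurement code, not biological realism.

**Cohorts** mirror the animal-study design: models A (responsive) and B
(non-responsive), control/treated arms, three timepoints, no control arm
at the last timepoint, 3 samples per design cell ⇒ 15 per model. A latent
per-sample "anti-TME driver" z ~ N(0,1) gains a shift equal to
`signature_effect` (default 2.0 log2 units) in treated model-A samples;
signature genes load on z with unit weight plus log-normal noise
(`noise_sd`, default 0.5), so the stated gene-level shift holds exactly
and the ssGSEA score tracks the driver. Planted metric correlations use a
Gaussian copula (Pearson ρ = 2·sin(π·r_s/6) for target Spearman r_s,
exact for Gaussian margins, approximate under the treated-arm mixture);
non-planted metrics are independent log-normal noise. Planted target
genes load on the driver in model A only (loading 2.0). Tumour weight is
exp(−0.7·z + noise) — a decreasing function of the driver, so the index
should anticorrelate with it. Expression scales are arbitrary: the source
material gives no distributional description of real metric or expression
values, so only *relationships* (signs, ranks, recovery rates) are
meaningful, never absolute magnitudes. Counts mode draws Poisson counts
from exponentiated log2 means so the detection filter is exercisable.

**Cell maps** place cells outside the tumour region with intensity
∝ max(0, 1 + gradient·d) at distance d µm from the interface; `gradient`
is a *relative* slope (fraction per µm) rather than an absolute
cells·mm⁻²·µm⁻¹ rate, decoupling profile shape from `n_cells`. Marker
booleans are canonical per-phenotype patterns chosen to satisfy the gates
(e.g. a TAM is CD206⁺F4/80⁺aSMA⁻), so gating recovers the generating
phenotype exactly; real data's partial and conflicting marker patterns are
not emulated.

## Operating characteristics (replicate studies)

`ecmstruct.benchmarks` runs the full pipeline over seeded replicate
cohorts at the study conditions (n = 15/model; planted metric r = ±0.9 on
gap area and lacunarity vs HDM and total length; three planted targets).
Problem sizes — 400 genes, 100 recovery replicates, 200 null replicates —
keep a full study run in tens of seconds while leaving Monte-Carlo
standard errors well below the margins being tested. The
`scripts/acceptance.py` entry point recomputes these numbers from scratch
together with the geometry oracles and writes them as JSON.

## Known limitations

- Skeleton-graph edge lengths slightly undercount at junctions (junction
  interior paths are excluded); the effect is symmetric across conditions.
- Curvature resampling assumes linear interpolation between pixel centers;
  other resampling rules would shift absolute values by a few percent.
- The greedy gap finder is order-dependent by construction (largest
  first); it is a definition, not an approximation of a unique optimum.
- The ssGSEA scorer is not numerically interchangeable with GSVA's KCDF
  statistic (directionally consistent, different scale).
- Exact Spearman p-values stop at n = 9; n = 10–15 uses the t
  approximation, which is slightly conservative at the screen's thresholds.
- The spatial profile assumes one connected tissue raster and a binary
  tumour mask; multi-region or graded annotations are out of scope.
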