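"""Synthetic fiber images, expression cohorts and cell maps with known truth.

Every generator is driven by a single integer seed through a splittable
``numpy`` generator, so identical ground-truth records give bit-identical
outputs.  The three generators emulate the study's three data modalities:

* **Fiber images** — biased random-walk polylines (Gaussian turning angles
  with spread ``curvature_param`` per unit step) dilated to a target
  thickness, on a two-level stain background.  The binary mask is exactly
  the binarization of the gray image.
* **Expression cohorts** — two tumour models (A: chemo-responsive, B:
  non-responsive), control/treated arms and three collection timepoints,
  with no control arm at the last timepoint, mirroring the animal-study
  design.  A latent per-sample "anti-TME driver" carries the treatment
  response; signature genes load on it 1:1 so the driver shift equals the
  stated log-scale ``signature_effect``; named structural metrics are given
  planted Spearman correlations with the driver through a Gaussian copula;
  planted matrix-gene targets track the driver in model A only; tumour
  weight decreases with the driver.
* **Cell maps** — spatial point patterns outside a tumour region with
  intensity linear in distance from the interface (relative slope
  ``gradient`` per um, clipped at zero), and marker booleans realised from
  canonical per-phenotype patterns consistent with the gating rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk

from .metrics import METRIC_COLUMNS
from .spatial import MARKERS, PHENOTYPES, RegionGeometry

__all__ = [
    "FiberGroundTruth", "CohortGroundTruth", "SpatialGroundTruth",
    "generate_fiber_image", "generate_cohort", "generate_cell_map",
    "METRIC_PANEL", "default_signatures", "default_gene_universe",
]

TEXTURE_COLUMNS = ["haralick_contrast", "haralick_correlation",
                   "haralick_energy", "haralick_homogeneity",
                   "haralick_entropy"]
#: canonical metric panel a cohort simulation can plant correlations on
METRIC_PANEL = METRIC_COLUMNS + TEXTURE_COLUMNS

MODELS = ("A", "B")
ARMS = ("control", "treated")
TIMEPOINTS = ("TP1", "TP2", "TP3")
#: (arm, timepoint) cells present per model; no control arm at TP3
DESIGN_CELLS = tuple(
    (arm, tp) for tp in TIMEPOINTS for arm in ARMS
    if not (arm == "control" and tp == "TP3")
)

_FG, _BG = 220.0, 20.0
_BINARIZE_AT = 128.0


@dataclass(frozen=True)
class FiberGroundTruth:
    n_fibers: int
    curvature_param: float = 0.1  # radians per 1-px step (sd of turn angle)
    thickness_px: int = 3
    fill_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.curvature_param < 0:
            raise ValueError("curvature_param must be >= 0")
        if self.thickness_px < 1:
            raise ValueError("thickness_px must be >= 1")
        if not 0 <= self.fill_fraction <= 1:
            raise ValueError("fill_fraction must lie in [0, 1]")


def generate_fiber_image(
    gt: FiberGroundTruth, size: int | tuple[int, int] = 256
) -> tuple[np.ndarray, np.ndarray, FiberGroundTruth]:
    """Render a synthetic stained-fiber image and its foreground mask."""
    if isinstance(size, int):
        size = (size, size)
    H, W = size
    if H < 64 or W < 64:
        raise ValueError("image must be at least 64 x 64")
    if gt.thickness_px >= min(H, W):
        raise ValueError("fiber thickness must be smaller than the image")
    rng = np.random.default_rng(np.random.SeedSequence(gt.seed))
    mask = np.zeros((H, W), dtype=bool)
    n_steps = max(16, int(gt.fill_fraction * H * W
                          / (max(gt.n_fibers, 1) * gt.thickness_px)))
    for _ in range(gt.n_fibers):
        # fibers end at the frame rather than kink back; retry starts that
        # exit early so drawn fibers reach a usable length
        best: list[tuple[int, int]] = []
        for _attempt in range(10):
            r = rng.uniform(0, H)
            c = rng.uniform(0, W)
            theta = rng.uniform(0, 2 * np.pi)
            pts = [(int(r), int(c))]
            for _ in range(n_steps):
                theta += rng.normal(0.0, gt.curvature_param)
                r += np.sin(theta)
                c += np.cos(theta)
                if not (0 <= r < H and 0 <= c < W):
                    break
                pts.append((int(r), int(c)))
            if len(pts) > len(best):
                best = pts
            if len(best) >= n_steps // 2:
                break
        for (r0, c0), (r1, c1) in zip(best[:-1], best[1:]):
            rr, cc = _draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
    radius = int(round((gt.thickness_px - 1) / 2))
    if radius > 0:
        mask = dilation(mask, disk(radius))
    noise = rng.uniform(-10.0, 10.0, size=(H, W))
    gray = np.where(mask, _FG, _BG) + noise
    gray = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    # by construction thresholding the image reproduces the mask exactly
    assert bool(((gray >= _BINARIZE_AT) == mask).all())
    return gray, mask, gt


@dataclass(frozen=True)
class CohortGroundTruth:
    n_samples_per_cell: int = 3
    signature_effect: float = 2.0  # log2-scale shift, treated model-A
    planted_metric_correlations: dict[str, float] = field(default_factory=dict)
    planted_target_genes: tuple[str, ...] = ()
    target_loading: float = 2.0  # driver loading of planted targets (model A)
    noise_sd: float = 0.5  # log2-scale residual sd
    seed: int = 0

    def __post_init__(self):
        if self.n_samples_per_cell < 1:
            raise ValueError("n_samples_per_cell must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for m, r in self.planted_metric_correlations.items():
            if m not in METRIC_PANEL:
                raise ValueError(f"unknown metric name {m!r}")
            if not -1 <= r <= 1:
                raise ValueError(f"planted r for {m!r} outside [-1, 1]")


def default_gene_universe(n_genes: int = 400) -> list[str]:
    return [f"gene{i:04d}" for i in range(n_genes)]


def default_signatures(gene_universe, genes_per_set: int = 12):
    """Placeholder component signatures carved from the top of the universe.

    Stand-ins for the functional TME signatures (synthetic; real analyses
    supply their own GMT).
    """
    from .expression import ANTI_TME_COMPONENTS, SignatureCollection

    sets = {}
    for i, name in enumerate(ANTI_TME_COMPONENTS):
        sets[name] = frozenset(
            gene_universe[i * genes_per_set:(i + 1) * genes_per_set]
        )
    return SignatureCollection(sets)


def _sample_table(n_per_cell: int) -> pd.DataFrame:
    rows = []
    for model in MODELS:
        for arm, tp in DESIGN_CELLS:
            for i in range(n_per_cell):
                rows.append({
                    "sample": f"{model}_{arm}_{tp}_{i}",
                    "model": model,
                    "arm": arm,
                    "timepoint": tp,
                    "batch": f"exp_{tp[-1]}",
                })
    return pd.DataFrame(rows).set_index("sample", drop=False)


def generate_cohort(
    gt: CohortGroundTruth,
    gene_universe: list[str] | None = None,
    signatures=None,
    kind: str = "log",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate (expression, sample table, metrics table, tumour weight).

    Expression is genes x samples, log2 scale by default; ``kind="counts"``
    draws Poisson counts from the exponentiated log2 means instead, so the
    cpm filter is exercisable.  The sample table carries model, arm,
    timepoint, batch and tumour weight; the metrics table carries the full
    canonical panel with the requested planted Spearman correlations to the
    latent driver; tumour weight decreases with the driver.
    """
    if kind not in ("log", "counts"):
        raise ValueError("kind must be 'log' or 'counts'")
    if gene_universe is None:
        gene_universe = default_gene_universe()
    if signatures is None:
        signatures = default_signatures(gene_universe)
    anti_tme = signatures.anti_tme()
    if not anti_tme <= frozenset(gene_universe):
        raise ValueError("signatures must be subsets of the gene universe")
    for g in gt.planted_target_genes:
        if g not in gene_universe:
            raise ValueError(f"planted target gene {g!r} not in universe")
        if g in anti_tme:
            raise ValueError(f"planted target gene {g!r} overlaps the "
                             "anti-TME signature")

    ss = np.random.SeedSequence(gt.seed)
    r_driver, r_expr, r_metrics, r_weight = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    samples = _sample_table(gt.n_samples_per_cell)
    n = len(samples)
    treated_a = ((samples["model"] == "A")
                 & (samples["arm"] == "treated")).to_numpy()
    model_a = (samples["model"] == "A").to_numpy()

    # latent anti-TME driver: unit-variance noise plus the treatment shift
    z = r_driver.normal(0.0, 1.0, size=n) + gt.signature_effect * treated_a

    baseline = pd.Series(r_expr.normal(6.0, 1.0, size=len(gene_universe)),
                         index=gene_universe)
    expr = (baseline.to_numpy()[:, None]
            + r_expr.normal(0.0, max(gt.noise_sd, 1e-12),
                            size=(len(gene_universe), n)))
    expr = pd.DataFrame(expr, index=gene_universe, columns=samples.index)
    for g in anti_tme:
        expr.loc[g] += z  # unit loading: treated-A shift == signature_effect
    for g in gt.planted_target_genes:
        expr.loc[g] += np.where(model_a, gt.target_loading * z, 0.0)

    # metrics: Gaussian copula against the driver for planted names
    metric_cols = {}
    for m in METRIC_PANEL:
        eps = r_metrics.normal(0.0, 1.0, size=n)
        r_s = gt.planted_metric_correlations.get(m, 0.0)
        rho = 2.0 * np.sin(np.pi * r_s / 6.0)
        zs = (z - z.mean()) / (z.std() or 1.0)
        w = rho * zs + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        metric_cols[m] = np.exp(0.5 * w)  # arbitrary positive scale
    metrics = pd.DataFrame(metric_cols, index=samples.index)

    weight = pd.Series(
        np.exp(-0.7 * z + r_weight.normal(0.0, 0.3, size=n)),
        index=samples.index, name="tumor_weight_g",
    )
    # keep the latent driver in the sample table so recovery is checkable
    samples = samples.assign(tumor_weight_g=weight, anti_tme_driver=z)

    if kind == "counts":
        mu = np.power(2.0, expr.to_numpy())
        counts = np.random.default_rng(ss.spawn(1)[0]).poisson(mu)
        expr = pd.DataFrame(counts, index=expr.index, columns=expr.columns)

    return expr, samples, metrics, weight


@dataclass(frozen=True)
class SpatialGroundTruth:
    n_cells: int
    gradient: float = 0.0  # relative intensity slope per um of distance
    phenotype_mix: dict[str, float] = field(
        default_factory=lambda: {"CD8 T cell": 0.15, "B cell": 0.1,
                                 "TAM": 0.25, "CAF": 0.2, "other": 0.3})
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        mix = self.phenotype_mix
        if any(not 0 <= f <= 1 for f in mix.values()):
            raise ValueError("phenotype fractions must lie in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("phenotype fractions must sum to 1")
        unknown = set(mix) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotypes {sorted(unknown)}")


# marker patterns realising each phenotype under the gating rules
_PATTERNS = {
    "CD8 T cell": {"CD8"},
    "B cell": {"B220"},
    "TAM": {"CD206", "F4/80"},
    "CAF": {"aSMA", "S100A4"},
    "other": set(),
}


def generate_cell_map(
    gt: SpatialGroundTruth, region: RegionGeometry
) -> pd.DataFrame:
    """Sample a cell table outside the tumour region of ``region``.

    Placement intensity at distance d um from the interface is
    max(0, 1 + gradient * d); gradient 0 gives a homogeneous pattern.
    Returns a table with micrometre x/y, one boolean column per marker and
    the generating ``true_phenotype``.
    """
    from .spatial import _signed_distance_field

    rng = np.random.default_rng(np.random.SeedSequence(gt.seed))
    field_um = _signed_distance_field(region)
    outside = field_um > 0
    weights = np.where(outside,
                       np.clip(1.0 + gt.gradient * field_um, 0.0, None), 0.0)
    cols = ["cell_id", "x", "y", *MARKERS, "true_phenotype"]
    if gt.n_cells == 0:
        return pd.DataFrame(columns=cols)
    total = weights.sum()
    if total <= 0:
        raise ValueError("placement intensity vanishes everywhere outside "
                         "the tumour region")
    flat = weights.ravel() / total
    picks = rng.choice(flat.size, size=gt.n_cells, p=flat)
    rr, cc = np.unravel_index(picks, weights.shape)
    jitter = rng.uniform(0.0, 1.0, size=(gt.n_cells, 2))
    x = (cc + jitter[:, 0]) * region.um_per_px
    y = (rr + jitter[:, 1]) * region.um_per_px

    phenos = list(gt.phenotype_mix)
    probs = np.array([gt.phenotype_mix[p] for p in phenos])
    labels = rng.choice(len(phenos), size=gt.n_cells, p=probs / probs.sum())

    rows = []
    for i in range(gt.n_cells):
        ph = phenos[labels[i]]
        pattern = _PATTERNS[ph]
        row = {"cell_id": f"cell{i:06d}", "x": x[i], "y": y[i],
               "true_phenotype": ph}
        for m in MARKERS:
            row[m] = m in pattern
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
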