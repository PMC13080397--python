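"""Per-image ECM structural metric panel.

Bundles the fiber-network, gap, lacunarity, fractal and high-density-matrix
statistics into one record per image, mirroring the metric panel used to
profile matrix architecture in stained tumour sections: total fiber length,
branch/endpoint counts and their per-length normalizations, average fiber
length, multi-window curvature, HDM fraction, mean gap area, gliding-box
lacunarity, box-counting fractal dimension, and the derived mean fiber
thickness

    thickness = HDM * image_area / total_fiber_length

i.e. high-density area spread over the measured centerline length.
Undefined values (empty skeleton, empty mask) are NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gaps import box_counting_fd, gap_analysis, lacunarity
from .images import binarize, hdm
from .skeleton import curvature, fiber_metrics, skeletonize

__all__ = ["MetricsConfig", "ECMMetrics", "compute_all_metrics", "metrics_table", "METRIC_COLUMNS"]


@dataclass
class MetricsConfig:
    """Tunable parameters of the metric panel.

    The HDM saturation threshold and binarization rule are exposed because
    the upstream workflow treats them as user parameters; defaults are
    package choices, documented as assumptions.
    """

    hdm_threshold: float = 140.0
    binarize_threshold: float | str = "otsu"
    min_gap_radius_px: float = 2.0
    curvature_windows: tuple[int, ...] = (10, 20, 30, 40)
    lacunarity_box_sizes: tuple[int, ...] | None = None  # None = dyadic default


@dataclass
class ECMMetrics:
    total_length_px: float = np.nan
    n_branchpoints: float = np.nan
    n_endpoints: float = np.nan
    norm_branchpoints: float = np.nan
    norm_endpoints: float = np.nan
    avg_fiber_length_px: float = np.nan
    curvature_deg: dict[int, float] = field(default_factory=dict)
    hdm_fraction: float = np.nan
    mean_gap_area_px2: float = np.nan
    lacunarity: float = np.nan
    bcfd: float = np.nan
    fiber_thickness_px: float = np.nan

    def to_row(self) -> dict[str, float]:
        d = asdict(self)
        curv = d.pop("curvature_deg")
        for w, v in curv.items():
            d[f"curvature{w}_deg"] = v
        return d


METRIC_COLUMNS = [
    "total_length_px", "n_branchpoints", "n_endpoints", "norm_branchpoints",
    "norm_endpoints", "avg_fiber_length_px", "curvature10_deg",
    "curvature20_deg", "curvature30_deg", "curvature40_deg", "hdm_fraction",
    "mean_gap_area_px2", "lacunarity", "bcfd", "fiber_thickness_px",
]


def compute_all_metrics(
    img: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    config: MetricsConfig | None = None,
) -> ECMMetrics:
    """Compute the full structural panel from a gray image and/or mask.

    With only a mask, HDM is the foreground fraction (the mask treated as a
    saturated two-level image).  With only an image, the mask is derived by
    the configured binarization.  Empty inputs yield a record of zeros and
    NaN flags without raising.
    """
    cfg = config or MetricsConfig()
    if img is None and mask is None:
        raise ValueError("provide an image, a mask, or both")
    if mask is None:
        mask = binarize(img, cfg.binarize_threshold)
    mask = np.asarray(mask, dtype=bool)

    rec = ECMMetrics()
    sk = skeletonize(mask)
    rec_fibers = fiber_metrics(sk)
    rec.total_length_px = rec_fibers["total_length_px"]
    rec.n_branchpoints = rec_fibers["n_branchpoints"]
    rec.n_endpoints = rec_fibers["n_endpoints"]
    rec.norm_branchpoints = rec_fibers["norm_branchpoints"]
    rec.norm_endpoints = rec_fibers["norm_endpoints"]
    rec.avg_fiber_length_px = rec_fibers["avg_fiber_length_px"]
    rec.curvature_deg = {w: curvature(sk, w) for w in cfg.curvature_windows}

    if img is not None:
        rec.hdm_fraction = hdm(img, cfg.hdm_threshold)
    else:
        rec.hdm_fraction = float(mask.mean()) if mask.size else 0.0

    rec.mean_gap_area_px2, _ = gap_analysis(mask, cfg.min_gap_radius_px)
    sizes = list(cfg.lacunarity_box_sizes) if cfg.lacunarity_box_sizes else None
    rec.lacunarity, _ = lacunarity(mask, sizes)
    rec.bcfd = box_counting_fd(mask)

    area = float(mask.size)
    if rec.total_length_px > 0:
        rec.fiber_thickness_px = rec.hdm_fraction * area / rec.total_length_px
    return rec


def metrics_table(records: dict[str, ECMMetrics]) -> pd.DataFrame:
    """Assemble one row per image id, with stable column order."""
    rows = {name: rec.to_row() for name, rec in records.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    cols = [c for c in METRIC_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df = df[cols + extra]
    df.index.name = "image"
    return df


def run_directory(images_dir, config: MetricsConfig | None = None,
                  stain_basis: str = "H-DAB") -> pd.DataFrame:
    """Process every TIFF/PNG in a directory into a metrics table.

    RGB images are stain-deconvolved (chromogen channel) first; gray images
    are used as-is.
    """
    from .images import deconvolve_stain, read_gray

    records: dict[str, ECMMetrics] = {}
    paths = sorted(
        p for p in Path(images_dir).iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    for p in paths:
        arr = read_gray(p)
        if arr.ndim == 3:
            arr = deconvolve_stain(arr[..., :3], stain_basis)
        records[p.stem] = compute_all_metrics(img=arr, config=config)
    return metrics_table(records)
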