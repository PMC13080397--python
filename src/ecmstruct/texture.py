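"""Haralick gray-level co-occurrence texture features and batch correction.

The co-occurrence matrix is built after quantizing intensities into
equal-width bins over the analysed region's min-max range, counting ordered
pixel pairs at a fixed offset (optionally restricted to a mask and
symmetrized), then normalizing to a joint distribution P(i, j).  Five
summary statistics are reported: contrast, correlation, energy (angular
second moment), homogeneity and entropy (base 2).

Staining batches imaged on different days drift in intensity; the
cross-experiment correction rescales every feature of a batch by the ratio
of control-group medians, reference batch first, so each batch's control
median lands exactly on the reference's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GLCM", "glcm", "glcm_multi_offset", "haralick", "batch_normalize",
           "DEFAULT_OFFSETS", "HARALICK_FEATURES"]

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
HARALICK_FEATURES = ("contrast", "correlation", "energy", "homogeneity", "entropy")


@dataclass
class GLCM:
    matrix: np.ndarray  # L x L, normalized to sum 1
    offset: tuple[int, int]
    symmetric: bool
    levels: int


def _quantize(img: np.ndarray, levels: int, mask: np.ndarray | None) -> np.ndarray:
    """Equal-width binning over the (masked) min-max intensity range."""
    img = np.asarray(img, dtype=float)
    sel = img[mask] if mask is not None else img
    lo, hi = float(sel.min()), float(sel.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(
    img: np.ndarray,
    offset: tuple[int, int] = (0, 1),
    levels: int = 16,
    symmetric: bool = True,
    mask: np.ndarray | None = None,
) -> GLCM:
    """Gray-level co-occurrence matrix at one (dy, dx) offset."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    dy, dx = offset
    if dy == 0 and dx == 0:
        raise ValueError("offset must be nonzero")
    img = np.asarray(img)
    H, W = img.shape
    if abs(dy) >= H or abs(dx) >= W:
        raise ValueError("image smaller than the requested offset")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask selects no pixels")
    q = _quantize(img, levels, mask)

    # ordered pairs (p, p + offset) with both ends inside the grid (and mask)
    ys = slice(max(0, -dy), H - max(0, dy))
    xs = slice(max(0, -dx), W - max(0, dx))
    a = q[ys, xs]
    b = np.roll(np.roll(q, -dy, axis=0), -dx, axis=1)[ys, xs]
    valid = np.ones(a.shape, dtype=bool)
    if mask is not None:
        valid = mask[ys, xs] & np.roll(np.roll(mask, -dy, axis=0), -dx, axis=1)[ys, xs]
        if not valid.any():
            raise ValueError("no co-occurring pixel pairs inside the mask")
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs at this offset")
    return GLCM(matrix=counts / total, offset=(dy, dx), symmetric=symmetric,
                levels=levels)


def haralick(g: GLCM) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity and entropy of one GLCM.

    Correlation is NaN (undefined) when a marginal has zero variance, e.g.
    for a constant image.
    """
    P = np.asarray(g.matrix, dtype=float)
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError("GLCM must be normalized")
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    contrast = float((P * (i - j) ** 2).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    mu_i, mu_j = float(pi @ np.arange(L)), float(pj @ np.arange(L))
    var_i = float(pi @ (np.arange(L) - mu_i) ** 2)
    var_j = float(pj @ (np.arange(L) - mu_j) ** 2)
    if var_i <= 0 or var_j <= 0:
        correlation = float("nan")
    else:
        cov = float((P * (i - mu_i) * (j - mu_j)).sum())
        correlation = cov / np.sqrt(var_i * var_j)
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


def glcm_multi_offset(
    img: np.ndarray,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int = 16,
    symmetric: bool = True,
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Haralick statistics averaged over the four standard directions."""
    feats = [haralick(glcm(img, off, levels, symmetric, mask)) for off in offsets]
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


def batch_normalize(
    table: pd.DataFrame,
    feature_columns: list[str],
    batch_column: str = "batch",
    group_column: str = "group",
    control_label: str = "control",
    reference_batch: str | int | None = None,
) -> pd.DataFrame:
    """Rescale features so every batch's control median matches the reference.

    For each feature f and batch b the scale is
    median(f | reference controls) / median(f | b controls); all of b's
    values of f are multiplied by it.  The reference batch (the first batch
    in table order when not named) is unchanged.
    """
    out = table.copy()
    batches = list(pd.unique(out[batch_column]))
    if reference_batch is None:
        reference_batch = batches[0]
    if reference_batch not in batches:
        raise ValueError(f"reference batch {reference_batch!r} not present")
    controls = out[group_column] == control_label
    for b in batches:
        if not (controls & (out[batch_column] == b)).any():
            raise ValueError(f"batch {b!r} has no control samples")
    ref_ctrl = out[controls & (out[batch_column] == reference_batch)]
    for f in feature_columns:
        ref_med = float(ref_ctrl[f].median())
        for b in batches:
            if b == reference_batch:
                continue
            sel = out[batch_column] == b
            med = float(out.loc[sel & controls, f].median())
            if med == 0:
                raise ValueError(f"zero control median for {f!r} in batch {b!r}")
            # divide first: a control sitting exactly on its batch median
            # lands exactly on the reference median
            out.loc[sel, f] = out.loc[sel, f] / med * ref_med
    return out
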