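"""Gap, lacunarity and fractal-dimension statistics of binary fiber masks.

These describe the *texture of absence*: how the background between fibers
is organised.  Gaps are maximal inscribed circles in the background found
greedily from the Euclidean distance transform; lacunarity is the classic
gliding-box statistic Lambda(r) = E[m^2] / E[m]^2 of box occupancy; the
box-counting fractal dimension is the log-log slope of occupied-box counts
over dyadic box sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["Gap", "gap_analysis", "lacunarity", "box_counting_fd"]


@dataclass(frozen=True)
class Gap:
    center: tuple[int, int]  # row, col
    radius_px: float

    @property
    def area_px2(self) -> float:
        return float(np.pi * self.radius_px**2)


def gap_analysis(
    mask: np.ndarray, min_gap_radius_px: float = 2.0
) -> tuple[float, list[Gap]]:
    """Greedy maximal non-overlapping inscribed background circles.

    Repeatedly takes the background pixel farthest from any foreground
    (global EDT maximum), records the inscribed circle there, deletes its
    disk from the distance field and repeats while the radius stays at or
    above ``min_gap_radius_px``.  Returns the mean circle area (0.0 when no
    gap is found) and the list of gaps, largest first.
    """
    mask = np.asarray(mask, dtype=bool)
    gaps: list[Gap] = []
    if mask.size == 0 or not (~mask).any():
        return 0.0, gaps
    # the image border acts as foreground so inscribed circles stay inside
    # the field of view (also makes the all-background mask well defined)
    padded = np.pad(mask, 1, constant_values=True)
    dist = np.asarray(
        ndimage.distance_transform_edt(~padded), dtype=float
    )[1:-1, 1:-1]
    H, W = dist.shape
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    while True:
        idx = np.unravel_index(np.argmax(dist), dist.shape)
        r = float(dist[idx])
        if r < min_gap_radius_px:
            break
        gaps.append(Gap(center=(int(idx[0]), int(idx[1])), radius_px=r))
        # remove every candidate whose inscribed circle would overlap this
        # one (covers the recorded disk itself)
        d_center = np.sqrt((rows - idx[0]) ** 2.0 + (cols - idx[1]) ** 2.0)
        dist[dist > d_center - r] = 0.0
    mean_area = float(np.mean([g.area_px2 for g in gaps])) if gaps else 0.0
    return mean_area, gaps


def _box_masses(mask: np.ndarray, r: int) -> np.ndarray:
    """Occupied-pixel counts of every r x r gliding box (integral image)."""
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    return (
        ii[r:, r:] - ii[:-r, r:] - ii[r:, :-r] + ii[:-r, :-r]
    )


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Dyadic sizes 2, 4, 8, ... up to min(shape) / 4."""
    top = min(shape) // 4
    sizes, r = [], 2
    while r <= top:
        sizes.append(r)
        r *= 2
    return sizes or [1]


def lacunarity(
    mask: np.ndarray, box_sizes: list[int] | None = None
) -> tuple[float, dict[int, float]]:
    """Gliding-box lacunarity, summarised as the mean over box sizes.

    Lambda(r) = E[m^2] / E[m]^2 over all gliding r x r boxes, where m is the
    occupied-pixel count in a box.  Equals 1 for a homogeneous mask, grows
    with gappiness.  Returns (summary, per-size values).  An empty mask has
    undefined lacunarity (NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan"), {}
    if box_sizes is None:
        box_sizes = default_box_sizes(mask.shape)
    per_size: dict[int, float] = {}
    for r in box_sizes:
        if r < 1 or r > min(mask.shape):
            continue
        m = _box_masses(mask, r).astype(float)
        mean = m.mean()
        if mean == 0:
            continue
        per_size[r] = float((m**2).mean() / mean**2)
    if not per_size:
        return float("nan"), {}
    return float(np.mean(list(per_size.values()))), per_size


def box_counting_fd(mask: np.ndarray, box_sizes: list[int] | None = None) -> float:
    """Box-counting fractal dimension over dyadic grid partitions.

    Counts boxes of a non-overlapping eps x eps grid that contain foreground
    and fits log N(eps) against log(1/eps) by least squares.  Roughly 1 for
    curves, 2 for filled areas.  NaN for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    if box_sizes is None:
        top = min(mask.shape) // 4
        box_sizes, r = [], 1
        while r <= max(top, 1):
            box_sizes.append(r)
            r *= 2
    counts, sizes = [], []
    for eps in box_sizes:
        if eps < 1 or eps > min(mask.shape):
            continue
        H, W = mask.shape
        ph, pw = (-H) % eps, (-W) % eps
        padded = np.pad(mask, ((0, ph), (0, pw)))
        blocks = padded.reshape(
            padded.shape[0] // eps, eps, padded.shape[1] // eps, eps
        )
        n = int(blocks.any(axis=(1, 3)).sum())
        counts.append(n)
        sizes.append(eps)
    if len(sizes) < 2:
        return float("nan")
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes)), np.log(counts), 1)[0]
    return float(slope)
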