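"""Fiber centerline extraction and skeleton-graph metrics.

A binary fiber mask is thinned to a 1-px-wide centerline, which is then
traced into a graph whose nodes are junctions (8-neighbourhood degree >= 3)
and tips (degree 1) and whose edges are the ordered pixel paths between
them.  Closed loops without any junction are kept as cyclic edges.  Path
length uses the usual 1 / sqrt(2) axial / diagonal step convention, so a
horizontal run of 50 pixels has length 49.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _thin

__all__ = ["SkeletonGraph", "skeletonize", "trace_skeleton", "fiber_metrics", "curvature"]

_SQRT2 = float(np.sqrt(2.0))

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _path_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(path.astype(int), axis=0))
    diag = (steps.sum(axis=1) == 2)
    return float(np.sum(np.where(diag, _SQRT2, 1.0)))


@dataclass
class SkeletonGraph:
    """Traced fiber network: typed nodes plus ordered pixel-path edges."""

    endpoints: list[tuple[int, int]] = field(default_factory=list)
    branchpoints: list[tuple[int, int]] = field(default_factory=list)
    edges: list[np.ndarray] = field(default_factory=list)  # (n_i, 2) row/col paths

    @property
    def n_endpoints(self) -> int:
        return len(self.endpoints)

    @property
    def n_branchpoints(self) -> int:
        return len(self.branchpoints)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_length_px(self) -> float:
        return float(sum(_path_length(p) for p in self.edges))

    def edge_lengths(self) -> list[float]:
        return [_path_length(p) for p in self.edges]


def skeletonize(mask: np.ndarray) -> SkeletonGraph:
    """Thin a mask to its medial axis and trace the resulting graph."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return SkeletonGraph()
    return trace_skeleton(_thin(mask))


def trace_skeleton(skel: np.ndarray) -> SkeletonGraph:
    """Trace an already 1-px-wide skeleton into a :class:`SkeletonGraph`."""
    skel = np.asarray(skel, dtype=bool)
    deg = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                           mode="constant") - skel
    deg = np.where(skel, deg, 0)

    graph = SkeletonGraph()
    node_mask = skel & (deg != 2)
    branch_px = skel & (deg >= 3)
    for r, c in zip(*np.nonzero(skel & (deg == 1))):
        graph.endpoints.append((int(r), int(c)))
    # adjacent junction pixels form one physical branchpoint: cluster them
    labels, n_clusters = ndimage.label(branch_px, structure=np.ones((3, 3)))
    for i in range(1, n_clusters + 1):
        rr, cc = np.nonzero(labels == i)
        graph.branchpoints.append((int(round(rr.mean())), int(round(cc.mean()))))
    # deg 0: isolated pixel; counted as neither, contributes no length

    H, W = skel.shape

    def neighbors(r, c):
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and skel[rr, cc]:
                yield rr, cc

    used = set()  # directed steps already traced

    def walk(start, first):
        path = [start, first]
        used.add((start, first))
        used.add((first, start))
        prev, cur = start, first
        while not node_mask[cur]:
            nxt = [q for q in neighbors(*cur) if q != prev and (cur, q) not in used]
            if not nxt:
                break
            # prefer continuing to a non-node only when forced; any candidate
            # works on a clean skeleton where degree-2 pixels have one way out
            q = nxt[0]
            used.add((cur, q))
            used.add((q, cur))
            prev, cur = cur, q
            path.append(cur)
        return np.array(path)

    node_pixels = [(int(r), int(c)) for r, c in zip(*np.nonzero(node_mask))]
    for node in node_pixels:
        for q in neighbors(*node):
            if (node, q) not in used:
                path = walk(node, q)
                # paths that never leave a junction cluster are junction
                # interior, not fibers
                if not all(branch_px[r, c] for r, c in path):
                    graph.edges.append(path)

    # pure cycles: remaining degree-2 pixels not reached from any node
    visited = {tuple(p) for path in graph.edges for p in path}
    for r, c in zip(*np.nonzero(skel & (deg == 2))):
        p = (int(r), int(c))
        if p in visited:
            continue
        # trace the cycle and close it
        nbrs = list(neighbors(r, c))
        path = [p, nbrs[0]]
        prev, cur = p, nbrs[0]
        while cur != p:
            nxt = [q for q in neighbors(*cur) if q != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        visited.update(path)
        graph.edges.append(np.array(path))

    return graph


def fiber_metrics(sk: SkeletonGraph) -> dict[str, float]:
    """Length, branch/endpoint counts and their per-length normalizations.

    Normalized counts divide by total skeleton length; on an empty skeleton
    they are NaN (undefined), never zero, so correlation screens can drop
    them explicitly.
    """
    total = sk.total_length_px
    out = {
        "total_length_px": total,
        "n_branchpoints": float(sk.n_branchpoints),
        "n_endpoints": float(sk.n_endpoints),
    }
    if total > 0:
        out["norm_branchpoints"] = sk.n_branchpoints / total
        out["norm_endpoints"] = sk.n_endpoints / total
        out["avg_fiber_length_px"] = total / sk.n_edges
    else:
        out["norm_branchpoints"] = np.nan
        out["norm_endpoints"] = np.nan
        out["avg_fiber_length_px"] = np.nan
    return out


def _resample(path: np.ndarray, spacing: float) -> np.ndarray:
    """Points every `spacing` of arc length along a pixel path (linear interp)."""
    pts = path.astype(float)
    seg = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, s[-1] + 1e-9, spacing)
    out = np.empty((len(targets), 2))
    out[:, 0] = np.interp(targets, s, pts[:, 0])
    out[:, 1] = np.interp(targets, s, pts[:, 1])
    return out


def curvature(sk: SkeletonGraph, window_px: int = 10) -> float:
    """Mean absolute turn angle (degrees) between successive chords.

    Each edge of arc length >= 2 * window is resampled at `window_px` arc
    spacing; the angles between successive chords are averaged over all
    eligible edges.  NaN when no edge is long enough.
    """
    if window_px <= 0:
        raise ValueError("window_px must be positive")
    angles: list[float] = []
    for path, length in zip(sk.edges, sk.edge_lengths()):
        if length < 2 * window_px:
            continue
        pts = _resample(path, float(window_px))
        chords = np.diff(pts, axis=0)
        if len(chords) < 2:
            continue
        a, b = chords[:-1], chords[1:]
        dot = (a * b).sum(axis=1)
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        angles.extend(np.abs(np.degrees(np.arctan2(cross, dot))))
    if not angles:
        return float("nan")
    return float(np.mean(angles))
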