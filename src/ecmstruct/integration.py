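"""Correlation screening, the per-sample structure index, and target ranking.

The integrative step links matrix architecture to the transcriptomic
anti-TME score: every structural/textural metric is screened by Spearman
correlation against the per-sample score; metrics passing |r| >= 0.5 and
p <= 0.05 split into a positive and a negative set; each selected metric is
min-max scaled to [0, 1] across samples and the per-sample structure index
is

    index = (mean scaled positives + delta) / (mean scaled negatives + delta)

with a small smoothing constant delta keeping the ratio finite.  Candidate
matrix-gene targets are genes whose expression tracks the index in the
responsive model (|r| >= 0.5, p <= 0.05) while showing no association
(p > 0.05) in the non-responsive model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpearmanResult", "spearman", "MetricCorrelation",
    "select_correlated_metrics", "StructureIndexResult", "structure_index",
    "TargetRanking", "rank_matrisome_targets", "radar_scale",
]

EXACT_P_MAX_N = 9


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p: float
    n: int


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with small-sample exact permutation p.

    NaN entries are dropped pairwise.  For n <= 9 the two-sided p-value is
    exact over all n! pairings; beyond that the usual t approximation is
    used.  A constant vector yields NaN r and p (undefined), not an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    r = _spearman_r(x, y)
    if not np.isfinite(r):
        return SpearmanResult(float("nan"), float("nan"), n)
    if n <= EXACT_P_MAX_N:
        p = _exact_perm_p(x, y)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return SpearmanResult(r, p, n)


def _exact_perm_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p over all n! pairings (n <= 9).

    With the rank denominators fixed, |r| ordering equals the ordering of
    |sum(rx_c * ry_perm_c)|, so only the centered rank cross-products are
    enumerated (vectorized over all permutations).
    """
    import itertools

    rxc = stats.rankdata(x)
    ryc = stats.rankdata(y)
    rxc = rxc - rxc.mean()
    ryc = ryc - ryc.mean()
    obs = abs(float(rxc @ ryc))
    perms = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(ryc)),
        dtype=float,
    ).reshape(-1, len(ryc))
    all_stats = np.abs(perms @ rxc)
    return float(np.mean(all_stats >= obs - 1e-9))


@dataclass(frozen=True)
class MetricCorrelation:
    metric: str
    r: float
    p: float
    n: int
    sign: str  # "positive" | "negative" | "none" | "undefined"


def select_correlated_metrics(
    metrics: pd.DataFrame,
    scores: pd.Series,
    r_thresh: float = 0.5,
    p_thresh: float = 0.05,
) -> list[MetricCorrelation]:
    """Screen each metric column against the score vector.

    ``metrics`` is samples x metrics and must share its index with
    ``scores``.  Metrics with fewer than 4 complete pairs, or constant
    values, come back flagged ``undefined`` rather than silently dropped.
    """
    common = metrics.index.intersection(scores.index)
    if len(common) < len(metrics.index) or len(common) < len(scores.index):
        raise ValueError("metrics table and scores are not sample-aligned")
    out: list[MetricCorrelation] = []
    for m in metrics.columns:
        x = metrics.loc[common, m].to_numpy(dtype=float)
        y = scores.loc[common].to_numpy(dtype=float)
        try:
            res = spearman(x, y)
        except ValueError:
            out.append(MetricCorrelation(m, float("nan"), float("nan"),
                                         int(np.isfinite(x).sum()), "undefined"))
            continue
        if not np.isfinite(res.r):
            sign = "undefined"
        elif res.r >= r_thresh and res.p <= p_thresh:
            sign = "positive"
        elif res.r <= -r_thresh and res.p <= p_thresh:
            sign = "negative"
        else:
            sign = "none"
        out.append(MetricCorrelation(m, res.r, res.p, res.n, sign))
    return out


def _minmax(col: pd.Series) -> tuple[pd.Series, float, float]:
    lo, hi = float(col.min()), float(col.max())
    if hi == lo:
        raise ValueError(f"metric {col.name!r} has zero range across samples")
    return (col - lo) / (hi - lo), lo, hi


def _zscore(col: pd.Series) -> tuple[pd.Series, float, float]:
    mu, sd = float(col.mean()), float(col.std(ddof=0))
    if sd == 0:
        raise ValueError(f"metric {col.name!r} has zero range across samples")
    return (col - mu) / sd, mu, sd


@dataclass
class StructureIndexResult:
    index: pd.Series
    positive: list[str]
    negative: list[str]
    delta: float
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)


def structure_index(
    metrics: pd.DataFrame,
    positive: list[str],
    negative: list[str],
    delta: float = 0.1,
    scaling: str = "minmax",
) -> StructureIndexResult:
    """Per-sample ratio of scaled score-positive over score-negative metrics.

    Each selected metric is min-max scaled to [0, 1] across samples
    (z-scoring available via ``scaling="zscore"``, in which case negative
    values are possible and delta matters more); the index is the ratio of
    the means of the scaled positive and negative sets, smoothed by delta in
    numerator and denominator.
    """
    if not positive or not negative:
        raise ValueError("both the positive and the negative metric set "
                         "must be nonempty")
    if set(positive) & set(negative):
        raise ValueError("positive and negative metric sets overlap")
    scaler = {"minmax": _minmax, "zscore": _zscore}[scaling]
    record: dict[str, tuple[float, float]] = {}
    scaled = {}
    for m in positive + negative:
        s, a, b = scaler(metrics[m].astype(float))
        scaled[m] = s
        record[m] = (a, b)
    scaled = pd.DataFrame(scaled)
    num = scaled[positive].mean(axis=1) + delta
    den = scaled[negative].mean(axis=1) + delta
    idx = num / den
    idx.name = "structure_index"
    return StructureIndexResult(index=idx, positive=list(positive),
                                negative=list(negative), delta=delta,
                                scaling=record)


@dataclass(frozen=True)
class TargetRanking:
    gene: str
    r_model_a: float
    p_model_a: float
    r_model_b: float
    p_model_b: float
    direction: str  # "positive" | "negative" | "none"
    candidate: bool


def rank_matrisome_targets(
    expr_a: pd.DataFrame,
    index_a: pd.Series,
    expr_b: pd.DataFrame,
    index_b: pd.Series,
    matrisome_genes,
    r_thresh: float = 0.5,
    p_thresh: float = 0.05,
) -> tuple[list[TargetRanking], list[str]]:
    """Screen matrix genes for model-specific association with the index.

    A gene is a candidate when it passes |r| >= r_thresh and p <= p_thresh
    against the structure index in model A while staying non-significant
    (p > p_thresh) in model B; both association directions are kept, with
    the sign recorded.  Returns the rankings sorted by |r_A| descending and
    the list of requested genes absent from either expression universe.
    """
    matrisome = list(dict.fromkeys(matrisome_genes))
    missing = [g for g in matrisome
               if g not in expr_a.index or g not in expr_b.index]
    present = [g for g in matrisome if g not in missing]
    for expr, idx, name in ((expr_a, index_a, "A"), (expr_b, index_b, "B")):
        common = expr.columns.intersection(idx.index)
        if len(common) < 4:
            raise ValueError(f"model {name} has < 4 samples with index values")

    def corr(expr: pd.DataFrame, idx: pd.Series, g: str) -> SpearmanResult:
        common = expr.columns.intersection(idx.index)
        try:
            return spearman(expr.loc[g, common].to_numpy(),
                            idx.loc[common].to_numpy())
        except ValueError:
            return SpearmanResult(float("nan"), float("nan"), len(common))

    out: list[TargetRanking] = []
    for g in present:
        ra = corr(expr_a, index_a, g)
        rb = corr(expr_b, index_b, g)
        sig_a = (np.isfinite(ra.r) and abs(ra.r) >= r_thresh
                 and ra.p <= p_thresh)
        clean_b = np.isfinite(rb.p) and rb.p > p_thresh
        candidate = bool(sig_a and clean_b)
        direction = ("positive" if sig_a and ra.r > 0
                     else "negative" if sig_a else "none")
        out.append(TargetRanking(g, ra.r, ra.p, rb.r, rb.p, direction, candidate))
    out.sort(key=lambda t: (-(abs(t.r_model_a) if np.isfinite(t.r_model_a)
                              else -1.0), t.gene))
    return out, missing


def radar_scale(group_means: pd.DataFrame) -> pd.DataFrame:
    """Scale group-mean metrics to [0, 1] per metric for radar comparison.

    Each metric column is (v - min) / (max - min) over the groups; when all
    groups tie the convention maps everyone to 1 (full radius).
    """
    if len(group_means) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for m in group_means.columns:
        col = group_means[m].astype(float)
        lo, hi = float(col.min()), float(col.max())
        out[m] = pd.Series(1.0, index=col.index) if hi == lo else (col - lo) / (hi - lo)
    return pd.DataFrame(out)
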