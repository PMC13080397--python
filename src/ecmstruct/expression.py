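"""Bulk expression preprocessing, per-sample gene-set scoring and clustering.

Expression matrices are pandas DataFrames with genes as rows and samples as
columns; raw counts and log2 abundances are distinguished by the caller.
The per-sample scorer is the ssGSEA running-sum statistic: genes are ranked
by descending expression within a sample and the score is the accumulated
difference between the weighted in-set and uniform out-of-set empirical
distributions.  Being rank-based, it is invariant under any strictly
monotone transform of a sample's values.

The composite anti-tumor-microenvironment (anti-TME) score is the ssGSEA
score of the union of the M1, Th1, anti-tumor-cytokine and B-cell
signatures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignatureCollection", "ANTI_TME_COMPONENTS", "read_gmt", "write_gmt",
    "cpm_filter", "log_rpkm", "ssgsea_score", "score_collection",
    "kmeans_genes", "hypergeometric_overlap",
]

ANTI_TME_COMPONENTS = ("M1", "Th1", "anti_tumor_cytokines", "B_cells")


@dataclass
class SignatureCollection:
    """Named gene sets plus the composite anti-TME union set."""

    sets: dict[str, frozenset[str]]
    anti_tme_components: tuple[str, ...] = ANTI_TME_COMPONENTS

    def __post_init__(self):
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        for name, s in self.sets.items():
            if not s:
                raise ValueError(f"signature {name!r} is empty")

    def anti_tme(self) -> frozenset[str]:
        """Union of the component signatures present in the collection."""
        members = [self.sets[c] for c in self.anti_tme_components if c in self.sets]
        if not members:
            raise ValueError("no anti-TME component signatures present")
        return frozenset().union(*members)


def read_gmt(path) -> SignatureCollection:
    from gseapy import read_gmt as _read

    return SignatureCollection({k: frozenset(v) for k, v in _read(str(path)).items()})


def write_gmt(path, sigs: SignatureCollection | dict) -> None:
    sets = sigs.sets if isinstance(sigs, SignatureCollection) else sigs
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def cpm_filter(
    counts: pd.DataFrame, cpm_min: float = 1.0, sample_fraction: float = 0.25
) -> pd.DataFrame:
    """Keep genes with >= cpm_min counts-per-million in enough samples.

    A gene is kept iff its cpm reaches ``cpm_min`` in at least
    ceil(sample_fraction * n_samples) samples — the fraction is inclusive,
    so with 4 samples a single passing sample meets the 25% rule.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    cpm = counts.astype(float) * 1e6 / lib
    need = math.ceil(sample_fraction * counts.shape[1])
    keep = (cpm >= cpm_min).sum(axis=1) >= need
    return counts.loc[keep]


def log_rpkm(
    counts: pd.DataFrame, gene_lengths_bp: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(RPKM + pseudocount); RPKM = count * 1e9 / (library * length)."""
    missing = counts.index.difference(gene_lengths_bp.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for {sorted(missing)[:5]} ...")
    lengths = gene_lengths_bp.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    rpkm = counts.astype(float).mul(1e9).div(lib, axis=1).div(lengths, axis=0)
    return np.log2(rpkm + pseudocount)


def ssgsea_score(
    expr_column: pd.Series, gene_set, weight_exponent: float = 0.25
) -> float:
    """ssGSEA running-sum enrichment score of one sample.

    Genes are ordered by descending expression (ties broken by gene id);
    rank weights are rank^alpha for in-set genes. The score is the mean
    running difference between the weighted in-set CDF and the uniform
    out-of-set CDF.  By convention the score is 0 when the set covers the
    whole universe.
    """
    genes = expr_column.index
    gene_set = frozenset(gene_set) & frozenset(genes)
    if len(gene_set) < 2:
        raise ValueError("gene set must share >= 2 genes with the universe")
    n = len(genes)
    if len(gene_set) == n:
        return 0.0
    order = expr_column.sort_index().sort_values(ascending=False, kind="stable")
    in_set = np.fromiter((g in gene_set for g in order.index), bool, n)
    ranks = np.arange(n, 0, -1, dtype=float)  # highest expression -> rank n
    w = np.where(in_set, ranks**weight_exponent, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_set) / float(n - len(gene_set))
    return float(np.sum(p_in - p_out) / n)


def score_collection(
    expr: pd.DataFrame, sigs: SignatureCollection, weight_exponent: float = 0.25
) -> pd.DataFrame:
    """Per-sample scores for every named set plus the anti-TME union.

    Returns a samples x sets DataFrame with an ``anti_TME`` column.
    """
    sets = dict(sigs.sets)
    sets["anti_TME"] = sigs.anti_tme()
    out = {}
    for name, s in sets.items():
        out[name] = [
            ssgsea_score(expr[c], s, weight_exponent) for c in expr.columns
        ]
    return pd.DataFrame(out, index=expr.columns)


def kmeans_genes(
    expr_subset: pd.DataFrame, k: int = 7, seed: int = 0, restarts: int = 25
) -> pd.Series:
    """Cluster genes on z-scored profiles with restarted Euclidean K-means.

    Constant genes cannot be z-scored and are dropped with a warning; the
    best of ``restarts`` initialisations by within-cluster sum of squares is
    kept, deterministically for a given seed.
    """
    from sklearn.cluster import KMeans

    X = expr_subset.astype(float)
    sd = X.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant gene rows")
        X = X.loc[~const]
        sd = sd[~const]
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} usable genes")
    Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(Z.to_numpy())
    return pd.Series(labels, index=Z.index, name="cluster")


def hypergeometric_overlap(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p-value of the overlap |A & B|.

    P(X >= |A & B|) with X ~ Hypergeometric(N=|universe|, K=|A|, n=|B|).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = frozenset(set_a), frozenset(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
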