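"""Count filtering, RPKM transform, ssGSEA scoring, clustering, overlap test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ecmstruct.expression import (
    SignatureCollection, cpm_filter, hypergeometric_overlap, kmeans_genes,
    log_rpkm, score_collection, ssgsea_score,
)


def brute_force_ssgsea(values: dict, gene_set, alpha=0.25):
    """Step-by-step running-sum evaluation (independent oracle)."""
    order = sorted(values, key=lambda g: (-values[g], g))
    n = len(order)
    in_set = [g in gene_set for g in order]
    weights = [(n - i) ** alpha if in_set[i] else 0.0 for i in range(n)]
    wsum = sum(weights)
    osum = n - sum(in_set)
    p_in = p_out = 0.0
    es = 0.0
    for i in range(n):
        p_in += weights[i] / wsum
        p_out += (not in_set[i]) / osum
        es += p_in - p_out
    return es / n


class TestCpmFilter:
    def make_counts(self, rows, lib=1_000_000):
        genes = [f"g{i}" for i in range(len(rows))]
        df = pd.DataFrame(rows, index=genes)
        # pad with a high gene so library sizes hit the target exactly
        pad = [lib - df[c].sum() for c in df.columns]
        df.loc["pad"] = pad
        return df

    def test_all_zero_gene_removed(self):
        counts = self.make_counts([[0, 0, 0, 0], [50, 50, 50, 50]])
        kept = cpm_filter(counts)
        assert "g0" not in kept.index and "g1" in kept.index

    def test_single_passing_sample_meets_inclusive_25_percent(self):
        # cpm (1,0,0,0): passes in exactly 1/4 of samples -> kept
        counts = self.make_counts([[1, 0, 0, 0]])
        assert "g0" in cpm_filter(counts).index

    def test_high_count_genes_all_kept(self):
        counts = self.make_counts([[10, 10, 10, 10], [99, 99, 99, 99]])
        assert len(cpm_filter(counts)) == len(counts)

    def test_gene_order_irrelevant(self):
        counts = self.make_counts([[1, 0, 0, 0], [0, 0, 0, 0],
                                   [5, 5, 5, 5]])
        a = cpm_filter(counts)
        b = cpm_filter(counts.iloc[::-1])
        assert set(a.index) == set(b.index)

    def test_filter_subset_noncommutative_on_constructed_case(self):
        # a gene passing 25% on 4 samples can fail after dropping the one
        # sample that carried it: filtering and subsetting do not commute
        counts = self.make_counts([[1, 0, 0, 0]])
        kept_then_subset = cpm_filter(counts)[[1, 2, 3]]
        subset_then_kept = cpm_filter(counts[[1, 2, 3]])
        assert "g0" in kept_then_subset.index
        assert "g0" not in subset_then_kept.index

    def test_zero_library_rejected(self):
        counts = pd.DataFrame([[0, 5], [0, 5]], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="s1"):
            cpm_filter(counts)


class TestLogRpkm:
    def test_zero_count_maps_to_zero_with_default_pseudocount(self):
        counts = pd.DataFrame({"s": [0, 999_999 + 1]}, index=["g0", "g1"])
        lengths = pd.Series([1000, 1000], index=["g0", "g1"])
        out = log_rpkm(counts, lengths)
        assert out.loc["g0", "s"] == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # count 10, length 1000 bp, library 1e6 -> RPKM 10 -> log2(11)
        counts = pd.DataFrame({"s": [10, 1_000_000 - 10]},
                              index=["g0", "pad"])
        lengths = pd.Series([1000, 1000], index=["g0", "pad"])
        out = log_rpkm(counts, lengths)
        assert out.loc["g0", "s"] == pytest.approx(math.log2(11), abs=1e-9)

    def test_doubling_library_halves_rpkm(self):
        idx = ["g0", "g1"]
        lengths = pd.Series([500, 2000], index=idx)
        c1 = pd.DataFrame({"s": [100, 900]}, index=idx)
        c2 = pd.DataFrame({"s": [200, 1800]}, index=idx)  # same composition
        r1 = 2 ** log_rpkm(c1, lengths, pseudocount=0)
        r2 = 2 ** log_rpkm(c2, lengths, pseudocount=0)
        assert np.allclose(r1, r2)  # doubled counts and library cancel
        c3 = pd.DataFrame({"s": [100, 1900]}, index=idx)  # library doubled
        r3 = 2 ** log_rpkm(c3, lengths, pseudocount=0)
        assert r3.loc["g0", "s"] == pytest.approx(r1.loc["g0", "s"] / 2)

    def test_missing_length_rejected(self):
        counts = pd.DataFrame({"s": [1]}, index=["g0"])
        with pytest.raises(ValueError, match="missing gene length"):
            log_rpkm(counts, pd.Series(dtype=float))


class TestSsgsea:
    def test_five_gene_enumeration_oracle(self):
        values = {"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0}
        col = pd.Series(values)
        expected = brute_force_ssgsea(values, {"g1", "g3"})
        assert ssgsea_score(col, {"g1", "g3"}) == pytest.approx(expected)

    def test_random_columns_match_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        for _ in range(5):
            col = pd.Series(rng.normal(size=30), index=genes)
            gene_set = set(rng.choice(genes, size=8, replace=False))
            assert ssgsea_score(col, gene_set) == pytest.approx(
                brute_force_ssgsea(col.to_dict(), gene_set))

    def test_top_ranked_set_is_maximal_and_positive(self):
        genes = [f"g{i:02d}" for i in range(12)]
        col = pd.Series(np.arange(12, 0, -1, dtype=float), index=genes)
        top = ssgsea_score(col, set(genes[:4]))
        assert top > 0
        others = [
            ssgsea_score(col, set(combo))
            for combo in itertools.combinations(genes, 4)
        ]
        assert top == pytest.approx(max(others))

    def test_whole_universe_scores_zero(self):
        col = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        assert ssgsea_score(col, {"a", "b", "c"}) == 0.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(17)
        col = pd.Series(rng.normal(size=40),
                        index=[f"g{i}" for i in range(40)])
        s = set(col.index[:7])
        base = ssgsea_score(col, s)
        assert ssgsea_score(np.exp(col), s) == pytest.approx(base)
        assert ssgsea_score(col * 100 - 3, s) == pytest.approx(base)

    def test_too_small_overlap_rejected(self):
        col = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 2 genes"):
            ssgsea_score(col, {"a"})


class TestScoreCollection:
    def sigs(self):
        return SignatureCollection({
            "M1": {"g0", "g1"}, "Th1": {"g1", "g2"},
            "anti_tumor_cytokines": {"g3", "g4"}, "B_cells": {"g5", "g1"},
            "ECM": {"g8", "g9"},
        })

    def test_union_deduplicates_shared_genes(self):
        u = self.sigs().anti_tme()
        # g1 appears in M1, Th1 and B_cells but is counted once
        assert u == frozenset({"g0", "g1", "g2", "g3", "g4", "g5"})

    def test_per_sample_locality(self):
        rng = np.random.default_rng(23)
        expr = pd.DataFrame(rng.normal(size=(12, 4)),
                            index=[f"g{i}" for i in range(12)],
                            columns=list("wxyz"))
        base = score_collection(expr, self.sigs())
        shuffled = expr.copy()
        shuffled["w"] = rng.permutation(shuffled["w"].to_numpy())
        new = score_collection(shuffled, self.sigs())
        pd.testing.assert_frame_equal(base.drop(index="w"),
                                      new.drop(index="w"))

    def test_signature_shift_raises_anti_tme_score_monotonically(self):
        # shifts small enough that the union set never saturates the top
        # ranks (the score is rank-based and flat once it does)
        rng = np.random.default_rng(31)
        expr = pd.DataFrame(rng.normal(size=(60, 3)),
                            index=[f"g{i}" for i in range(60)],
                            columns=list("abc"))
        union = self.sigs().anti_tme()
        scores = []
        for shift in (0.0, 0.4, 0.8):
            shifted = expr.copy()
            shifted.loc[sorted(union)] += shift
            scores.append(score_collection(shifted, self.sigs())["anti_TME"])
        for s in scores[0].index:
            assert scores[0][s] < scores[1][s] < scores[2][s]


class TestKmeans:
    def test_single_cluster(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(10, 6)))
        labels = kmeans_genes(expr, k=1, seed=0)
        assert set(labels) == {0}

    def test_separated_groups_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        up = np.tile([10.0, -10.0, 10.0, -10.0, 10.0, -10.0], (15, 1))
        down = -up
        expr = pd.DataFrame(np.vstack([up, down]) + rng.normal(0, 1, (30, 6)),
                            index=[f"g{i}" for i in range(30)])
        truth = [0] * 15 + [1] * 15
        labels = kmeans_genes(expr, k=2, seed=1)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_same_seed_reproduces_assignment(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(rng.normal(size=(40, 8)))
        a = kmeans_genes(expr, k=7, seed=3)
        b = kmeans_genes(expr, k=7, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_constant_rows_dropped_with_warning_and_k_bound(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0],
                             [2.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="constant"):
            labels = kmeans_genes(expr, k=2, seed=0)
        assert 0 not in labels.index
        with pytest.warns(UserWarning, match="constant"), \
                pytest.raises(ValueError, match="exceeds"):
            kmeans_genes(expr, k=5, seed=0)


def brute_force_overlap_p(n_universe, k_a, k_b, overlap):
    """Exact combinatorial enumeration of P(|A & B| >= overlap)."""
    universe = list(range(n_universe))
    a = set(universe[:k_a])
    hits = total = 0
    for combo in itertools.combinations(universe, k_b):
        total += 1
        hits += len(a & set(combo)) >= overlap
    return hits / total


class TestHypergeometricOverlap:
    def test_disjoint_sets_give_p_one(self):
        u = [f"x{i}" for i in range(10)]
        assert hypergeometric_overlap(u[:3], u[3:6], u) == pytest.approx(1.0)

    def test_full_overlap_three_of_ten(self):
        u = [f"x{i}" for i in range(10)]
        p = hypergeometric_overlap(u[:3], u[:3], u)
        assert p == pytest.approx(1 / 120)

    def test_a_equals_universe(self):
        u = [f"x{i}" for i in range(8)]
        assert hypergeometric_overlap(u, u[:4], u) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,ka,kb,ov", [
        (10, 3, 3, 2), (12, 5, 4, 1), (9, 4, 4, 3), (12, 6, 6, 4),
    ])
    def test_matches_exhaustive_enumeration(self, n, ka, kb, ov):
        u = [f"x{i}" for i in range(n)]
        a, b = u[:ka], u[ka - ov:ka - ov + kb]
        assert len(set(a) & set(b)) == ov
        assert hypergeometric_overlap(a, b, u) == pytest.approx(
            brute_force_overlap_p(n, ka, kb, ov))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            hypergeometric_overlap([], [], [])
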