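"""Spearman screening, structure index, radar scaling and target ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecmstruct.integration import (
    radar_scale, rank_matrisome_targets, select_correlated_metrics, spearman,
    structure_index,
)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman(x, x * 3 + 1).r == pytest.approx(1.0)
        assert spearman(x, -x).r == pytest.approx(-1.0)

    def test_toy_rank_formula_and_exact_permutation_p(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        res = spearman(x, y)
        assert res.r == pytest.approx(1 - 6 * 4 / (5 * 24))  # = 0.8
        # oracle: enumerate all 120 pairings with scipy's r
        robs = abs(stats.spearmanr(x, y).statistic)
        hits = sum(
            abs(stats.spearmanr(x, perm).statistic) >= robs - 1e-12
            for perm in itertools.permutations(y)
        )
        assert res.p == pytest.approx(hits / 120)

    def test_nan_pairs_dropped(self):
        x = [1.0, 2, 3, np.nan, 5, 6]
        y = [2.0, 4, 6, 8, np.nan, 12]
        res = spearman(x, y)
        assert res.n == 4
        assert res.r == pytest.approx(1.0)

    def test_constant_vector_flagged_undefined(self):
        res = spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(res.r) and np.isnan(res.p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            spearman([1, 2, 3], [3, 2, 1])

    def test_large_n_uses_t_approximation_consistent_with_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


def toy_screen():
    rng = np.random.default_rng(6)
    idx = [f"s{i}" for i in range(20)]
    score = pd.Series(np.linspace(0, 1, 20) + rng.normal(0, 0.01, 20),
                      index=idx)
    metrics = pd.DataFrame({
        "identical": score.to_numpy(),
        "anti": -score.to_numpy(),
        "noise": rng.normal(size=20),
    }, index=idx)
    return metrics, score


class TestSelectCorrelatedMetrics:
    def test_identical_metric_is_positive_with_r_one(self):
        metrics, score = toy_screen()
        cors = {c.metric: c for c in select_correlated_metrics(metrics, score)}
        assert cors["identical"].sign == "positive"
        assert cors["identical"].r == pytest.approx(1.0)
        assert cors["anti"].sign == "negative"

    def test_constant_metric_flagged_not_dropped(self):
        metrics, score = toy_screen()
        metrics["flat"] = 1.0
        cors = {c.metric: c for c in select_correlated_metrics(metrics, score)}
        assert cors["flat"].sign == "undefined"

    def test_misaligned_samples_rejected(self):
        metrics, score = toy_screen()
        with pytest.raises(ValueError, match="aligned"):
            select_correlated_metrics(metrics.iloc[:10], score)


class TestStructureIndex:
    def test_three_sample_spreadsheet_oracle(self):
        metrics = pd.DataFrame({"pos": [1.0, 2.0, 3.0],
                                "neg": [3.0, 2.0, 1.0]},
                               index=list("abc"))
        res = structure_index(metrics, ["pos"], ["neg"], delta=0.1)
        # scaled pos (0, .5, 1), neg (1, .5, 0) -> (0.1/1.1, 0.6/0.6, 1.1/0.1)
        assert res.index.to_numpy() == pytest.approx(
            [0.1 / 1.1, 1.0, 11.0])

    def test_identical_scaled_patterns_give_unit_index(self):
        metrics = pd.DataFrame({"p": [0.0, 5.0, 10.0],
                                "n": [100.0, 150.0, 200.0]})
        res = structure_index(metrics, ["p"], ["n"])
        assert res.index.to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_extremal_sample_attains_max_index(self):
        rng = np.random.default_rng(9)
        metrics = pd.DataFrame(rng.uniform(1, 9, size=(8, 4)),
                               columns=["p1", "p2", "n1", "n2"])
        metrics.loc[0, ["p1", "p2"]] = 10.0
        metrics.loc[0, ["n1", "n2"]] = 0.0
        res = structure_index(metrics, ["p1", "p2"], ["n1", "n2"])
        assert res.index.idxmax() == 0

    def test_affine_rescaling_of_raw_metric_is_absorbed(self):
        rng = np.random.default_rng(13)
        metrics = pd.DataFrame(rng.uniform(size=(10, 2)), columns=["p", "n"])
        a = structure_index(metrics, ["p"], ["n"]).index
        metrics2 = metrics.assign(p=metrics["p"] * 37.0 - 4.0)
        b = structure_index(metrics2, ["p"], ["n"]).index
        assert a.to_numpy() == pytest.approx(b.to_numpy())

    def test_swapping_sets_inverts_the_ratio(self):
        rng = np.random.default_rng(14)
        metrics = pd.DataFrame(rng.uniform(size=(6, 2)), columns=["p", "n"])
        fwd = structure_index(metrics, ["p"], ["n"], delta=0.1)
        rev = structure_index(metrics, ["n"], ["p"], delta=0.1)
        assert (fwd.index * rev.index).to_numpy() == pytest.approx(
            np.ones(6))

    def test_empty_set_and_zero_range_rejected(self):
        metrics = pd.DataFrame({"p": [1.0, 2.0, 3.0], "n": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="nonempty"):
            structure_index(metrics, [], ["n"])
        with pytest.raises(ValueError, match="zero range"):
            structure_index(metrics, ["p"], ["n"])


class TestRadarScale:
    def test_extremes_and_midpoint(self):
        gm = pd.DataFrame({"m": [2.0, 4.0, 6.0]}, index=["g1", "g2", "g3"])
        out = radar_scale(gm)
        assert out["m"].to_list() == pytest.approx([0.0, 0.5, 1.0])

    def test_tied_metric_maps_everyone_to_one(self):
        gm = pd.DataFrame({"m": [3.0, 3.0], "k": [1.0, 2.0]})
        out = radar_scale(gm)
        assert out["m"].to_list() == [1.0, 1.0]
        assert out["k"].to_list() == pytest.approx([0.0, 1.0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            radar_scale(pd.DataFrame({"m": [1.0]}))


class TestTargetRanking:
    def make_models(self, seed=0, n=15):
        rng = np.random.default_rng(seed)
        sa = [f"a{i}" for i in range(n)]
        sb = [f"b{i}" for i in range(n)]
        idx_a = pd.Series(rng.uniform(0.5, 5, n), index=sa)
        idx_b = pd.Series(rng.uniform(0.5, 5, n), index=sb)
        genes = ["tgt", "both", "flat", "noise"]
        expr_a = pd.DataFrame({
            s: [idx_a[s] + rng.normal(0, 0.05),
                idx_a[s] + rng.normal(0, 0.05),
                1.0,
                rng.normal()]
            for s in sa}, index=genes)
        expr_b = pd.DataFrame({
            s: [rng.normal(),
                idx_b[s] + rng.normal(0, 0.05),
                1.0,
                rng.normal()]
            for s in sb}, index=genes)
        return expr_a, idx_a, expr_b, idx_b

    def test_model_specific_gene_is_candidate(self):
        ranks, missing = rank_matrisome_targets(*self.make_models(),
                                                ["tgt", "both", "flat"])
        byname = {r.gene: r for r in ranks}
        assert missing == []
        assert byname["tgt"].candidate
        assert byname["tgt"].direction == "positive"

    def test_gene_tracking_both_models_is_not_candidate(self):
        ranks, _ = rank_matrisome_targets(*self.make_models(),
                                          ["both"])
        assert not ranks[0].candidate

    def test_constant_gene_flagged_undefined_noncandidate(self):
        ranks, _ = rank_matrisome_targets(*self.make_models(), ["flat"])
        assert np.isnan(ranks[0].r_model_a)
        assert not ranks[0].candidate

    def test_missing_genes_reported_and_sorted_by_strength(self):
        ranks, missing = rank_matrisome_targets(
            *self.make_models(), ["noise", "tgt", "ghost"])
        assert missing == ["ghost"]
        assert ranks[0].gene == "tgt"  # strongest |r_A| first
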