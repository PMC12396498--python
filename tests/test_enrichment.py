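"""Preranked enrichment and MeanRank TF aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lactolink.data import GeneSetLibrary
from lactolink.enrichment import (
    MeanRankTF,
    PrerankedGSEA,
    fisher_overlap_test,
    meanrank_tf,
    preranked_enrichment,
    rank_metric,
)


def brute_force_es(scores, hit_flags, weight):
    """Independent running-sum walk computed step by step."""
    scores = np.asarray(scores, float)
    hits = np.asarray(hit_flags, bool)
    denom = np.sum(np.abs(scores[hits]) ** weight)
    n_miss = (~hits).sum()
    running, best, best_abs = 0.0, 0.0, -1.0
    for s, h in zip(scores, hits):
        if h:
            running += abs(s) ** weight / denom
        else:
            running -= 1.0 / n_miss
        if abs(running) > best_abs:
            best_abs, best = abs(running), running
    return best


def _ranked(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return pd.DataFrame({"gene": genes, "score": scores,
                         "log2fc": np.sign(scores), "pvalue": 0.5})


class TestRankMetric:
    def test_score_formula(self):
        de = pd.DataFrame({"gene": ["a", "b"], "log2fc": [2.0, -1.0],
                           "pvalue": [1e-3, 1e-2]})
        ranked = rank_metric(de)
        lookup = ranked.set_index("gene")["score"]
        assert lookup["a"] == pytest.approx(3.0)
        assert lookup["b"] == pytest.approx(-2.0)

    def test_zero_p_floored(self):
        de = pd.DataFrame({"gene": ["a"], "log2fc": [1.0], "pvalue": [0.0]})
        assert rank_metric(de)["score"].iloc[0] == pytest.approx(300.0)

    def test_missing_p_excluded(self):
        de = pd.DataFrame({"gene": ["a", "b"], "log2fc": [1.0, 1.0],
                           "pvalue": [0.5, np.nan]})
        assert list(rank_metric(de)["gene"]) == ["a"]

    def test_descending_order_with_ties_by_abs_lfc(self):
        de = pd.DataFrame({"gene": ["a", "b", "c"], "log2fc": [0.5, 2.0, 1.0],
                           "pvalue": [0.1, 0.1, 0.01]})
        assert list(rank_metric(de)["gene"]) == ["c", "b", "a"]


class TestPrerankedEnrichment:
    def test_toy_es_075(self):
        # universe (3,2,1,-1,-2) descending, set = 1st and 3rd genes
        ranked = _ranked([3.0, 2.0, 1.0, -1.0, -2.0])
        lib = GeneSetLibrary("toy", {"s": ["g0", "g2"]})
        res = preranked_enrichment(ranked, lib, weight=1.0, n_perm=100, seed=0)
        assert res.loc[0, "es"] == pytest.approx(0.75, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            scores = np.sort(rng.normal(size=n))[::-1]
            size = int(rng.integers(1, n - 1))
            members = rng.choice(n, size=size, replace=False)
            genes = [f"g{i}" for i in range(n)]
            ranked = _ranked(scores, genes)
            lib = GeneSetLibrary("r", {"s": [genes[i] for i in members]})
            res = preranked_enrichment(ranked, lib, weight=1.0, n_perm=100, seed=1)
            hits = np.zeros(n, bool)
            hits[members] = True
            assert res.loc[0, "es"] == pytest.approx(
                brute_force_es(scores, hits, 1.0), abs=1e-12
            )

    def test_weight_zero_reduces_to_ks_statistic(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = np.sort(rng.normal(size=n))[::-1]
            size = int(rng.integers(2, n - 2))
            members = rng.choice(n, size=size, replace=False)
            genes = [f"g{i}" for i in range(n)]
            ranked = _ranked(scores, genes)
            lib = GeneSetLibrary("r", {"s": [genes[i] for i in members]})
            res = preranked_enrichment(ranked, lib, weight=0.0, n_perm=100, seed=1)
            hit_pos = np.sort(members)
            miss_pos = np.setdiff1d(np.arange(n), hit_pos)
            ks = stats.ks_2samp(hit_pos, miss_pos, method="asymp").statistic
            assert abs(res.loc[0, "es"]) == pytest.approx(ks, abs=1e-10)

    def test_es_invariant_under_positive_rescaling(self, rng):
        scores = np.sort(rng.normal(size=20))[::-1]
        genes = [f"g{i}" for i in range(20)]
        lib = GeneSetLibrary("r", {"s": genes[2:8]})
        a = preranked_enrichment(_ranked(scores, genes), lib, n_perm=100, seed=2)
        b = preranked_enrichment(_ranked(scores * 7.5, genes), lib, n_perm=100, seed=2)
        assert a.loc[0, "es"] == pytest.approx(b.loc[0, "es"], rel=1e-12)

    def test_whole_universe_set_skipped(self):
        ranked = _ranked([2.0, 1.0, -1.0])
        lib = GeneSetLibrary("toy", {"all": ["g0", "g1", "g2"]})
        res = preranked_enrichment(ranked, lib, n_perm=100, seed=0)
        assert len(res) == 0

    def test_leading_edge_within_set_and_universe(self, small_dataset, rng):
        genes = [f"g{i}" for i in range(30)]
        scores = np.sort(rng.normal(size=30))[::-1]
        members = genes[1:9]
        lib = GeneSetLibrary("toy", {"s": members})
        res = preranked_enrichment(_ranked(scores, genes), lib, n_perm=100, seed=0)
        le = res.loc[0, "leading_edge"]
        assert set(le) <= set(members)
        assert len(le) >= 1

    def test_permutation_p_roughly_uniform_for_random_sets(self, rng):
        genes = [f"g{i}" for i in range(60)]
        rejections = []
        for rep in range(60):
            scores = rng.normal(size=60)
            scores = np.sort(scores)[::-1]
            members = rng.choice(genes, size=10, replace=False)
            lib = GeneSetLibrary("r", {"s": list(members)})
            res = preranked_enrichment(_ranked(scores, genes), lib,
                                       n_perm=100, seed=int(rep))
            rejections.append(res.loc[0, "pvalue"] <= 0.2)
        assert np.mean(rejections) <= 0.40


class TestFisherOverlap:
    def test_matches_enumeration(self):
        # background 100, input 10, tf set 20, overlap 5
        got = fisher_overlap_test([f"i{i}" for i in range(5)] + ["x1", "x2", "x3", "x4", "x5"],
                                  [f"i{i}" for i in range(5)] + [f"t{i}" for i in range(15)],
                                  background_size=100)
        tot = math.comb(100, 10)
        want = sum(
            math.comb(20, j) * math.comb(80, 10 - j) for j in range(5, 11)
        ) / tot
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_overlap_is_certain_event(self):
        assert fisher_overlap_test(["a"], ["b"], 10) == pytest.approx(1.0)

    def test_full_overlap_is_minimal_attainable_p(self):
        # input subset of tf set entirely: smallest p for these margins
        input_set = ["a", "b", "c"]
        tf = ["a", "b", "c", "d"]
        p_full = fisher_overlap_test(input_set, tf, 50)
        p_partial = fisher_overlap_test(["a", "b", "x"], tf, 50)
        assert p_full < p_partial

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            fisher_overlap_test([], ["a"], 10)


class TestMeanRank:
    def _libraries(self):
        libA = GeneSetLibrary("libA", {
            "TF1 chip": ["i0", "i1", "i2", "x0", "x1"],
            "TF2 chip": ["i0", "x2", "x3", "x4"],
            "TF3 chip": ["x5", "x6", "x7"],
        })
        libB = GeneSetLibrary("libB", {
            "TF1 coexp": ["i0", "x0"],
            "TF2 coexp": ["i0", "i1", "i2", "i3"],
        })
        return [libA, libB]

    def test_mean_of_two_ranks(self):
        input_set = {f"i{i}" for i in range(5)}
        out = meanrank_tf(input_set, self._libraries(), background_size=50)
        tf1 = out.set_index("tf").loc["TF1"]
        assert tf1["n_libraries"] == 2
        assert tf1["mean_rank"] == pytest.approx(
            np.mean(list(tf1["library_ranks"].values()))
        )

    def test_single_library_reduces_to_its_ordering(self):
        input_set = {f"i{i}" for i in range(5)}
        [libA, _] = self._libraries()
        out = meanrank_tf(input_set, [libA], background_size=50)
        assert list(out["mean_rank"]) == sorted(out["mean_rank"])
        assert set(out["tf"]) == {"TF1", "TF2", "TF3"}

    def test_matches_hand_enumeration(self):
        """Full ordering against an independent FET + BH + rank computation."""
        from statsmodels.stats.multitest import multipletests

        input_set = {f"i{i}" for i in range(5)}
        background = 50
        libs = self._libraries()
        expected_ranks = {}
        for lib in libs:
            rows = []
            for set_name, genes in lib.sets.items():
                k = len(input_set & set(genes))
                tot = math.comb(background, len(input_set))
                p = sum(
                    math.comb(len(genes), j)
                    * math.comb(background - len(genes), len(input_set) - j)
                    for j in range(k, min(len(genes), len(input_set)) + 1)
                ) / tot
                rows.append((set_name.split(" ")[0], p))
            df = pd.DataFrame(rows, columns=["tf", "p"])
            df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
            df = df.sort_values(["tf", "p"]).groupby("tf").first().reset_index()
            df = df.sort_values(["padj", "p", "tf"]).reset_index(drop=True)
            for rank, tf in enumerate(df["tf"], start=1):
                expected_ranks.setdefault(tf, {})[lib.name] = rank
        expected_mean = {tf: np.mean(list(r.values())) for tf, r in expected_ranks.items()}

        out = meanrank_tf(input_set, libs, background_size=background)
        for _, row in out.iterrows():
            assert row["mean_rank"] == pytest.approx(expected_mean[row["tf"]])
            assert row["library_ranks"] == expected_ranks[row["tf"]]

    def test_ordering_invariant_to_library_order(self):
        input_set = {f"i{i}" for i in range(5)}
        libs = self._libraries()
        a = meanrank_tf(input_set, libs, background_size=50)
        b = meanrank_tf(input_set, libs[::-1], background_size=50)
        pd.testing.assert_frame_equal(a, b)


class TestEstimators:
    def test_gsea_estimator_seeded_reproducible(self, rng):
        genes = [f"g{i}" for i in range(30)]
        scores = np.sort(rng.normal(size=30))[::-1]
        lib = GeneSetLibrary("r", {"s": genes[:6], "t": genes[10:20]})
        a = PrerankedGSEA(n_perm=200, seed=5).fit(_ranked(scores, genes), lib).results_
        b = PrerankedGSEA(n_perm=200, seed=5).fit(_ranked(scores, genes), lib).results_
        pd.testing.assert_frame_equal(a, b)

    def test_meanrank_estimator_interface(self):
        model = MeanRankTF(background_size=50)
        out = model.fit({"i0", "i1"}, [GeneSetLibrary("L", {"TF1 x": ["i0", "a"]})])
        assert "mean_rank" in out.results_.columns
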