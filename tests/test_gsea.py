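"""Preranked GSEA: ranking, running-sum ES, permutation NES/FDR, run overlap."""

import numpy as np
import pandas as pd
import pytest

from gseacmap import (DeTable, GeneSetCollection, PipelineConfig,
                      ValidationError, compare_runs, enrichment_score,
                      permutation_stats, rank_genes)
from gseacmap.gsea import RankedList, _batch_es

from oracles import brute_force_es


def _de(logfc, p, genes=None):
    genes = genes or [chr(ord("a") + i) for i in range(len(logfc))]
    table = pd.DataFrame({
        "logFC": logfc, "avg_expr": 1.0, "s2": 1.0, "t": 0.0,
        "df_total": 4.0, "p": p, "fdr": p,
    }, index=genes)
    return DeTable(table, 4.0, 1.0)


class TestRanking:
    def test_tie_broken_by_smaller_p_then_id(self):
        ranked = rank_genes(_de([2.0, 2.0, -1.0], [0.01, 0.2, 0.5]))
        assert ranked.genes == ["a", "b", "c"]
        assert ranked.n_tied == 2

    def test_distinct_scores_sort_descending(self):
        ranked = rank_genes(_de([1.0, 3.0, -2.0, 0.5], [0.1] * 4))
        assert ranked.genes == ["b", "a", "d", "c"]

    def test_ranking_is_a_permutation(self):
        rng = np.random.default_rng(0)
        logfc = rng.normal(size=2000)
        genes = [f"g{i}" for i in range(2000)]
        ranked = rank_genes(_de(list(logfc), [0.5] * 2000, genes))
        assert sorted(ranked.genes) == sorted(genes)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            rank_genes(DeTable(pd.DataFrame(
                columns=["logFC", "avg_expr", "s2", "t", "df_total", "p", "fdr"]),
                4.0, 1.0))


class TestEnrichmentScore:
    def test_single_member_at_top_is_one(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(10, 0, -1.0))
        es, profile, hits = enrichment_score(ranked, {"g0"}, exponent=1.0)
        assert es == pytest.approx(1.0)
        assert list(hits) == [0]
        assert len(profile) == 10

    def test_single_member_at_bottom_is_minus_one(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(10, 0, -1.0))
        es, profile, _ = enrichment_score(ranked, {"g9"}, exponent=0.0)
        assert es == pytest.approx(-1.0)  # running sum reaches -9/9 just before the hit
        assert profile[-2] == pytest.approx(-1.0)

    def test_hand_run_worked_example(self):
        # N=5, scores (5,4,3,2,1), hits at positions 2 and 4 (1-based), p=1:
        # running sum: -1/3, +1/3, 0, +1/3, 0 -> ES = +1/3
        ranked = RankedList(list("abcde"), np.array([5.0, 4.0, 3.0, 2.0, 1.0]))
        es, profile, _ = enrichment_score(ranked, {"b", "d"}, exponent=1.0)
        assert np.allclose(profile, [-1 / 3, 1 / 3, 0, 1 / 3, 0])
        assert es == pytest.approx(1 / 3)

    def test_degenerate_sets_rejected(self):
        ranked = RankedList(list("abc"), np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValidationError):
            enrichment_score(ranked, {"z"})
        with pytest.raises(ValidationError):
            enrichment_score(ranked, {"a", "b", "c"})

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            exponent = float(rng.choice([0.0, 1.0, 2.0]))
            ranked = RankedList(genes, scores)
            es, _, _ = enrichment_score(ranked, members, exponent)
            flags = [g in members for g in genes]
            assert es == pytest.approx(
                brute_force_es(list(scores), flags, exponent), abs=1e-12)

    def test_batch_es_equals_single_path(self):
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(size=40))[::-1]
        genes = [f"g{i}" for i in range(40)]
        ranked = RankedList(genes, scores)
        absw = np.abs(scores)
        for _ in range(50):
            pos = np.sort(rng.choice(40, size=7, replace=False))
            es_single, _, _ = enrichment_score(ranked, {genes[i] for i in pos})
            assert _batch_es(pos[None, :], absw, 40)[0] == pytest.approx(es_single, abs=1e-12)

    def test_reversal_negates_es(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            members = set(rng.choice(genes, size=int(rng.integers(1, n)), replace=False))
            es_fwd, prof, _ = enrichment_score(RankedList(genes, scores), members)
            es_rev, _, _ = enrichment_score(
                RankedList(genes[::-1], -scores[::-1]), members)
            assert abs(es_rev) == pytest.approx(abs(es_fwd), abs=1e-12)
            # the sign flips except on an exact max/min magnitude tie, where
            # both directions resolve to the preferred positive deviation
            if abs(prof.max() + prof.min()) > 1e-9:
                assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_exponent_zero_invariant_to_monotone_rescale(self):
        genes = [f"g{i}" for i in range(20)]
        scores = np.linspace(5, -5, 20)
        members = {"g2", "g7", "g15"}
        es1, _, _ = enrichment_score(RankedList(genes, scores), members, exponent=0.0)
        es2, _, _ = enrichment_score(RankedList(genes, scores * 17.3), members, exponent=0.0)
        assert es1 == pytest.approx(es2, abs=1e-15)

    def test_exponent_one_invariant_to_positive_scaling(self):
        genes = [f"g{i}" for i in range(20)]
        scores = np.linspace(5, -5, 20)
        members = {"g2", "g7", "g15"}
        es1, _, _ = enrichment_score(RankedList(genes, scores), members, exponent=1.0)
        es2, _, _ = enrichment_score(RankedList(genes, scores * 3.5), members, exponent=1.0)
        assert es1 == pytest.approx(es2, abs=1e-12)


class TestPermutationStats:
    def _collection(self, rng, genes, n_sets=50, size=(5, 40)):
        sets = {}
        for i in range(n_sets):
            k = int(rng.integers(*size))
            sets[f"S{i:03d}"] = frozenset(rng.choice(genes, size=k, replace=False))
        return GeneSetCollection(sets)

    def test_extreme_signal_floors_p_and_passes_fdr(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(2000)]
        scores = np.sort(rng.normal(size=2000))[::-1]
        ranked = RankedList(genes, scores)
        coll = self._collection(rng, genes, n_sets=20)
        coll.sets["TOP"] = frozenset(genes[:20])
        cfg = PipelineConfig(n_perm=1000, seed=5)
        res = permutation_stats(ranked, coll, cfg)
        row = res.table.loc["TOP"]
        assert row["p"] == pytest.approx(1 / 1001)
        assert row["q"] < 0.25
        assert row["enriched"]

    def test_null_calibration_over_seeds(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(1000)]
            scores = np.sort(rng.normal(size=1000))[::-1]
            ranked = RankedList(genes, scores)
            coll = self._collection(rng, genes, n_sets=50)
            cfg = PipelineConfig(n_perm=200, seed=seed)
            res = permutation_stats(ranked, coll, cfg)
            fracs.append(float((res.table["q"] < 0.25).mean()))
        assert np.mean(fracs) <= 0.25

    def test_monte_carlo_stability_in_permutation_count(self, small_sim):
        sim, counts, genesets, _, _ = small_sim
        from gseacmap import run_de
        de = run_de(counts, PipelineConfig(seed=1))
        ranked = rank_genes(de)
        res1 = permutation_stats(ranked, genesets, PipelineConfig(n_perm=1000, seed=1))
        res2 = permutation_stats(ranked, genesets, PipelineConfig(n_perm=2000, seed=1))
        common = res1.table.index.intersection(res2.table.index)
        dp = (res1.table.loc[common, "p"] - res2.table.loc[common, "p"]).abs()
        assert dp.max() < 0.02


class TestCompareRuns:
    def _result(self, enriched, names=("A", "B", "C", "D")):
        table = pd.DataFrame({
            "size": 10, "es": [0.5 if n in enriched else 0.1 for n in names],
            "nes": 1.0, "p": 0.01, "q": 0.01,
            "direction": [enriched.get(n, "up") for n in names],
            "enriched": [n in enriched for n in names],
            "unstable": False,
        }, index=pd.Index(names, name="set"))
        from gseacmap.gsea import GseaResult
        return GseaResult(table, 100, 1.0, 0, tuple(sorted(names)))

    def test_identical_results_have_unit_jaccard(self):
        r = self._result({"A": "up", "B": "down"})
        out = compare_runs(r, r)
        assert out["jaccard"] == 1.0
        assert out["both"] == {"up": ["A"], "down": ["B"]}

    def test_disjoint_enrichment_zero_jaccard(self):
        out = compare_runs(self._result({"A": "up"}), self._result({"B": "down"}))
        assert out["jaccard"] == 0.0
        assert out["a_only"]["up"] == ["A"]
        assert out["b_only"]["down"] == ["B"]

    def test_different_collections_rejected(self):
        with pytest.raises(ValidationError):
            compare_runs(self._result({}, names=("A", "B", "C", "D")),
                         self._result({}, names=("A", "B", "C", "E")))

    def test_shared_planted_program_found_in_both_cell_lines(self):
        # two synthetic "cell lines" = two count draws of the same planted
        # truth; the planted sets should be called in both runs
        from gseacmap import SimConfig, generate_experiment, generate_genesets, run_de
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            sim_a = SimConfig(seed=seed)
            sim_b = SimConfig(seed=seed, n_reps=4)  # second line: same truth, new noise
            cm_a, truth = generate_experiment(sim_a)
            cm_b, _ = generate_experiment(sim_b)
            genesets = generate_genesets(sim_a)
            cfg = PipelineConfig(n_perm=200, seed=seed)
            res_a = permutation_stats(rank_genes(run_de(cm_a, cfg)), genesets, cfg)
            res_b = permutation_stats(rank_genes(run_de(cm_b, cfg)), genesets, cfg)
            out = compare_runs(res_a, res_b)
            both = set(out["both"]["up"]) | set(out["both"]["down"])
            if set(truth.shared_programs) <= both:
                hits += 1
        assert hits >= 0.9 * n_seeds
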