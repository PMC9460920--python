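"""Connectivity-map scoring: KS statistic, scaled scores, hit selection."""

import numpy as np
import pandas as pd
import pytest

from gseacmap import (DeTable, PipelineConfig, QuerySignature,
                      SignatureReference, ValidationError,
                      connectivity_scores, extract_hit_signatures,
                      ks_statistic, make_query, select_hits)
from gseacmap.connectivity import ConnectivityTable
from gseacmap.simulate import SimConfig, generate_genesets, generate_reference

from oracles import ks_oracle


def _reference(values, genes=None, compounds=None):
    values = np.asarray(values, dtype=float)
    g, k = values.shape
    genes = genes or [f"g{i}" for i in range(g)]
    instances = [f"i{j}" for j in range(k)]
    compounds = compounds or [f"c{j}" for j in range(k)]
    meta = pd.DataFrame({
        "instance_id": instances,
        "compound": compounds,
        "moa_class": [f"m{j % 2}" for j in range(k)],
        "cell_line": "L",
    }).set_index("instance_id")
    return SignatureReference(genes, instances, values, meta)


class TestKsStatistic:
    def test_tags_at_top(self):
        # t=2, N=10, V=(1,2): a = max(1/2 - 1/10, 1 - 2/10) = 0.8
        assert ks_statistic(np.array([1, 2]), 10) == pytest.approx(0.8)

    def test_tags_at_bottom(self):
        # V=(9,10): b = max(9/10 - 0, 1 - 1/2) = 0.9 -> statistic -0.9
        assert ks_statistic(np.array([9, 10]), 10) == pytest.approx(-0.9)

    def test_uniform_spread_is_small(self):
        v = np.arange(10, 101, 10)  # 10, 20, ..., 100 in N = 100
        assert abs(ks_statistic(v, 100)) <= 0.15

    def test_empty_tag_set_rejected(self):
        with pytest.raises(ValidationError):
            ks_statistic(np.array([]), 10)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(500):
            n = int(rng.integers(4, 21))
            t = int(rng.integers(1, min(6, n)))
            v = rng.choice(np.arange(1, n + 1), size=t, replace=False)
            assert ks_statistic(v, n) == ks_oracle(list(v), n)


class TestMakeQuery:
    def _de(self, n_up, n_down, n_ns):
        status = ["up"] * n_up + ["down"] * n_down + ["ns"] * n_ns
        n = len(status)
        table = pd.DataFrame({
            "logFC": [2] * n_up + [-2] * n_down + [0] * n_ns,
            "avg_expr": 1.0, "s2": 1.0,
            "t": np.linspace(10, 1, n),
            "df_total": 4.0, "p": 0.01, "fdr": 0.01, "status": status,
        }, index=[f"g{i}" for i in range(n)])
        return DeTable(table, 4.0, 1.0)

    def test_tail_sizes_match_status_counts(self):
        q = make_query(self._de(601, 730, 100), PipelineConfig())
        assert len(q.up) == 601 and len(q.down) == 730

    def test_cap_selects_largest_t(self):
        de = self._de(10, 10, 0)
        q = make_query(de, PipelineConfig(), n_sig=4)
        assert len(q.up) == 4 and len(q.down) == 4
        # the up tail holds the 4 largest |t| among up genes (listed first)
        assert q.up == frozenset(f"g{i}" for i in range(4))

    def test_all_ns_rejected(self):
        with pytest.raises(ValidationError, match="both tails"):
            make_query(self._de(0, 0, 10), PipelineConfig())


class TestConnectivityScores:
    def test_self_query_attains_plus_100(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            vals = np.random.default_rng(seed).normal(size=(100, 4))
            ref = _reference(vals)
            order = np.argsort(-vals[:, 1])
            up = {f"g{i}" for i in order[:10]}
            down = {f"g{i}" for i in order[-10:]}
            table = connectivity_scores(ref, QuerySignature(up, down))
            assert table.instances.loc[1, "score"] == pytest.approx(100.0)

    def test_swapping_tails_negates_scores(self):
        vals = np.random.default_rng(8).normal(size=(60, 5))
        ref = _reference(vals)
        up = {f"g{i}" for i in range(0, 8)}
        down = {f"g{i}" for i in range(30, 38)}
        t1 = connectivity_scores(ref, QuerySignature(up, down))
        t2 = connectivity_scores(ref, QuerySignature(down, up))
        np.testing.assert_allclose(t1.instances["s"], -t2.instances["s"], atol=1e-12)
        np.testing.assert_allclose(t1.instances["score"], -t2.instances["score"], atol=1e-12)

    def test_scale_invariance_of_reference_values(self):
        vals = np.random.default_rng(4).normal(size=(50, 3))
        up = {f"g{i}" for i in range(5)}
        down = {f"g{i}" for i in range(20, 25)}
        t1 = connectivity_scores(_reference(vals), QuerySignature(up, down))
        t2 = connectivity_scores(_reference(vals * 37.0), QuerySignature(up, down))
        np.testing.assert_allclose(t1.instances["score"], t2.instances["score"], atol=1e-12)

    def test_toy_matches_brute_force(self):
        vals = np.random.default_rng(2).normal(size=(10, 3))
        ref = _reference(vals)
        up = {"g0", "g3"}
        down = {"g7", "g9"}
        table = connectivity_scores(ref, QuerySignature(up, down))
        for j in range(3):
            ranks = {f"g{i}": r for i, r in enumerate(ref.ranks[:, j])}
            ks_up = ks_oracle([ranks[g] for g in up], 10)
            ks_down = ks_oracle([ranks[g] for g in down], 10)
            s = 0.0 if np.sign(ks_up) == np.sign(ks_down) else ks_up - ks_down
            assert table.instances.loc[j, "s"] == pytest.approx(s, abs=1e-14)

    def test_one_instance_attains_max_magnitude(self):
        vals = np.random.default_rng(10).normal(size=(80, 6))
        ref = _reference(vals)
        up = {f"g{i}" for i in range(6)}
        down = {f"g{i}" for i in range(40, 46)}
        table = connectivity_scores(ref, QuerySignature(up, down))
        assert np.max(np.abs(table.instances["score"])) == pytest.approx(100.0)

    def test_empty_reference_rejected(self):
        genes = ["g0", "g1"]
        meta = pd.DataFrame(columns=["compound", "moa_class", "cell_line"])
        ref = SignatureReference(genes, [], np.empty((2, 0)), meta)
        with pytest.raises(ValidationError, match="empty reference"):
            connectivity_scores(ref, QuerySignature({"g0"}, {"g1"}))


class TestSelectHits:
    def _table(self, scores):
        compounds = pd.DataFrame({
            "compound": [f"c{i}" for i in range(len(scores))],
            "moa_class": "m0", "cell_line": "L",
            "score": scores, "median_score": scores,
            "best_instance": [f"c{i}_i" for i in range(len(scores))],
        })
        return ConnectivityTable(pd.DataFrame({"score": scores}), compounds)

    def test_window_boundaries_inclusive(self):
        hits = select_hits(self._table([99.2, 96.0, 95.0, 94.9]), PipelineConfig())
        assert hits.compounds == ["c0", "c1", "c2"]

    def test_truncation_to_top_k(self):
        hits = select_hits(self._table(list(np.linspace(100, 95.5, 12))), PipelineConfig())
        assert len(hits.hits) == 10

    def test_zero_hits_is_empty_not_error(self):
        hits = select_hits(self._table([10.0, 20.0]), PipelineConfig())
        assert len(hits.hits) == 0 and hits.by_class == {}

    def test_matched_class_compound_among_hits_across_seeds(self):
        from gseacmap import run_de, PipelineConfig as PC
        from gseacmap.simulate import generate_experiment
        found = 0
        n_seeds = 20
        for seed in range(n_seeds):
            sim = SimConfig(seed=seed, n_genes=800, n_sets=30,
                            n_compounds=9, n_classes=3)
            cm, truth = generate_experiment(sim)
            genesets = generate_genesets(sim)
            ref, _ = generate_reference(sim, genesets)
            cfg = PC(seed=seed)
            de = run_de(cm, cfg)
            q = make_query(de, cfg)
            hits = select_hits(connectivity_scores(ref, q), cfg)
            classes = set(hits.hits["moa_class"])
            if truth.matched_class in classes:
                found += 1
        assert found >= 0.95 * n_seeds

    def test_matched_instances_outrank_unmatched_across_seeds(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            sim = SimConfig(seed=seed, n_genes=600, n_sets=25, n_compounds=6)
            genesets = generate_genesets(sim)
            ref, truth = generate_reference(sim, genesets)
            up = frozenset(g for g, v in truth.de_genes.items() if v > 0)
            down = frozenset(g for g, v in truth.de_genes.items() if v < 0)
            table = connectivity_scores(ref, QuerySignature(up, down))
            inst = table.instances
            matched = inst[inst["moa_class"] == truth.matched_class]["s"]
            other = inst[inst["moa_class"] != truth.matched_class]["s"]
            if matched.min() > other.max():
                wins += 1
        assert wins == n_seeds


class TestExtractSignatures:
    def test_extracted_list_is_universe_permutation_and_verbatim(self):
        sim = SimConfig(seed=2, n_genes=300, n_sets=15, n_compounds=4,
                        n_classes=2, instances_per_compound=1)
        genesets = generate_genesets(sim)
        ref, _ = generate_reference(sim, genesets)
        hits = select_hits(
            connectivity_scores(ref, QuerySignature(
                frozenset(ref.genes[:20]), frozenset(ref.genes[50:70]))),
            PipelineConfig(score_window=(-100, 100)))
        sigs = extract_hit_signatures(ref, hits, n_sig=30)
        for compound, sig in sigs.items():
            ranked = sig["ranked"]
            assert sorted(ranked.genes) == sorted(ref.genes)
            j = ref.instances.index(sig["instance"])
            top_gene = ranked.genes[0]
            assert ref.values[ref.genes.index(top_gene), j] == ranked.scores[0]
            assert len(sig["top"]) == 30 and len(sig["bottom"]) == 30

    def test_noiseless_same_compound_instances_identical(self):
        sim = SimConfig(seed=4, n_genes=200, n_sets=15, n_compounds=4,
                        n_classes=2, signature_noise_sd=0.0)
        genesets = generate_genesets(sim)
        ref, _ = generate_reference(sim, genesets)
        # both instances of each compound share the same planted program
        for cpd in ("CPD001", "CPD002"):
            cols = [k for k, inst in enumerate(ref.instances) if inst.startswith(cpd)]
            assert np.array_equal(ref.ranks[:, cols[0]], ref.ranks[:, cols[1]])
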