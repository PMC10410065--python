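"""Level expansion, hypergeometric enrichment and the bootstrap null."""

import numpy as np
import pandas as pd
import pytest

import pleiopipe as pp
from pleiopipe import ppin as pn
from pleiopipe.grn import Grn

from oracles import bfs_levels_matrix, hypergeom_tail


def grn_from_pairs(pairs):
    df = pd.DataFrame(
        [{"snp": s, "gene": g, "beta": 0.1, "se": 0.05, "p": 1e-8,
          "p_adjusted": 1e-6, "interaction_class": "cis", "gene_tpm": 1.0}
         for s, g in pairs]
    )
    return Grn(df)


def ppin_from_edges(edges, genes):
    df = pd.DataFrame(
        [{"protein_a": a, "protein_b": b, "score": s} for a, b, s in edges],
        columns=["protein_a", "protein_b", "score"],
    )
    return pn.PpinGraph(df, {g: f"P_{g}" for g in genes})


class TestBuildLevel0:
    def test_only_query_snp_targets_enter(self):
        grn = grn_from_pairs([("s1", "gA"), ("s2", "gB")])
        genes, hits = pn.build_level0({"s1"}, grn)
        assert genes == {"gA"} and list(hits["snp"]) == ["s1"]

    def test_disjoint_query_warns_and_is_empty(self):
        grn = grn_from_pairs([("s1", "gA")])
        with pytest.warns(UserWarning):
            genes, hits = pn.build_level0({"zz"}, grn)
        assert genes == set() and hits.empty

    def test_planted_world_level0_recovers_target_genes(self, world, built_grn):
        truth = world.truth.true_spatial_eqtls
        query = {s for s, _ in truth}
        genes, _ = pn.build_level0(query, built_grn)
        assert {g for _, g in truth} <= genes


class TestExpandPpin:
    def test_path_levels(self):
        ppin = ppin_from_edges(
            [("P_A", "P_B", 0.8), ("P_B", "P_C", 0.8)], ["A", "B", "C"]
        )
        lv = pn.expand_ppin({"A"}, ppin)
        assert lv.levels[0] == {"P_A"}
        assert lv.levels[1] == {"P_B"}
        assert lv.levels[2] == {"P_C"}

    def test_low_score_edge_not_traversed(self):
        ppin = ppin_from_edges([("P_A", "P_B", 0.69)], ["A", "B"])
        lv = pn.expand_ppin({"A"}, ppin, min_score=0.7)
        assert lv.levels[1] == set()

    def test_score_exactly_at_threshold_traversed(self):
        ppin = ppin_from_edges([("P_A", "P_B", 0.7)], ["A", "B"])
        lv = pn.expand_ppin({"A"}, ppin, min_score=0.7)
        assert lv.levels[1] == {"P_B"}

    def test_levels_disjoint_and_minimum_depth(self):
        # diamond: A-B, A-C, B-D, C-D; D reachable at depth 2 two ways
        ppin = ppin_from_edges(
            [("P_A", "P_B", 0.9), ("P_A", "P_C", 0.9),
             ("P_B", "P_D", 0.9), ("P_C", "P_D", 0.9)],
            ["A", "B", "C", "D"],
        )
        lv = pn.expand_ppin({"A"}, ppin)
        assert lv.levels[1] == {"P_B", "P_C"} and lv.levels[2] == {"P_D"}
        for i in range(lv.n_levels):
            for j in range(i + 1, lv.n_levels):
                assert not (lv.levels[i] & lv.levels[j])

    def test_random_graphs_match_bfs_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(30):
            n = int(rng.integers(3, 13))
            genes = [f"g{i}" for i in range(n)]
            prots = [f"P_g{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.uniform() < 0.3:
                        edges.append((prots[i], prots[j], 0.9))
            seeds = set(rng.choice(genes, size=max(1, n // 4), replace=False))
            ppin = ppin_from_edges(edges, genes) if edges else pn.PpinGraph(
                pd.DataFrame(columns=["protein_a", "protein_b", "score"]),
                {g: f"P_{g}" for g in genes},
            )
            lv = pn.expand_ppin(seeds, ppin, max_level=4)
            want = bfs_levels_matrix(
                prots, [(a, b) for a, b, _ in edges],
                {f"P_{g}" for g in seeds}, 4,
            )
            got = {p: d for d, level in enumerate(lv.levels) for p in level}
            assert got == want

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            pn.PpinGraph(
                pd.DataFrame([{"protein_a": "P1", "protein_b": "P1", "score": 0.9}]),
                {},
            )


class TestRequery:
    def test_level_gene_collects_its_snps(self):
        grn = grn_from_pairs([("s1", "gA"), ("s2", "gA"), ("s3", "gA"), ("s4", "gB")])
        lv = pn.PpinLevels(levels=[{"P_gA"}], level_genes=[{"gA"}])
        lv = pn.requery_eqtls(lv, grn)
        assert lv.level_eqtls[0] == {"s1", "s2", "s3"}

    def test_gene_absent_from_grn_contributes_nothing(self):
        grn = grn_from_pairs([("s1", "gA")])
        lv = pn.PpinLevels(levels=[{"P_gZ"}], level_genes=[{"gZ"}])
        lv = pn.requery_eqtls(lv, grn)
        assert lv.level_eqtls[0] == set()


class TestEnrichment:
    def test_worked_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        assert pn.hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        assert pn.hypergeom_upper_tail(0, 5, 4, 10) == pytest.approx(1.0)

    def test_exhaustive_enumeration_oracle(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(K, n) + 1):
                        got = pn.hypergeom_upper_tail(k, K, n, N)
                        want = hypergeom_tail(k, K, n, N)
                        assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_enrich_traits_counts_and_retention(self):
        catalog = pd.DataFrame(
            [{"trait": "T1", "snp": s} for s in ["s1", "s2", "s3", "s4", "s5"]]
            + [{"trait": "T2", "snp": s} for s in ["s6", "s7", "s8", "s9", "s10"]]
        )
        level_eqtls = [{"s1", "s2", "s3", "s4"}]
        out = pn.enrich_traits(level_eqtls, catalog, alpha=0.05)
        assert len(out) == 1
        e = out[0]
        assert (e.trait_name, e.k, e.K, e.n, e.N) == ("T1", 4, 5, 4, 10)
        assert e.p_hyper == pytest.approx(5 / 210)

    def test_empty_level_skipped_with_warning(self):
        catalog = pd.DataFrame([{"trait": "T1", "snp": "s1"}])
        with pytest.warns(UserWarning):
            out = pn.enrich_traits([set()], catalog)
        assert out == []


class TestBootstrap:
    def _setup(self, world, built_grn, catalog, ppin_graph):
        query = {s for s, _ in world.truth.true_spatial_eqtls}
        genes, _ = pn.build_level0(query, built_grn)
        lv = pn.requery_eqtls(pn.expand_ppin(genes, ppin_graph), built_grn)
        enr = pn.enrich_traits(lv.level_eqtls, catalog, keep_all=True)
        return query, lv, enr

    def test_p_values_multiples_of_inverse_n_iter(self, world, built_grn, catalog, ppin_graph):
        query, lv, enr = self._setup(world, built_grn, catalog, ppin_graph)
        cfg = pn.BootstrapConfig(n_iter=50, resample_size=len(query), seed=5)
        boot = pn.bootstrap_null(enr, catalog, built_grn, ppin_graph, cfg)
        for p in boot.values():
            assert 0.0 <= p <= 1.0
            assert (p * 50) == pytest.approx(round(p * 50))

    def test_observed_zero_overlap_gives_p_one(self, world, built_grn, catalog, ppin_graph):
        query, lv, enr = self._setup(world, built_grn, catalog, ppin_graph)
        zeros = [e for e in enr if e.k == 0]
        assert zeros, "expect some traits with zero overlap"
        cfg = pn.BootstrapConfig(n_iter=20, resample_size=len(query), seed=6)
        boot = pn.bootstrap_null(zeros, catalog, built_grn, ppin_graph, cfg)
        for e in zeros:
            assert boot[(e.trait_name, e.level)] == 1.0

    def test_planted_trait_never_matched_gives_p_zero(self, world, built_grn, catalog, ppin_graph):
        query, lv, enr = self._setup(world, built_grn, catalog, ppin_graph)
        planted = [e for e in enr if e.trait_name in world.truth.pleiotropic_loci
                   and e.level == 0]
        assert planted and planted[0].k >= 10
        cfg = pn.BootstrapConfig(n_iter=100, resample_size=len(query), seed=7)
        boot = pn.bootstrap_null(planted, catalog, built_grn, ppin_graph, cfg)
        assert boot[(planted[0].trait_name, 0)] == 0.0

    def test_conservative_variant(self, world, built_grn, catalog, ppin_graph):
        query, lv, enr = self._setup(world, built_grn, catalog, ppin_graph)
        planted = [e for e in enr if e.k >= 10][:1]
        cfg = pn.BootstrapConfig(n_iter=20, resample_size=len(query), seed=8,
                                 conservative=True)
        boot = pn.bootstrap_null(planted, catalog, built_grn, ppin_graph, cfg)
        key = (planted[0].trait_name, planted[0].level)
        assert boot[key] == pytest.approx(1 / 21)

    def test_seeded_bootstrap_reproducible(self, world, built_grn, catalog, ppin_graph):
        query, lv, enr = self._setup(world, built_grn, catalog, ppin_graph)
        cfg = pn.BootstrapConfig(n_iter=30, resample_size=len(query), seed=9)
        a = pn.bootstrap_null(enr, catalog, built_grn, ppin_graph, cfg)
        b = pn.bootstrap_null(enr, catalog, built_grn, ppin_graph, cfg)
        assert a == b

    def test_monotone_in_observed_overlap(self, world, built_grn, catalog, ppin_graph):
        query, lv, enr = self._setup(world, built_grn, catalog, ppin_graph)
        e = max(enr, key=lambda x: x.k)
        import copy
        weaker = copy.copy(e)
        weaker.k = max(0, e.k - 3)
        # identical seed => identical bootstrap draws for the two runs
        cfg = pn.BootstrapConfig(n_iter=40, resample_size=len(query), seed=10)
        cfg2 = pn.BootstrapConfig(n_iter=40, resample_size=len(query), seed=10)
        b_strong = pn.bootstrap_null([e], catalog, built_grn, ppin_graph, cfg)[
            (e.trait_name, e.level)
        ]
        b_weak = pn.bootstrap_null([weaker], catalog, built_grn, ppin_graph, cfg2)[
            (weaker.trait_name, weaker.level)
        ]
        assert b_strong <= b_weak

    def test_oversized_resample_rejected(self, built_grn, catalog, ppin_graph):
        cfg = pn.BootstrapConfig(n_iter=5, resample_size=10_000, seed=1)
        with pytest.raises(ValueError):
            pn.bootstrap_null([], catalog, built_grn, ppin_graph, cfg)


class TestSummary:
    def test_empty_enrichment_empty_table(self):
        lv = pn.PpinLevels(levels=[set()], level_genes=[set()])
        df = pn.summarize_discovery(lv, [], {})
        assert df.empty and "p_hyper" in df.columns

    def test_sorted_by_level_then_p(self, world, built_grn, catalog, ppin_graph):
        query = {s for s, _ in world.truth.true_spatial_eqtls}
        genes, _ = pn.build_level0(query, built_grn)
        lv = pn.requery_eqtls(pn.expand_ppin(genes, ppin_graph), built_grn)
        enr = pn.enrich_traits(lv.level_eqtls, catalog, keep_all=True)
        df = pn.summarize_discovery(lv, enr, None)
        assert list(df["level"]) == sorted(df["level"])
        for _, grp in df.groupby("level"):
            assert list(grp["p_hyper"]) == sorted(grp["p_hyper"])
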