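"""Spatial pairing, BH calling, and interaction classification."""

import numpy as np
import pandas as pd
import pytest

from pleiopipe import grn as g
from pleiopipe import synthetic as syn
import pleiopipe as pp

from oracles import bh_stepup


def _frags(*triples):
    rows = [{"chrom": c, "start": s, "end": e, "fragment_id": f"F{i}"}
            for i, (c, s, e) in enumerate(triples)]
    return pd.DataFrame(rows)


def _snps(*triples):
    rows = [{"snp_id": f"s{i}", "chrom": c, "pos": p, "ref": "A", "alt": "G", "maf": m}
            for i, (c, p, m) in enumerate(triples)]
    return pd.DataFrame(rows)


class TestAssignFragments:
    def test_halfopen_boundary_goes_to_next_fragment(self):
        frags = _frags(("chr1", 0, 4000), ("chr1", 4000, 8000))
        snps = _snps(("chr1", 4000, 0.3))
        assert g.assign_fragments(snps, frags) == {"s0": "F1"}

    def test_position_zero_first_fragment(self):
        frags = _frags(("chr1", 0, 4000), ("chr1", 4000, 8000))
        snps = _snps(("chr1", 0, 0.3))
        assert g.assign_fragments(snps, frags) == {"s0": "F0"}

    def test_unknown_chromosome_raises(self):
        frags = _frags(("chr1", 0, 4000))
        snps = _snps(("chr2", 100, 0.3))
        with pytest.raises(g.InputConsistencyError):
            g.assign_fragments(snps, frags)

    def test_position_beyond_fragments_raises(self):
        frags = _frags(("chr1", 0, 4000))
        snps = _snps(("chr1", 5000, 0.3))
        with pytest.raises(g.InputConsistencyError):
            g.assign_fragments(snps, frags)


class TestSpatialPairs:
    frags = _frags(("chr1", 0, 1000), ("chr1", 1000, 2000), ("chr1", 2000, 3000))
    genes = pd.DataFrame(
        [{"gene_id": "gA", "chrom": "chr1", "start": 2100, "end": 2500,
          "strand": "+", "tpm": 1.0}]
    )

    def test_contact_emits_pair(self):
        contacts = pd.DataFrame([{"fragment_a": "F0", "fragment_b": "F2"}])
        pairs = g.find_spatial_pairs({"s0": "F0"}, self.genes, self.frags, contacts)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert (row["snp_id"], row["gene_id"], row["same_fragment"]) == ("s0", "gA", False)

    def test_no_contact_no_pair(self):
        contacts = pd.DataFrame([{"fragment_a": "F0", "fragment_b": "F1"}])
        pairs = g.find_spatial_pairs({"s0": "F0"}, self.genes, self.frags, contacts)
        assert pairs.empty

    def test_same_fragment_flag(self):
        contacts = pd.DataFrame(columns=["fragment_a", "fragment_b"])
        pairs = g.find_spatial_pairs({"s0": "F2"}, self.genes, self.frags, contacts,
                                     include_same_fragment=True)
        assert len(pairs) == 1 and bool(pairs.iloc[0]["same_fragment"])
        none = g.find_spatial_pairs({"s0": "F2"}, self.genes, self.frags, contacts,
                                    include_same_fragment=False)
        assert none.empty

    def test_multi_fragment_gene_deduplicated(self):
        genes = pd.DataFrame(
            [{"gene_id": "gB", "chrom": "chr1", "start": 500, "end": 2500,
              "strand": "+", "tpm": 1.0}]
        )  # overlaps F0, F1, F2
        contacts = pd.DataFrame(
            [{"fragment_a": "F0", "fragment_b": "F1"},
             {"fragment_a": "F0", "fragment_b": "F2"}]
        )
        pairs = g.find_spatial_pairs({"s0": "F0"}, genes, self.frags, contacts,
                                     include_same_fragment=True)
        assert len(pairs) == 1


def _mini_world(pvals, mafs=None):
    """One chromosome, n SNPs each contacting one gene; association ps given."""
    n = len(pvals)
    mafs = mafs or [0.3] * n
    frags = _frags(*[("chr1", i * 1000, (i + 1) * 1000) for i in range(n + 1)])
    snps = _snps(*[("chr1", i * 1000 + 10, mafs[i]) for i in range(n)])
    genes = pd.DataFrame(
        [{"gene_id": "gA", "chrom": "chr1", "start": n * 1000 + 10,
          "end": n * 1000 + 900, "strand": "+", "tpm": 5.0}]
    )
    contacts = pd.DataFrame(
        [{"fragment_a": f"F{i}", "fragment_b": f"F{n}"} for i in range(n)]
    )
    snp_frag = g.assign_fragments(snps, frags)
    pairs = g.find_spatial_pairs(snp_frag, genes, frags, contacts)
    assoc = pd.DataFrame(
        [{"snp": f"s{i}", "gene": "gA", "beta": 0.1, "se": 0.05, "p": pvals[i]}
         for i in range(n)]
    )
    return pairs, assoc, snps, genes


class TestCallEqtls:
    def test_bh_example_two_retained(self):
        pairs, assoc, snps, genes = _mini_world([0.01, 0.02, 0.04, 0.5])
        grn = g.call_eqtls(pairs, assoc, snps, genes, alpha=0.05)
        assert len(grn) == 2
        assert set(grn.records["snp"]) == {"s0", "s1"}

    def test_all_p_one_empty_grn(self):
        pairs, assoc, snps, genes = _mini_world([1.0, 1.0, 1.0])
        assert len(g.call_eqtls(pairs, assoc, snps, genes)) == 0

    def test_maf_filter_removes_rare_snps_before_testing(self):
        pairs, assoc, snps, genes = _mini_world([1e-9, 1e-9], mafs=[0.3, 0.01])
        grn = g.call_eqtls(pairs, assoc, snps, genes, maf_min=0.05)
        assert set(grn.records["snp"]) == {"s0"}

    def test_missing_association_raises(self):
        pairs, assoc, snps, genes = _mini_world([0.01, 0.02])
        with pytest.raises(g.InputConsistencyError):
            g.call_eqtls(pairs, assoc.iloc[:1], snps, genes)

    def test_adjusted_p_matches_stepup_oracle(self):
        rng = np.random.default_rng(0)
        for m in range(1, 11):
            for _ in range(20):
                pvals = list(np.round(rng.uniform(size=m), 4))
                pairs, assoc, snps, genes = _mini_world(pvals)
                grn = g.call_eqtls(pairs, assoc, snps, genes, alpha=1.0)
                got = dict(zip(grn.records["snp"], grn.records["p_adjusted"]))
                want = bh_stepup(pvals)
                for i in range(m):
                    assert got[f"s{i}"] == pytest.approx(want[i], rel=1e-12)

    def test_bh_stepup_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=100, derandomize=True, deadline=None)
        @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
        def check(pvals):
            pvals = [round(p, 6) for p in pvals]
            pairs, assoc, snps, genes = _mini_world(pvals)
            grn = g.call_eqtls(pairs, assoc, snps, genes, alpha=1.0)
            got = dict(zip(grn.records["snp"], grn.records["p_adjusted"]))
            want = bh_stepup(pvals)
            for i, p in enumerate(pvals):
                # adjusted p never below nominal, never above 1, matches oracle
                assert got[f"s{i}"] >= p - 1e-12
                assert got[f"s{i}"] <= 1.0 + 1e-12
                assert got[f"s{i}"] == pytest.approx(want[i], rel=1e-9, abs=1e-12)

        check()

    def test_shrinking_alpha_never_adds_records(self):
        pairs, assoc, snps, genes = _mini_world(
            list(np.random.default_rng(1).uniform(size=8))
        )
        prev = None
        for alpha in [0.5, 0.2, 0.05, 0.01]:
            recs = set(map(tuple, g.call_eqtls(pairs, assoc, snps, genes,
                                               alpha=alpha).records[["snp", "gene"]].values))
            if prev is not None:
                assert recs <= prev
            prev = recs

    def test_planted_fixture_recovery_and_spatial_gate(self, big_world):
        table = pp.gen_eqtl_table(big_world, seed=21)
        snp_frag = g.assign_fragments(big_world.snps, big_world.fragments)
        pairs = g.find_spatial_pairs(snp_frag, big_world.genes,
                                     big_world.fragments, big_world.contacts)
        assert len(pairs) > 1500  # planted pairs are a needle in ~2k candidates
        grn = g.call_eqtls(pairs, table, big_world.snps, big_world.genes)
        truth = set(big_world.truth.true_spatial_eqtls)
        found = set(zip(grn.records["snp"], grn.records["gene"]))
        assert truth <= found  # sensitivity 1 (planted p << alpha/m)
        # every retained record has spatial support by construction
        candidate_keys = set(zip(pairs["snp_id"], pairs["gene_id"]))
        assert found <= candidate_keys

    def test_duplicate_records_rejected(self):
        df = pd.DataFrame(
            [{"snp": "s0", "gene": "gA", "beta": 0.1, "se": 0.05, "p": 0.01,
              "p_adjusted": 0.02, "interaction_class": "cis", "gene_tpm": 1.0}] * 2
        )
        with pytest.raises(g.InputConsistencyError):
            g.Grn(df)


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "snp_pos, gene_start, gene_end, expected",
        [
            (0, 500_000, 510_000, g.CIS),                    # 500 kb away
            (0, 2_000_000, 2_010_000, g.TRANS_INTRA),        # 2 Mb away
            (0, 999_999, 1_009_999, g.CIS),                  # just inside 1 Mb
            (0, 1_000_000, 1_010_000, g.TRANS_INTRA),        # exactly 1 Mb -> trans
            (505_000, 500_000, 510_000, g.CIS),              # inside gene: distance 0
        ],
    )
    def test_same_chromosome_distance_rule(self, snp_pos, gene_start, gene_end, expected):
        assert g.classify_interaction("chr1", snp_pos, "chr1", gene_start, gene_end) == expected

    def test_different_chromosomes(self):
        assert g.classify_interaction("chr1", 0, "chr2", 0, 1000) == g.TRANS_INTER

    def test_distance_uses_nearest_boundary(self):
        # SNP downstream of the gene: nearest boundary is end-1
        assert g.classify_interaction("chr1", 1_500_000, "chr1", 0, 600_000) == g.CIS
        assert g.classify_interaction("chr1", 1_700_000, "chr1", 0, 600_000) == g.TRANS_INTRA
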