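"""Spatially constrained gene regulatory network construction.

A regulatory pair is *spatial* when the restriction fragment carrying the
SNP forms a chromatin contact with a fragment overlapping the candidate
target gene (or is that fragment itself, when same-fragment pairs are
enabled).  Candidate pairs are then tested against an eQTL association
table: common SNPs (MAF >= ``maf_min``) are kept, Benjamini-Hochberg
correction is applied jointly over all candidate pairs, and pairs with
adjusted p <= ``alpha`` form the tissue GRN.

Interaction classes follow the standard distance rule: a pair on the same
chromosome closer than 1 Mb is *cis*, at 1 Mb or beyond it is
*trans_intrachromosomal*, and pairs spanning chromosomes are
*trans_interchromosomal*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

CIS_TRANS_BOUNDARY_BP = 1_000_000

CIS = "cis"
TRANS_INTRA = "trans_intrachromosomal"
TRANS_INTER = "trans_interchromosomal"


class InputConsistencyError(ValueError):
    """Raised when cross-referenced tables disagree (missing SNPs, pairs...)."""


@dataclass
class Grn:
    """A tissue gene regulatory network: significant spatial eQTL records.

    ``records`` has one row per retained (snp, gene) pair with columns
    ``snp, gene, beta, se, p, p_adjusted, interaction_class, gene_tpm``.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records.duplicated(["snp", "gene"]).any():
            raise InputConsistencyError("duplicate (snp, gene) records in GRN")

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"])

    @property
    def snps(self) -> set[str]:
        return set(self.records["snp"])

    def __len__(self) -> int:
        return len(self.records)


def assign_fragments(snps: pd.DataFrame, fragments: pd.DataFrame) -> dict[str, str]:
    """Map each SNP to the unique half-open fragment interval containing it.

    Parameters
    ----------
    snps : DataFrame with columns ``snp_id, chrom, pos``.
    fragments : DataFrame with columns ``chrom, start, end, fragment_id``;
        fragments must tile each chromosome (disjoint, sorted coverage).

    Returns
    -------
    dict mapping ``snp_id`` to ``fragment_id`` with start <= pos < end.
    """
    out: dict[str, str] = {}
    by_chrom = {c: g.sort_values("start") for c, g in fragments.groupby("chrom")}
    for chrom, snp_group in snps.groupby("chrom"):
        if chrom not in by_chrom:
            raise InputConsistencyError(f"SNPs on chromosome {chrom!r} but no fragments there")
        frags = by_chrom[chrom]
        starts = frags["start"].to_numpy()
        ends = frags["end"].to_numpy()
        ids = frags["fragment_id"].to_numpy()
        pos = snp_group["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        bad = (idx < 0) | (pos >= ends[np.clip(idx, 0, len(ends) - 1)])
        if bad.any():
            culprit = snp_group["snp_id"].to_numpy()[bad][0]
            raise InputConsistencyError(f"SNP {culprit} falls outside every fragment")
        out.update(zip(snp_group["snp_id"], ids[idx]))
    return out


def gene_fragments(genes: pd.DataFrame, fragments: pd.DataFrame) -> dict[str, list[str]]:
    """Fragments overlapping each gene interval (half-open overlap)."""
    out: dict[str, list[str]] = {}
    by_chrom = {c: g.sort_values("start") for c, g in fragments.groupby("chrom")}
    for _, gene in genes.iterrows():
        frags = by_chrom.get(gene["chrom"])
        if frags is None:
            out[gene["gene_id"]] = []
            continue
        hit = frags[(frags["start"] < gene["end"]) & (frags["end"] > gene["start"])]
        out[gene["gene_id"]] = list(hit["fragment_id"])
    return out


def find_spatial_pairs(
    snp_frags: dict[str, str],
    genes: pd.DataFrame,
    fragments: pd.DataFrame,
    contacts: pd.DataFrame,
    include_same_fragment: bool = True,
) -> pd.DataFrame:
    """Enumerate SNP-gene pairs supported by a fragment-fragment contact.

    A pair (s, g) is emitted iff some fragment overlapping g contacts s's
    fragment, or equals it when ``include_same_fragment`` is set.  Contacts
    are unordered; duplicates collapse.  Output columns:
    ``snp_id, gene_id, snp_fragment, gene_fragment, same_fragment``.
    """
    contact_sets: dict[str, set[str]] = {}
    for a, b in zip(contacts["fragment_a"], contacts["fragment_b"]):
        contact_sets.setdefault(a, set()).add(b)
        contact_sets.setdefault(b, set()).add(a)

    gfrags = gene_fragments(genes, fragments)
    # invert: fragment -> genes overlapping it
    frag_genes: dict[str, set[str]] = {}
    for g, fl in gfrags.items():
        for f in fl:
            frag_genes.setdefault(f, set()).add(g)

    rows = []
    seen: set[tuple[str, str]] = set()
    for snp, sfrag in snp_frags.items():
        partners = set(contact_sets.get(sfrag, ()))
        if include_same_fragment:
            partners.add(sfrag)
        for pfrag in partners:
            for gene in frag_genes.get(pfrag, ()):
                key = (snp, gene)
                if key in seen:
                    continue
                seen.add(key)
                rows.append(
                    {
                        "snp_id": snp,
                        "gene_id": gene,
                        "snp_fragment": sfrag,
                        "gene_fragment": pfrag,
                        "same_fragment": pfrag == sfrag,
                    }
                )
    cols = ["snp_id", "gene_id", "snp_fragment", "gene_fragment", "same_fragment"]
    return pd.DataFrame(rows, columns=cols).sort_values(["snp_id", "gene_id"]).reset_index(drop=True)


def classify_interaction(
    snp_chrom: str,
    snp_pos: int,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    boundary_bp: int = CIS_TRANS_BOUNDARY_BP,
) -> str:
    """Classify a regulatory pair as cis / trans-intra / trans-inter.

    Distance is measured from the SNP to the nearest gene boundary and is 0
    when the SNP lies inside the gene.  Exactly ``boundary_bp`` maps to
    trans (the cis window is strictly "within" 1 Mb).
    """
    if snp_chrom != gene_chrom:
        return TRANS_INTER
    if gene_start <= snp_pos < gene_end:
        dist = 0
    else:
        dist = min(abs(snp_pos - gene_start), abs(snp_pos - (gene_end - 1)))
    return CIS if dist < boundary_bp else TRANS_INTRA


def call_eqtls(
    pairs: pd.DataFrame,
    assoc_table: pd.DataFrame,
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    maf_min: float = 0.05,
    alpha: float = 0.05,
    provenance: dict | None = None,
) -> Grn:
    """Call significant spatial eQTLs from candidate pairs.

    SNPs with MAF < ``maf_min`` are removed before testing; BH correction is
    applied jointly over all remaining candidate pairs; records with adjusted
    p <= ``alpha`` are retained, annotated with interaction class and gene TPM.

    ``assoc_table`` needs columns ``snp, gene, beta, se, p`` (optionally
    ``gene_tpm``); ``snps`` needs ``snp_id, chrom, pos, maf``; ``genes``
    needs ``gene_id, chrom, start, end`` (optionally ``tpm``).
    """
    maf = dict(zip(snps["snp_id"], snps["maf"]))
    common = pairs[pairs["snp_id"].map(maf).ge(maf_min)]
    if common.empty:
        empty = pd.DataFrame(
            columns=["snp", "gene", "beta", "se", "p", "p_adjusted", "interaction_class", "gene_tpm"]
        )
        return Grn(empty, provenance or {})

    merged = common.merge(
        assoc_table,
        left_on=["snp_id", "gene_id"],
        right_on=["snp", "gene"],
        how="left",
        validate="one_to_one",
    )
    if merged["p"].isna().any():
        missing = merged.loc[merged["p"].isna(), ["snp_id", "gene_id"]].iloc[0]
        raise InputConsistencyError(
            f"candidate pair ({missing['snp_id']}, {missing['gene_id']}) missing from association table"
        )

    _, p_adj, _, _ = multipletests(merged["p"].to_numpy(), method="fdr_bh")
    merged = merged.assign(p_adjusted=p_adj)
    kept = merged[merged["p_adjusted"] <= alpha].copy()

    snp_info = snps.set_index("snp_id")
    gene_info = genes.set_index("gene_id")
    classes = [
        classify_interaction(
            snp_info.at[r.snp_id, "chrom"],
            int(snp_info.at[r.snp_id, "pos"]),
            gene_info.at[r.gene_id, "chrom"],
            int(gene_info.at[r.gene_id, "start"]),
            int(gene_info.at[r.gene_id, "end"]),
        )
        for r in kept.itertuples()
    ]
    kept["interaction_class"] = classes
    if "gene_tpm" not in kept.columns or kept["gene_tpm"].isna().all():
        if "tpm" in gene_info.columns:
            kept["gene_tpm"] = kept["gene_id"].map(gene_info["tpm"]).to_numpy()
        else:
            kept["gene_tpm"] = np.nan

    records = (
        kept[["snp_id", "gene_id", "beta", "se", "p", "p_adjusted", "interaction_class", "gene_tpm"]]
        .rename(columns={"snp_id": "snp", "gene_id": "gene"})
        .sort_values(["p_adjusted", "snp", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )
    prov = dict(provenance or {})
    prov.update({"alpha": alpha, "maf_min": maf_min, "n_candidates": int(len(merged))})
    return Grn(records, prov)
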