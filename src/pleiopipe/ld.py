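"""Linkage-disequilibrium utilities: query expansion, clumping, locus grouping.

All operations consume a precomputed pairwise r-squared resource plus SNP
positions; nothing here estimates LD from genotypes.  A missing pair is
treated as r-squared 0 (unlinked), which makes sparse LD tables safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .grn import InputConsistencyError


@dataclass
class LdResource:
    """Symmetric pairwise r-squared lookup with SNP positions.

    ``pairs``: DataFrame with columns ``snp_a, snp_b, r2``;
    ``positions``: DataFrame with columns ``snp_id, chrom, pos``.
    """

    pairs: pd.DataFrame
    positions: pd.DataFrame
    _r2: dict[tuple[str, str], float] = field(init=False, repr=False)
    _pos: dict[str, tuple[str, int]] = field(init=False, repr=False)
    _partners: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._r2 = {}
        self._partners = {}
        for a, b, r2 in zip(self.pairs["snp_a"], self.pairs["snp_b"], self.pairs["r2"]):
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r2 out of [0,1] for pair ({a}, {b}): {r2}")
            key = (a, b) if a <= b else (b, a)
            self._r2[key] = float(r2)
            self._partners.setdefault(a, set()).add(b)
            self._partners.setdefault(b, set()).add(a)
        self._pos = {
            s: (c, int(p))
            for s, c, p in zip(
                self.positions["snp_id"], self.positions["chrom"], self.positions["pos"]
            )
        }

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._r2.get(key, 0.0)

    def partners(self, snp: str) -> set[str]:
        return self._partners.get(snp, set())

    def position(self, snp: str) -> tuple[str, int]:
        try:
            return self._pos[snp]
        except KeyError:
            raise InputConsistencyError(f"SNP {snp} has no position in the LD resource") from None


@dataclass
class Locus:
    index_snp: str
    member_snps: set[str]
    span: tuple[str, int, int]  # chrom, min pos, max pos


def _within_window(ld: LdResource, a: str, b: str, width_bp: int) -> bool:
    ca, pa = ld.position(a)
    cb, pb = ld.position(b)
    return ca == cb and abs(pa - pb) <= width_bp


def expand_ld(
    query_snps: list[str],
    ld: LdResource,
    r2_min: float = 0.8,
    width_bp: int = 5_000,
) -> tuple[set[str], dict[str, str]]:
    """Add LD partners of the query SNPs.

    A partner enters the expanded set when its r-squared with some query SNP
    is >= ``r2_min`` and it lies within ``width_bp`` of that SNP (window
    interpreted as +/- width around the index).  Each added SNP is tagged
    with its best index SNP: highest r2, ties broken by distance then id.

    Returns (expanded SNP set, map snp -> index snp); query SNPs map to
    themselves.
    """
    index_of: dict[str, str] = {}
    for q in sorted(set(query_snps)):
        ld.position(q)  # raises if unknown
        index_of[q] = q
    best: dict[str, tuple[float, int, str]] = {}
    for q in sorted(set(query_snps)):
        _, qpos = ld.position(q)
        for partner in sorted(ld.partners(q)):
            if partner in index_of or partner not in ld._pos:
                continue
            r2 = ld.r2(q, partner)
            if r2 < r2_min or not _within_window(ld, q, partner, width_bp):
                continue
            _, ppos = ld.position(partner)
            cand = (-r2, abs(ppos - qpos), q)
            if partner not in best or cand < best[partner]:
                best[partner] = cand
    for partner, (_, _, q) in best.items():
        index_of[partner] = q
    return set(index_of), index_of


def clump(
    snps: list[str],
    pvalues: dict[str, float],
    ld: LdResource,
    r2_max: float = 0.001,
    window_bp: int = 10_000_000,
) -> list[str]:
    """Greedy p-value clumping to an independent index-SNP set.

    SNPs are visited in ascending p (ties by id); a SNP is accepted iff its
    r-squared with every previously accepted SNP within ``window_bp`` is
    strictly below ``r2_max``.  Returns accepted SNPs in acceptance order.
    """
    order = sorted(set(snps), key=lambda s: (pvalues[s], s))
    accepted: list[str] = []
    for s in order:
        ld.position(s)
        ok = True
        for a in accepted:
            if _within_window(ld, s, a, window_bp) and ld.r2(s, a) >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(s)
    return accepted


def group_loci(
    snps: list[str],
    ld: LdResource,
    r2_min: float = 0.8,
    width_bp: int = 5_000,
    pvalues: dict[str, float] | None = None,
) -> list[Locus]:
    """Single-linkage grouping of SNPs into LD loci.

    Edges connect pairs with r-squared >= ``r2_min`` and distance <=
    ``width_bp``; connected components become loci.  The index SNP is the
    lowest-p member (ties/no p-values: first id).  Loci are returned sorted
    by (chrom, min pos).
    """
    snps = sorted(set(snps))
    g = nx.Graph()
    g.add_nodes_from(snps)
    for i, a in enumerate(snps):
        for b in snps[i + 1 :]:
            if ld.r2(a, b) >= r2_min and _within_window(ld, a, b, width_bp):
                g.add_edge(a, b)
    loci = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if pvalues:
            index = min(members, key=lambda s: (pvalues.get(s, 1.0), s))
        else:
            index = members[0]
        positions = [ld.position(s) for s in members]
        chroms = {c for c, _ in positions}
        chrom = ld.position(index)[0]
        pos_on = [p for c, p in positions if c == chrom] or [ld.position(index)[1]]
        # components can in principle straddle chromosomes only if the edge
        # rule allowed it; the window rule forbids that, so chroms is a singleton
        assert len(chroms) == 1
        loci.append(Locus(index, set(members), (chrom, min(pos_on), max(pos_on))))
    loci.sort(key=lambda lo: (lo.span[0], lo.span[1], lo.index_snp))
    return loci
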