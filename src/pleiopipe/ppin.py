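"""Multi-level protein-interaction expansion and trait pleiotropy discovery.

The discovery procedure starts from the genes whose expression is regulated
by the query SNPs in a tissue GRN ("level 0"), walks outward through a
high-confidence protein-interaction network for up to four interaction
steps (levels 1-4, each protein assigned its shortest-path distance from
the level-0 set), re-queries the GRN with each level's genes to collect
that level's regulatory SNPs, and tests every catalogued trait for
over-representation of its SNPs among the level SNPs with an upper-tail
hypergeometric test.  An empirical null is attached by rerunning the whole
walk on random SNP draws of the same size as the query set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .grn import Grn


@dataclass
class PpinGraph:
    """Undirected scored protein-interaction network plus gene<->protein map.

    ``edges``: DataFrame with columns ``protein_a, protein_b, score``
    (scores in [0, 1], no self-loops).  ``gene_to_protein`` maps gene ids
    onto protein ids; the inverse map is derived.
    """

    edges: pd.DataFrame
    gene_to_protein: dict[str, str]
    protein_to_gene: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        if (self.edges["protein_a"] == self.edges["protein_b"]).any():
            raise ValueError("PPIN contains self-loops")
        scores = self.edges["score"]
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError("PPIN scores must lie in [0, 1]")
        self.protein_to_gene = {p: g for g, p in self.gene_to_protein.items()}

    def thresholded(self, min_score: float) -> nx.Graph:
        kept = self.edges[self.edges["score"] >= min_score]
        g = nx.Graph()
        g.add_edges_from(zip(kept["protein_a"], kept["protein_b"]))
        return g


@dataclass
class PpinLevels:
    """Leveled neighbourhood: disjoint protein sets at shortest-path depth 0..max."""

    levels: list[set[str]]                       # proteins per level
    level_genes: list[set[str]]                  # genes encoding them
    level_eqtls: list[set[str]] = field(default_factory=list)
    level_pairs: list[pd.DataFrame] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class TraitEnrichment:
    trait_name: str
    level: int
    overlap_snps: set[str]
    k: int
    K: int
    n: int
    N: int
    p_hyper: float
    p_bootstrap: float | None = None


@dataclass
class BootstrapConfig:
    n_iter: int = 1000
    resample_size: int | None = None   # defaults to the expanded query size
    seed: int = 0
    threshold: float = 0.01
    conservative: bool = False         # (b+1)/(n+1) variant

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.resample_size is not None and self.resample_size < 1:
            raise ValueError("resample_size must be >= 1")


def build_level0(query_snps: set[str], grn: Grn) -> tuple[set[str], pd.DataFrame]:
    """Query-specific GRN: records whose SNP is in the (LD-expanded) query set.

    Returns (level-0 gene set, the matching eQTL-gene records).  An empty
    intersection yields an empty level 0 with a warning, not an error.
    """
    hits = grn.records[grn.records["snp"].isin(query_snps)]
    genes = set(hits["gene"])
    if not genes:
        warnings.warn("query SNPs share no records with the GRN; level 0 is empty", stacklevel=2)
    return genes, hits.reset_index(drop=True)


def expand_ppin(
    level0_genes: set[str],
    ppin: PpinGraph,
    max_level: int = 4,
    min_score: float = 0.7,
) -> PpinLevels:
    """Breadth-first level assignment from the level-0 protein set.

    Edges scoring below ``min_score`` are discarded; every reachable protein
    is assigned its minimum graph distance from the level-0 seeds, capped at
    ``max_level``.  Genes without a protein mapping are skipped.
    """
    seeds = sorted(
        ppin.gene_to_protein[g] for g in level0_genes if g in ppin.gene_to_protein
    )
    graph = ppin.thresholded(min_score)
    levels: list[set[str]] = [set(seeds)]
    if seeds:
        present = [s for s in seeds if s in graph]
        dist = nx.multi_source_dijkstra_path_length(graph, present, cutoff=max_level, weight=None) if present else {}
        for depth in range(1, max_level + 1):
            levels.append({p for p, d in dist.items() if d == depth})
    else:
        levels.extend(set() for _ in range(max_level))
    level_genes = [
        {ppin.protein_to_gene.get(p, p) for p in level} for level in levels
    ]
    return PpinLevels(levels=levels, level_genes=level_genes)


def requery_eqtls(levels: PpinLevels, grn: Grn) -> PpinLevels:
    """Attach each level's significant regulatory SNPs from the GRN."""
    levels.level_eqtls = []
    levels.level_pairs = []
    for genes in levels.level_genes:
        hits = grn.records[grn.records["gene"].isin(genes)]
        levels.level_eqtls.append(set(hits["snp"]))
        levels.level_pairs.append(hits.reset_index(drop=True))
    return levels


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_traits(
    level_eqtls: list[set[str]],
    catalog: pd.DataFrame,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> list[TraitEnrichment]:
    """Hypergeometric trait over-representation per PPIN level.

    The universe N is the set of distinct SNPs in the catalog; for each
    (trait, level): K = trait SNPs, n = level SNPs restricted to the
    universe, k = their overlap, p = upper-tail hypergeometric including the
    observed count.  Traits with p < ``alpha`` are returned (all tested
    records when ``keep_all``).
    """
    universe = set(catalog["snp"])
    N = len(universe)
    trait_snps = {t: set(g["snp"]) for t, g in catalog.groupby("trait")}
    out: list[TraitEnrichment] = []
    for level, eqtls in enumerate(level_eqtls):
        n_set = eqtls & universe
        n = len(n_set)
        if n == 0:
            warnings.warn(f"level {level}: no eQTLs in the catalog universe; skipped", stacklevel=2)
            continue
        for trait in sorted(trait_snps):
            K_set = trait_snps[trait]
            overlap = K_set & n_set
            k = len(overlap)
            p = hypergeom_upper_tail(k, len(K_set), n, N)
            rec = TraitEnrichment(trait, level, overlap, k, len(K_set), n, N, p)
            if keep_all or p < alpha:
                out.append(rec)
    return out


class _FastDiscovery:
    """Precomputed lookups so the bootstrap can rerun the walk cheaply."""

    def __init__(self, grn: Grn, ppin: PpinGraph, catalog: pd.DataFrame,
                 max_level: int = 4, min_score: float = 0.7):
        self.snp_to_genes: dict[str, set[str]] = {}
        self.gene_to_snps: dict[str, set[str]] = {}
        for snp, gene in zip(grn.records["snp"], grn.records["gene"]):
            self.snp_to_genes.setdefault(snp, set()).add(gene)
            self.gene_to_snps.setdefault(gene, set()).add(snp)
        self.ppin = ppin
        self.graph = ppin.thresholded(min_score)
        self.max_level = max_level
        self.universe = sorted(set(catalog["snp"]))
        self.trait_snps = {t: set(g["snp"]) for t, g in catalog.groupby("trait")}

    def level_eqtls(self, query_snps: set[str]) -> list[set[str]]:
        level0_genes: set[str] = set()
        for s in query_snps:
            level0_genes |= self.snp_to_genes.get(s, set())
        seeds = {self.ppin.gene_to_protein[g] for g in level0_genes
                 if g in self.ppin.gene_to_protein}
        levels_genes: list[set[str]] = [level0_genes]
        present = [s for s in seeds if s in self.graph]
        dist = (
            nx.multi_source_dijkstra_path_length(self.graph, present, cutoff=self.max_level, weight=None)
            if present
            else {}
        )
        for depth in range(1, self.max_level + 1):
            prots = {p for p, d in dist.items() if d == depth}
            levels_genes.append({self.ppin.protein_to_gene.get(p, p) for p in prots})
        out = []
        for genes in levels_genes:
            snps: set[str] = set()
            for g in genes:
                snps |= self.gene_to_snps.get(g, set())
            out.append(snps)
        return out

    def overlaps(self, query_snps: set[str]) -> dict[tuple[str, int], int]:
        uni = set(self.universe)
        res: dict[tuple[str, int], int] = {}
        for level, eqtls in enumerate(self.level_eqtls(query_snps)):
            n_set = eqtls & uni
            for trait, K_set in self.trait_snps.items():
                res[(trait, level)] = len(K_set & n_set)
        return res


def bootstrap_null(
    observed: list[TraitEnrichment],
    catalog: pd.DataFrame,
    grn: Grn,
    ppin: PpinGraph,
    cfg: BootstrapConfig,
    max_level: int = 4,
    min_score: float = 0.7,
) -> dict[tuple[str, int], float]:
    """Empirical p-values by rerunning discovery on random SNP draws.

    Each iteration draws ``resample_size`` distinct SNPs uniformly without
    replacement from the catalog universe, reruns level-0 construction,
    protein-network expansion and per-level re-querying, and counts each
    (trait, level) overlap.  p = (#iterations with overlap >= observed) /
    n_iter, or (b+1)/(n_iter+1) under ``cfg.conservative``.
    """
    fast = _FastDiscovery(grn, ppin, catalog, max_level=max_level, min_score=min_score)
    universe = fast.universe
    size = cfg.resample_size if cfg.resample_size is not None else len(universe)
    if size > len(universe):
        raise ValueError(
            f"resample_size {size} exceeds catalog universe size {len(universe)}"
        )
    rng = np.random.default_rng(cfg.seed)
    obs = {(e.trait_name, e.level): e.k for e in observed}
    exceed = {key: 0 for key in obs}
    uni_arr = np.asarray(universe, dtype=object)
    for _ in range(cfg.n_iter):
        draw = set(rng.choice(uni_arr, size=size, replace=False))
        counts = fast.overlaps(draw)
        for key, k_obs in obs.items():
            if counts.get(key, 0) >= k_obs:
                exceed[key] += 1
    if cfg.conservative:
        return {key: (b + 1) / (cfg.n_iter + 1) for key, b in exceed.items()}
    return {key: b / cfg.n_iter for key, b in exceed.items()}


def summarize_discovery(
    levels: PpinLevels,
    enrichments: list[TraitEnrichment],
    bootstrap: dict[tuple[str, int], float] | None = None,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """One row per (trait, level), sorted by level, hypergeometric p, trait."""
    rows = []
    for e in enrichments:
        p_boot = None if bootstrap is None else bootstrap.get((e.trait_name, e.level))
        pairs = ""
        if levels.level_pairs:
            lp = levels.level_pairs[e.level]
            hits = lp[lp["snp"].isin(e.overlap_snps)]
            pairs = ";".join(sorted(f"{s}->{g}" for s, g in zip(hits["snp"], hits["gene"])))
        rows.append(
            {
                "trait": e.trait_name,
                "level": e.level,
                "k": e.k,
                "K": e.K,
                "n": e.n,
                "N": e.N,
                "p_hyper": e.p_hyper,
                "p_bootstrap": np.nan if p_boot is None else p_boot,
                "significant_bootstrap": (p_boot is not None and p_boot < threshold),
                "eqtl_gene_pairs": pairs,
            }
        )
    cols = ["trait", "level", "k", "K", "n", "N", "p_hyper", "p_bootstrap",
            "significant_bootstrap", "eqtl_gene_pairs"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["level", "p_hyper", "trait"], kind="mergesort").reset_index(drop=True)
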