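"""Synthetic genome-scale inputs with planted ground truth.

Every table the pipeline consumes can be generated here at desk scale: a
fragment-partitioned genome with gene annotation; SNPs organised into LD
blocks carrying an explicit pairwise r-squared table; fragment contact
lists; an eQTL association table where planted regulatory pairs receive
concentrated low p-values and everything else is null-uniform; a scored
protein-interaction edge list; a trait-SNP catalog with planted pleiotropic
traits; exposure/outcome GWAS summary statistics with a known causal effect
and optional directional pleiotropy; and person-level coded admission
records with planted co-occurrence odds ratios.

All generators are pure functions of (config, seed): the same arguments
always reproduce the same tables.  Planted identifiers are recorded in
``PlantedTruth`` so downstream recovery can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import grn as grn_mod
from .ld import LdResource
from .ppin import PpinGraph

NUCLEOTIDES = np.array(list("ACGT"))
# non-palindromic allele pairs only, so harmonisation never silently drops rows
ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


class ConfigurationError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Shape of the synthetic world.

    Defaults give a two-chromosome, 1 Mb-per-chromosome genome cut into 4 kb
    restriction fragments, with 60 genes, 400 SNPs in 4-SNP LD blocks and 20
    planted regulatory pairs — small enough for second-scale reruns while
    exercising every rule the pipeline applies at scale.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    fragment_length_bp: int = 4_000
    n_genes: int = 60
    gene_length_bp: int = 10_000
    n_snps: int = 400
    maf_min: float = 0.01
    maf_max: float = 0.5
    ld_block_size: int = 4
    ld_max_gap_bp: int = 1_500
    ld_r2_adjacent: float = 0.9
    n_true_eqtls: int = 20
    n_true_genes: int | None = None   # restrict planted pairs to this many genes
    n_background_contacts: int = 300
    tpm_log_mean: float = 1.0
    tpm_log_sd: float = 1.0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.fragment_length_bp <= 0:
            raise ConfigurationError("fragment_length_bp must be > 0")
        if self.n_genes < 1 or self.n_snps < 1:
            raise ConfigurationError("n_genes and n_snps must be >= 1")
        if self.gene_length_bp > self.chrom_length_bp:
            raise ConfigurationError("gene longer than chromosome")
        if not (0 <= self.maf_min <= self.maf_max <= 1):
            raise ConfigurationError("MAF bounds must satisfy 0 <= min <= max <= 1")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if self.n_true_eqtls < 0:
            raise ConfigurationError("n_true_eqtls must be >= 0")


@dataclass
class PlantedTruth:
    """Ground-truth register: what was planted, for recovery assertions."""

    true_spatial_eqtls: dict[tuple[str, str], float] = field(default_factory=dict)
    pleiotropic_loci: dict[str, set[str]] = field(default_factory=dict)
    causal_genes: dict[str, float] = field(default_factory=dict)
    pleiotropy_intercept: dict[str, float] = field(default_factory=dict)
    comorbid_or: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticWorld:
    genome: pd.DataFrame        # chrom, length
    fragments: pd.DataFrame     # chrom, start, end, fragment_id
    genes: pd.DataFrame         # gene_id, chrom, start, end, strand, tpm
    snps: pd.DataFrame          # snp_id, chrom, pos, ref, alt, maf
    ld_pairs: pd.DataFrame      # snp_a, snp_b, r2
    contacts: pd.DataFrame      # fragment_a, fragment_b
    truth: PlantedTruth
    config: SimConfig

    def ld_resource(self) -> LdResource:
        positions = self.snps[["snp_id", "chrom", "pos"]]
        return LdResource(self.ld_pairs, positions)


def _tile_fragments(genome: pd.DataFrame, frag_len: int) -> pd.DataFrame:
    rows = []
    counter = 0
    for chrom, length in zip(genome["chrom"], genome["length"]):
        starts = np.arange(0, length, frag_len)
        for s in starts:
            rows.append(
                {"chrom": chrom, "start": int(s), "end": int(min(s + frag_len, length)),
                 "fragment_id": f"F{counter:05d}"}
            )
            counter += 1
    return pd.DataFrame(rows)


def gen_world(config: SimConfig, seed: int) -> SyntheticWorld:
    """Generate the base genomic world; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)

    genome = pd.DataFrame(
        {"chrom": [f"chr{i + 1}" for i in range(config.n_chromosomes)],
         "length": [config.chrom_length_bp] * config.n_chromosomes}
    )
    fragments = _tile_fragments(genome, config.fragment_length_bp)

    # genes: uniform placement, lognormal expression
    gene_chrom = rng.integers(0, config.n_chromosomes, size=config.n_genes)
    gene_start = rng.integers(0, config.chrom_length_bp - config.gene_length_bp + 1,
                              size=config.n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(config.n_genes)],
            "chrom": [f"chr{c + 1}" for c in gene_chrom],
            "start": gene_start,
            "end": gene_start + config.gene_length_bp,
            "strand": rng.choice(["+", "-"], size=config.n_genes),
            "tpm": np.round(rng.lognormal(config.tpm_log_mean, config.tpm_log_sd,
                                          size=config.n_genes), 2),
        }
    )

    # SNPs in LD blocks: a block anchors somewhere and members follow at
    # small gaps, so r2 >= 0.8 partners genuinely sit within the 5 kb window
    n_blocks = int(np.ceil(config.n_snps / config.ld_block_size))
    snp_rows, ld_rows = [], []
    snp_i = 0
    for b in range(n_blocks):
        size = min(config.ld_block_size, config.n_snps - b * config.ld_block_size)
        chrom = f"chr{rng.integers(0, config.n_chromosomes) + 1}"
        span = config.ld_max_gap_bp * (size + 1)
        anchor = int(rng.integers(0, config.chrom_length_bp - span))
        gaps = rng.integers(100, config.ld_max_gap_bp + 1, size=size - 1) if size > 1 else []
        positions = anchor + np.concatenate([[0], np.cumsum(gaps)]).astype(int)
        block_ids = []
        for pos in positions:
            pair = ALLELE_PAIRS[rng.integers(0, len(ALLELE_PAIRS))]
            snp_rows.append(
                {"snp_id": f"rs{snp_i:06d}", "chrom": chrom, "pos": int(pos),
                 "ref": pair[0], "alt": pair[1],
                 "maf": float(rng.uniform(config.maf_min, config.maf_max))}
            )
            block_ids.append(f"rs{snp_i:06d}")
            snp_i += 1
        for i in range(size):
            for j in range(i + 1, size):
                r2 = config.ld_r2_adjacent ** (j - i)
                ld_rows.append({"snp_a": block_ids[i], "snp_b": block_ids[j], "r2": r2})
    snps = pd.DataFrame(snp_rows)
    ld_pairs = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"])

    # planted regulatory pairs; SNP fragment must differ from all gene fragments
    snp_frag = grn_mod.assign_fragments(snps, fragments)
    gfrags = grn_mod.gene_fragments(genes, fragments)
    truth = PlantedTruth()
    contact_set: set[tuple[str, str]] = set()
    snp_ids = list(snps["snp_id"])
    gene_ids = list(genes["gene_id"])
    if config.n_true_genes is not None:
        if not 1 <= config.n_true_genes <= config.n_genes:
            raise ConfigurationError("n_true_genes must lie in [1, n_genes]")
        pool_idx = rng.choice(len(gene_ids), size=config.n_true_genes, replace=False)
        gene_ids = [gene_ids[i] for i in sorted(pool_idx)]
    available = snp_ids.copy()
    attempts = 0
    while len(truth.true_spatial_eqtls) < config.n_true_eqtls:
        attempts += 1
        if attempts > 50 * config.n_true_eqtls or not available:
            raise ConfigurationError("could not place the requested planted eQTL pairs")
        s = available[rng.integers(0, len(available))]
        g = gene_ids[rng.integers(0, len(gene_ids))]
        if not gfrags[g] or snp_frag[s] in gfrags[g]:
            continue
        available.remove(s)
        mu = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.8))
        truth.true_spatial_eqtls[(s, g)] = mu
        # planted regulatory variants are common variants: the pipeline only
        # tests MAF >= 0.05, so keep the planted signal inside that panel
        snps.loc[snps["snp_id"] == s, "maf"] = max(
            0.05, float(snps.loc[snps["snp_id"] == s, "maf"].iloc[0])
        )
        target = gfrags[g][rng.integers(0, len(gfrags[g]))]
        contact_set.add(tuple(sorted((snp_frag[s], target))))

    # background contacts
    frag_ids = list(fragments["fragment_id"])
    while len(contact_set) < config.n_true_eqtls + config.n_background_contacts:
        a, b = rng.choice(len(frag_ids), size=2, replace=False)
        contact_set.add(tuple(sorted((frag_ids[a], frag_ids[b]))))
    contacts = pd.DataFrame(sorted(contact_set), columns=["fragment_a", "fragment_b"])

    return SyntheticWorld(genome, fragments, genes, snps, ld_pairs, contacts, truth, config)


def spatial_candidates(world: SyntheticWorld, include_same_fragment: bool = True) -> pd.DataFrame:
    """All SNP-gene pairs with spatial support in the world's contact list."""
    snp_frag = grn_mod.assign_fragments(world.snps, world.fragments)
    return grn_mod.find_spatial_pairs(
        snp_frag, world.genes, world.fragments, world.contacts,
        include_same_fragment=include_same_fragment,
    )


def gen_eqtl_table(
    world: SyntheticWorld,
    effect_sd: float = 0.1,
    null_p_uniform: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Association statistics for every spatial SNP-gene candidate.

    Planted pairs draw p = 10**(-U), U ~ Uniform(6, 12) and beta ~
    N(mu_pair, effect_sd); all other candidates are null: p ~ Uniform(0, 1)
    and beta ~ N(0, effect_sd).  Alleles are copied from the SNP table so
    the table doubles as MR exposure data.

    Columns: ``snp, gene, effect_allele, other_allele, beta, se, p, gene_tpm``.
    """
    if effect_sd <= 0:
        raise ConfigurationError("effect_sd must be > 0")
    rng = np.random.default_rng(seed)
    cand = spatial_candidates(world)
    planted = world.truth.true_spatial_eqtls
    snp_info = world.snps.set_index("snp_id")
    tpm = dict(zip(world.genes["gene_id"], world.genes["tpm"]))
    rows = []
    for r in cand.itertuples():
        key = (r.snp_id, r.gene_id)
        if key in planted:
            p = 10.0 ** (-rng.uniform(6.0, 12.0))
            beta = float(rng.normal(planted[key], effect_sd))
        else:
            p = float(rng.uniform()) if null_p_uniform else 1.0
            beta = float(rng.normal(0.0, effect_sd))
        rows.append(
            {
                "snp": r.snp_id,
                "gene": r.gene_id,
                "effect_allele": snp_info.at[r.snp_id, "alt"],
                "other_allele": snp_info.at[r.snp_id, "ref"],
                "beta": beta,
                "se": float(rng.uniform(0.02, 0.08)),
                "p": p,
                "gene_tpm": tpm[r.gene_id],
            }
        )
    return pd.DataFrame(
        rows, columns=["snp", "gene", "effect_allele", "other_allele", "beta", "se", "p", "gene_tpm"]
    )


def query_snps(world: SyntheticWorld, n_extra: int = 10, seed: int = 0) -> list[str]:
    """The query-condition SNP list: planted regulatory SNPs plus decoys."""
    rng = np.random.default_rng(seed)
    planted = sorted({s for s, _ in world.truth.true_spatial_eqtls})
    rest = sorted(set(world.snps["snp_id"]) - set(planted))
    extra = list(rng.choice(rest, size=min(n_extra, len(rest)), replace=False)) if rest else []
    return sorted(set(planted) | set(extra))


def gen_gwas_catalog(
    world: SyntheticWorld,
    n_traits: int,
    pleiotropy_frac: float,
    seed: int = 0,
    trait_size: int = 20,
    n_pleiotropic: int = 1,
) -> pd.DataFrame:
    """Trait-SNP catalog with planted pleiotropic traits.

    The catalog universe is the world's SNP panel.  The first
    ``n_pleiotropic`` traits draw ``pleiotropy_frac`` of their SNPs from the
    query condition's planted regulatory SNPs, the remainder uniformly from
    the universe; other traits are drawn fully uniformly.  Planted shared
    SNP sets are recorded in ``world.truth.pleiotropic_loci``.

    Returns a long DataFrame with columns ``trait, snp``.
    """
    if n_traits < 1:
        raise ConfigurationError("n_traits must be >= 1")
    if not 0.0 <= pleiotropy_frac <= 1.0:
        raise ConfigurationError("pleiotropy_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = sorted(world.snps["snp_id"])
    eqtl_snps = sorted({s for s, _ in world.truth.true_spatial_eqtls})
    rows = []
    for t in range(n_traits):
        trait = f"trait_{t:03d}"
        planted_here = t < n_pleiotropic and pleiotropy_frac > 0 and eqtl_snps
        if planted_here:
            n_shared = min(int(round(pleiotropy_frac * trait_size)), len(eqtl_snps))
            shared = list(rng.choice(eqtl_snps, size=n_shared, replace=False))
            pool = sorted(set(universe) - set(shared))
            rest = list(rng.choice(pool, size=trait_size - n_shared, replace=False))
            members = shared + rest
            world.truth.pleiotropic_loci[trait] = set(shared)
        else:
            members = list(rng.choice(universe, size=min(trait_size, len(universe)),
                                      replace=False))
        rows.extend({"trait": trait, "snp": s} for s in sorted(members))
    return pd.DataFrame(rows, columns=["trait", "snp"])


def gen_ppin(
    world: SyntheticWorld,
    n_extra_proteins: int = 40,
    avg_degree: float = 4.0,
    seed: int = 0,
    score_low: float = 0.4,
    score_high: float = 1.0,
) -> PpinGraph:
    """Random scored interaction network over the world's gene products.

    Each gene maps to one protein (P suffix of the gene id); extra unmapped
    proteins pad the graph.  Edges follow an Erdos-Renyi draw with the
    requested mean degree and uniform scores, so thresholding at a high
    confidence score leaves a genuinely sparser graph.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(world.genes["gene_id"])
    proteins = [f"P_{g}" for g in gene_ids] + [f"PX{i:03d}" for i in range(n_extra_proteins)]
    n = len(proteins)
    p_edge = min(1.0, avg_degree / max(n - 1, 1))
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p_edge:
                rows.append(
                    {"protein_a": proteins[i], "protein_b": proteins[j],
                     "score": float(np.round(rng.uniform(score_low, score_high), 3))}
                )
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])
    mapping = {g: f"P_{g}" for g in gene_ids}
    return PpinGraph(edges, mapping)


def gen_mr_summary(
    world: SyntheticWorld,
    gene: str,
    n_instruments: int,
    theta: float,
    intercept_c: float = 0.0,
    seed: int = 0,
    swap_frac: float = 0.0,
    beta_x_mean: float = 0.2,
    beta_x_sd: float = 0.05,
    se_x: float = 0.02,
    se_y: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure/outcome GWAS summary statistics with a known causal effect.

    Per instrument j: beta_Xj ~ N(beta_x_mean, beta_x_sd^2) with fixed
    se_x; beta_Yj = theta * beta_Xj + intercept_c + eps_j, eps_j ~
    N(0, se_y^2).  A ``swap_frac`` fraction of outcome rows is emitted with
    effect/other alleles swapped (and beta negated) so harmonisation is
    exercised.  The planted effect is registered in ``world.truth``.
    """
    from scipy.stats import norm

    if n_instruments < 1:
        raise ConfigurationError("n_instruments must be >= 1")
    rng = np.random.default_rng(seed)
    snp_ids = [f"iv_{gene}_{j:04d}" for j in range(n_instruments)]
    alleles = [ALLELE_PAIRS[rng.integers(0, len(ALLELE_PAIRS))] for _ in snp_ids]
    bx = rng.normal(beta_x_mean, beta_x_sd, size=n_instruments)
    by = theta * bx + intercept_c + rng.normal(0.0, se_y, size=n_instruments)
    p_x = 2.0 * norm.sf(np.abs(bx) / se_x)
    p_y = 2.0 * norm.sf(np.abs(by) / se_y)
    exposure = pd.DataFrame(
        {
            "snp": snp_ids,
            "gene": gene,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "beta": bx,
            "se": se_x,
            "p": p_x,
        }
    )
    n_swap = int(round(swap_frac * n_instruments))
    swap_mask = np.zeros(n_instruments, dtype=bool)
    if n_swap:
        swap_mask[rng.choice(n_instruments, size=n_swap, replace=False)] = True
    outcome = pd.DataFrame(
        {
            "snp": snp_ids,
            "effect_allele": [b if m else a for (a, b), m in zip(alleles, swap_mask)],
            "other_allele": [a if m else b for (a, b), m in zip(alleles, swap_mask)],
            "beta": np.where(swap_mask, -by, by),
            "se": se_y,
            "p": p_y,
        }
    )
    world.truth.causal_genes[gene] = theta
    world.truth.pleiotropy_intercept[gene] = intercept_c
    return exposure, outcome


def gen_outcome_gwas(
    world: SyntheticWorld,
    eqtl_table: pd.DataFrame,
    theta_map: dict[str, float],
    intercept_map: dict[str, float] | None = None,
    seed: int = 0,
    se_y: float = 0.05,
) -> pd.DataFrame:
    """Outcome summary statistics for every SNP in an eQTL table.

    A SNP instrumenting a gene in ``theta_map`` inherits beta_Y =
    theta * beta_X (+ per-gene intercept) + noise; all other SNPs are null.
    When a SNP instruments several genes, the first planted gene wins.
    Alleles match the exposure orientation.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    intercept_map = intercept_map or {}
    rows = []
    for snp, g in eqtl_table.groupby("snp", sort=True):
        causal = [gg for gg in g["gene"] if gg in theta_map]
        if causal:
            gene = causal[0]
            bx = float(g.loc[g["gene"] == gene, "beta"].iloc[0])
            mean = theta_map[gene] * bx + intercept_map.get(gene, 0.0)
        else:
            mean = 0.0
        by = float(rng.normal(mean, se_y))
        first = g.iloc[0]
        rows.append(
            {
                "snp": snp,
                "effect_allele": first["effect_allele"],
                "other_allele": first["other_allele"],
                "beta": by,
                "se": se_y,
                "p": 2.0 * float(norm.sf(abs(by) / se_y)),
            }
        )
    for gene, theta in theta_map.items():
        world.truth.causal_genes[gene] = theta
        world.truth.pleiotropy_intercept[gene] = intercept_map.get(gene, 0.0)
    return pd.DataFrame(rows, columns=["snp", "effect_allele", "other_allele", "beta", "se", "p"])


def solve_comorbidity_cells(
    index_prevalence: float, base_rate: float, odds_ratio: float
) -> tuple[float, float]:
    """Per-group condition probabilities matching a marginal rate and OR.

    Given P(index) = pi, marginal condition rate r and target odds ratio,
    solve for q0 = P(condition | not index) and q1 = P(condition | index)
    such that pi*q1 + (1-pi)*q0 = r and odds(q1)/odds(q0) = OR.  Raises
    when no probability-valued solution exists.
    """
    pi, r, orr = index_prevalence, base_rate, odds_ratio
    if orr <= 0:
        raise ConfigurationError("odds ratio must be > 0")
    if not (0.0 < pi < 1.0 and 0.0 < r < 1.0):
        raise ConfigurationError("prevalence and base rate must lie in (0, 1)")
    if abs(orr - 1.0) < 1e-12:
        q0 = r
    else:
        a = (1 - pi) * (orr - 1)
        b = pi * orr + (1 - pi) - r * (orr - 1)
        c = -r
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ConfigurationError("infeasible OR/rate combination")
        roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
        valid = [q for q in roots if 0.0 < q < 1.0]
        q0 = None
        for q in valid:
            q1 = orr * q / (1 + (orr - 1) * q)
            if 0.0 < q1 < 1.0:
                q0 = q
                break
        if q0 is None:
            raise ConfigurationError("infeasible OR/rate combination")
    q1 = orr * q0 / (1 + (orr - 1) * q0)
    if not (0.0 < q0 < 1.0 and 0.0 < q1 < 1.0):
        raise ConfigurationError("infeasible OR/rate combination")
    return float(q0), float(q1)


def gen_admissions(
    n_individuals: int,
    index_prevalence: float,
    or_map: dict[str, float],
    base_rates: dict[str, float],
    seed: int = 0,
    index_code: str = "F840",
    truth: PlantedTruth | None = None,
) -> pd.DataFrame:
    """Person-level coded admission records with planted co-occurrence ORs.

    Each individual carries an index-condition flag (prevalence
    ``index_prevalence``); each non-index code k is sampled per person from
    the exact 2x2 cell-probability construction so the population odds
    ratio equals ``or_map[k]`` at its marginal ``base_rates[k]``.  Every
    person receives a generic encounter code so the full cohort is
    recoverable from the long table.

    Returns a DataFrame with columns ``person_id, icd10_code``.
    """
    if n_individuals < 1:
        raise ConfigurationError("n_individuals must be >= 1")
    if not 0.0 < index_prevalence < 1.0:
        raise ConfigurationError("index_prevalence must lie in (0, 1)")
    for code, r in base_rates.items():
        if not 0.0 < r < 1.0:
            raise ConfigurationError(f"base rate for {code} must lie in (0, 1)")
    if set(or_map) != set(base_rates):
        raise ConfigurationError("or_map and base_rates must cover the same codes")

    rng = np.random.default_rng(seed)
    is_index = rng.uniform(size=n_individuals) < index_prevalence
    person_ids = np.array([f"p{i:07d}" for i in range(n_individuals)])
    frames = [
        pd.DataFrame({"person_id": person_ids, "icd10_code": "Z000"}),
        pd.DataFrame({"person_id": person_ids[is_index], "icd10_code": index_code}),
    ]
    for code in sorted(or_map):
        q0, q1 = solve_comorbidity_cells(index_prevalence, base_rates[code], or_map[code])
        prob = np.where(is_index, q1, q0)
        has = rng.uniform(size=n_individuals) < prob
        frames.append(pd.DataFrame({"person_id": person_ids[has], "icd10_code": code}))
        if truth is not None:
            truth.comorbid_or[code] = or_map[code]
    return pd.concat(frames, ignore_index=True).sort_values(
        ["person_id", "icd10_code"], kind="mergesort"
    ).reset_index(drop=True)


def with_null_truth(world: SyntheticWorld) -> SyntheticWorld:
    """A copy of the world with no planted regulatory pairs (null scenario)."""
    return replace(world, truth=PlantedTruth())
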