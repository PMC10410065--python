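"""End-to-end orchestration: simulate -> GRN -> LD expand -> discovery -> MR
-> comorbidity, with per-stage staged output directories and a run manifest.

Two tissue contexts (e.g. "fetal" and "adult") run as independent
configurations over tissue-specific worlds; a comparison report counts the
bootstrap-significant traits shared between and unique to the two contexts.
Identical configuration and seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import comorbidity as cm
from . import grn as grn_mod
from . import io as pio
from . import mr as mr_mod
from . import ppin as ppin_mod
from . import synthetic as syn


class ConfigValidationError(ValueError):
    """A RunConfig field failed validation; the message names the field."""


@dataclass
class TissueConfig:
    label: str = "fetal"
    seed: int = 11
    # concentrate planted pairs on a few genes so multi-instrument MR runs;
    # a large SNP panel keeps the catalog universe much bigger than the
    # query set, as in real trait catalogs
    sim: dict = field(default_factory=lambda: {"n_true_genes": 5, "n_snps": 2000})
    n_traits: int = 100
    trait_size: int = 20
    pleiotropy_frac: float = 0.8
    n_pleiotropic: int = 1
    causal_theta: float = 0.5


@dataclass
class RunConfig:
    """Every stage parameter, mirroring the CLI flags.

    Defaults follow the analysis shape of the published procedure: LD
    expansion at r2 >= 0.8 within +/- 5 kb, interaction-score cutoff 0.7,
    four expansion levels, 1,000 bootstrap iterations, exposure p <= 1e-5,
    and 0.05 significance levels — at desk-scale synthetic sizes.
    """

    outdir: str = "runs/demo"
    tissues: list[TissueConfig] = field(default_factory=lambda: [
        TissueConfig(label="fetal", seed=11), TissueConfig(label="adult", seed=23),
    ])
    # GRN
    maf_min: float = 0.05
    grn_alpha: float = 0.05
    include_same_fragment: bool = True
    # LD
    ld_r2: float = 0.8
    ld_width_bp: int = 5_000
    # discovery
    max_level: int = 4
    min_score: float = 0.7
    enrich_alpha: float = 0.05
    n_iter: int = 1000
    bootstrap_threshold: float = 0.01
    # MR
    mr_p_max: float = 1e-5
    mr_alpha: float = 0.05
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    # comorbidity
    n_individuals: int = 50_000
    index_prevalence: float = 0.01
    comorbid_or: dict = field(default_factory=lambda: {"J45": 4.0, "E66": 1.0, "K21": 1.0})
    comorbid_base_rates: dict = field(default_factory=lambda: {"J45": 0.05, "E66": 0.08, "K21": 0.06})
    comorbidity_alpha: float = 0.05
    correction: str = "fdr_bh"
    comorbidity_seed: int = 404

    def validate(self) -> None:
        for name in ("maf_min", "grn_alpha", "ld_r2", "min_score", "enrich_alpha",
                     "bootstrap_threshold", "mr_alpha", "comorbidity_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigValidationError(f"{name} must lie in (0, 1]: got {v}")
        if self.max_level < 0 or self.max_level > 4:
            raise ConfigValidationError(f"max_level must lie in [0, 4]: got {self.max_level}")
        if self.n_iter < 1:
            raise ConfigValidationError(f"n_iter must be >= 1: got {self.n_iter}")
        if not self.tissues:
            raise ConfigValidationError("tissues must name at least one tissue context")
        labels = [t.label for t in self.tissues]
        if len(set(labels)) != len(labels):
            raise ConfigValidationError(f"tissues labels must be unique: got {labels}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        tissues = [TissueConfig(**t) for t in d.pop("tissues", [])] or None
        cfg = cls(**d) if tissues is None else cls(tissues=tissues, **d)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def validate_inputs(paths: dict[str, Path], schemas: dict[str, list[str]] | None = None) -> list[str]:
    """Report-only structural checks on a staged input bundle.

    Checks column schemas (when supplied), coordinate sanity on BED-like
    tables (0 <= start < end), allele alphabets on SNP tables and positive
    SEs on association tables.  Returns every violation found.
    """
    violations: list[str] = []
    schemas = schemas or {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            violations.append(f"{name}: missing file {path}")
            continue
        if path.suffix == ".json":
            continue
        if name == "fragments" or path.suffix == ".bed":
            df = pio.read_bed(path)
        else:
            df = pio.read_tsv(path)
        want = schemas.get(name)
        if want:
            missing = [c for c in want if c not in df.columns]
            if missing:
                violations.append(f"{name}: missing columns {missing}")
                continue
        if {"start", "end"}.issubset(df.columns):
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
            for _, r in bad.iterrows():
                violations.append(f"{name}: bad interval [{r['start']}, {r['end']})")
        if {"ref", "alt"}.issubset(df.columns):
            ok = set("ACGT")
            bad = df[~(df["ref"].isin(ok) & df["alt"].isin(ok))]
            for _, r in bad.iterrows():
                violations.append(f"{name}: bad alleles {r['ref']}/{r['alt']}")
        if "se" in df.columns and (df["se"] <= 0).any():
            n = int((df["se"] <= 0).sum())
            violations.append(f"{name}: {n} rows with se <= 0")
        if "pos" in df.columns and (df["pos"] < 0).any():
            violations.append(f"{name}: negative positions")
    return violations


def _run_tissue(cfg: RunConfig, tissue: TissueConfig, outdir: Path, manifest: dict) -> dict:
    """One tissue context end to end; returns summary objects for comparison."""
    t0 = time.perf_counter()
    stage_dir = outdir / tissue.label
    sim_cfg = syn.SimConfig(**tissue.sim)
    world = syn.gen_world(sim_cfg, seed=tissue.seed)
    eqtl_table = syn.gen_eqtl_table(world, seed=tissue.seed + 1)
    catalog = syn.gen_gwas_catalog(
        world, n_traits=tissue.n_traits, pleiotropy_frac=tissue.pleiotropy_frac,
        seed=tissue.seed + 2, trait_size=tissue.trait_size,
        n_pleiotropic=tissue.n_pleiotropic,
    )
    ppin = syn.gen_ppin(world, seed=tissue.seed + 3)

    sim_dir = stage_dir / "simulate"
    paths = pio.write_world(world, sim_dir)
    pio.write_tsv(eqtl_table, sim_dir / "eqtl_associations.tsv")
    pio.write_tsv(catalog, sim_dir / "gwas_catalog.tsv")
    pio.write_tsv(ppin.edges, sim_dir / "ppin_edges.tsv")
    manifest["stages"][f"{tissue.label}/simulate"] = {
        "rows": {"snps": len(world.snps), "genes": len(world.genes),
                 "contacts": len(world.contacts), "eqtl_candidates": len(eqtl_table)},
        "digests": {k: file_digest(p) for k, p in paths.items()},
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # GRN
    t0 = time.perf_counter()
    snp_frag = grn_mod.assign_fragments(world.snps, world.fragments)
    pairs = grn_mod.find_spatial_pairs(
        snp_frag, world.genes, world.fragments, world.contacts,
        include_same_fragment=cfg.include_same_fragment,
    )
    grn = grn_mod.call_eqtls(
        pairs, eqtl_table, world.snps, world.genes,
        maf_min=cfg.maf_min, alpha=cfg.grn_alpha,
        provenance={"tissue": tissue.label},
    )
    grn_dir = stage_dir / "grn"
    grn_dir.mkdir(parents=True, exist_ok=True)
    pio.write_tsv(grn.records, grn_dir / "grn.tsv")
    manifest["stages"][f"{tissue.label}/grn"] = {
        "rows": {"candidates": len(pairs), "significant": len(grn)},
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # LD expansion of the query SNPs
    t0 = time.perf_counter()
    from .ld import expand_ld

    query = syn.query_snps(world, seed=tissue.seed + 4)
    ldr = world.ld_resource()
    expanded, index_of = expand_ld(query, ldr, r2_min=cfg.ld_r2, width_bp=cfg.ld_width_bp)
    ld_dir = stage_dir / "ld"
    ld_dir.mkdir(parents=True, exist_ok=True)
    pio.write_tsv(
        pd.DataFrame(sorted(index_of.items()), columns=["snp", "index_snp"]),
        ld_dir / "expanded_query.tsv",
    )
    manifest["stages"][f"{tissue.label}/ld"] = {
        "rows": {"query": len(query), "expanded": len(expanded)},
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # discovery
    t0 = time.perf_counter()
    level0_genes, level0_pairs = ppin_mod.build_level0(expanded, grn)
    levels = ppin_mod.expand_ppin(level0_genes, ppin, max_level=cfg.max_level,
                                  min_score=cfg.min_score)
    levels = ppin_mod.requery_eqtls(levels, grn)
    enrichments = ppin_mod.enrich_traits(levels.level_eqtls, catalog, alpha=cfg.enrich_alpha)
    boot_cfg = ppin_mod.BootstrapConfig(
        n_iter=cfg.n_iter, resample_size=min(len(expanded), len(set(catalog["snp"]))),
        seed=tissue.seed + 5, threshold=cfg.bootstrap_threshold,
    )
    bootstrap = ppin_mod.bootstrap_null(
        enrichments, catalog, grn, ppin, boot_cfg,
        max_level=cfg.max_level, min_score=cfg.min_score,
    )
    discovery = ppin_mod.summarize_discovery(levels, enrichments, bootstrap,
                                             threshold=cfg.bootstrap_threshold)
    disc_dir = stage_dir / "discovery"
    disc_dir.mkdir(parents=True, exist_ok=True)
    pio.write_tsv(discovery, disc_dir / "trait_discovery.tsv")
    manifest["stages"][f"{tissue.label}/discovery"] = {
        "rows": {"level0_genes": len(level0_genes), "enriched": len(enrichments)},
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # Mendelian randomisation against a synthetic outcome GWAS
    t0 = time.perf_counter()
    planted_genes = [g for _, g in world.truth.true_spatial_eqtls]
    causal_gene = max(sorted(set(planted_genes)), key=planted_genes.count)
    outcome = syn.gen_outcome_gwas(
        world, eqtl_table, theta_map={causal_gene: tissue.causal_theta},
        seed=tissue.seed + 6,
    )
    mr_results = mr_mod.run_2smr(
        grn, eqtl_table, outcome, ld=ldr, p_max=cfg.mr_p_max, alpha=cfg.mr_alpha,
        clump_r2=cfg.clump_r2, clump_window_bp=cfg.clump_window_bp,
    )
    mr_frame = mr_mod.results_frame(mr_results)
    mr_dir = stage_dir / "mr"
    mr_dir.mkdir(parents=True, exist_ok=True)
    pio.write_tsv(mr_frame, mr_dir / "mr_results.tsv")
    pio.write_tsv(outcome, mr_dir / "outcome_gwas.tsv")
    manifest["stages"][f"{tissue.label}/mr"] = {
        "rows": {"genes_tested": int(mr_frame["gene"].nunique()) if len(mr_frame) else 0},
        "seconds": round(time.perf_counter() - t0, 3),
    }

    sig_traits = set(
        discovery.loc[discovery["significant_bootstrap"], "trait"]
    )
    return {"tissue": tissue.label, "world": world, "grn": grn, "discovery": discovery,
            "mr": mr_frame, "significant_traits": sig_traits}


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage for every tissue plus the shared comorbidity stage.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    Any stage failure still writes a manifest recording completed stages.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "status": "running"}
    results = []
    try:
        for tissue in cfg.tissues:
            results.append(_run_tissue(cfg, tissue, outdir, manifest))

        # comparison report across tissue contexts
        if len(results) >= 2:
            sig = [r["significant_traits"] for r in results[:2]]
            shared = sig[0] & sig[1]
            comparison = {
                "tissues": [r["tissue"] for r in results[:2]],
                "shared_traits": sorted(shared),
                "unique_to_first": sorted(sig[0] - sig[1]),
                "unique_to_second": sorted(sig[1] - sig[0]),
                "n_shared": len(shared),
            }
            (outdir / "tissue_comparison.json").write_text(
                json.dumps(comparison, indent=2, sort_keys=True) + "\n"
            )
            manifest["stages"]["comparison"] = {"rows": {"shared": len(shared)}}

        # comorbidity on a shared synthetic cohort
        t0 = time.perf_counter()
        truth = results[0]["world"].truth if results else None
        admissions = syn.gen_admissions(
            cfg.n_individuals, cfg.index_prevalence, cfg.comorbid_or,
            cfg.comorbid_base_rates, seed=cfg.comorbidity_seed, truth=truth,
        )
        records = cm.run_comorbidity(
            admissions, index_codes={"F840", "F845"},
            alpha=cfg.comorbidity_alpha, correction=cfg.correction,
        )
        cm_dir = outdir / "comorbidity"
        cm_dir.mkdir(parents=True, exist_ok=True)
        pio.write_tsv(cm.records_frame(records), cm_dir / "cooccurrence.tsv")
        manifest["stages"]["comorbidity"] = {
            "rows": {"codes_tested": len(records)},
            "seconds": round(time.perf_counter() - t0, 3),
        }
        manifest["status"] = "ok"
    except Exception as exc:  # record completed stages before re-raising
        manifest["status"] = f"failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["results"] = results
    return manifest
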