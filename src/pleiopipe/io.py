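"""Plain-text readers and writers for every pipeline table.

Fragments travel as 4-column BED (0-based half-open), genes as a GFF3-style
TSV, everything else as headered TSV; planted truth as JSON.  Writers are
deterministic: fixed column order, fixed float formatting, trailing
newline — so reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import PlantedTruth, SyntheticWorld

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments[["chrom", "start", "end", "fragment_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "fragment_id"], header=None
    )


def write_genes_gff(genes: pd.DataFrame, path: str | Path) -> None:
    """GFF3-style gene table: 1-based inclusive coordinates on output."""
    rows = []
    for g in genes.itertuples():
        attrs = f"ID={g.gene_id};tpm={g.tpm}"
        rows.append(
            [g.chrom, "pleiopipe", "gene", int(g.start) + 1, int(g.end), ".", g.strand, ".", attrs]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_genes_gff(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "source", "type", "start1", "end1",
                             "score", "strand", "frame", "attrs"])
    def parse_attr(attrs: str, key: str) -> str:
        for item in attrs.split(";"):
            k, _, v = item.partition("=")
            if k == key:
                return v
        raise ValueError(f"attribute {key} missing in {attrs!r}")
    return pd.DataFrame(
        {
            "gene_id": [parse_attr(a, "ID") for a in raw["attrs"]],
            "chrom": raw["chrom"],
            "start": raw["start1"] - 1,
            "end": raw["end1"],
            "strand": raw["strand"],
            "tpm": [float(parse_attr(a, "tpm")) for a in raw["attrs"]],
        }
    )


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "true_spatial_eqtls": [
            {"snp": s, "gene": g, "mu": mu} for (s, g), mu in sorted(truth.true_spatial_eqtls.items())
        ],
        "pleiotropic_loci": {t: sorted(s) for t, s in sorted(truth.pleiotropic_loci.items())},
        "causal_genes": dict(sorted(truth.causal_genes.items())),
        "pleiotropy_intercept": dict(sorted(truth.pleiotropy_intercept.items())),
        "comorbid_or": dict(sorted(truth.comorbid_or.items())),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        true_spatial_eqtls={(r["snp"], r["gene"]): r["mu"] for r in payload["true_spatial_eqtls"]},
        pleiotropic_loci={t: set(s) for t, s in payload["pleiotropic_loci"].items()},
        causal_genes=payload["causal_genes"],
        pleiotropy_intercept=payload["pleiotropy_intercept"],
        comorbid_or=payload["comorbid_or"],
    )


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write every world table under ``outdir``; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.tsv",
        "fragments": outdir / "fragments.bed",
        "genes": outdir / "genes.gff.tsv",
        "snps": outdir / "snps.tsv",
        "ld_pairs": outdir / "ld_pairs.tsv",
        "contacts": outdir / "contacts.tsv",
        "truth": outdir / "truth.json",
    }
    write_tsv(world.genome, paths["genome"])
    write_bed(world.fragments, paths["fragments"])
    write_genes_gff(world.genes, paths["genes"])
    write_tsv(world.snps, paths["snps"])
    write_tsv(world.ld_pairs, paths["ld_pairs"])
    write_tsv(world.contacts, paths["contacts"])
    write_truth(world.truth, paths["truth"])
    return paths
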