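"""Two-sample Mendelian randomisation over GRN genes.

For each gene, its significant regulatory SNPs act as instruments: exposure
effects (SNP -> transcript level) come from the eQTL association table,
outcome effects (SNP -> condition) from an outcome GWAS.  Weak instruments
(exposure p > 1e-5) are removed, the rest clumped to pairwise independence,
and alleles harmonised between the two tables.  Genes with a single
instrument get the Wald ratio; genes with two or more get the fixed-effect
inverse-variance-weighted (IVW) estimate, plus MR-Egger regression (whose
intercept absorbs directional pleiotropy) when three or more instruments
are available.  Significance is Bonferroni-corrected over the genes tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grn import Grn
from .ld import LdResource, clump

logger = logging.getLogger(__name__)

PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class UndefinedInstrumentError(ValueError):
    """Wald ratio requested with a zero exposure effect."""


class InsufficientInstrumentsError(ValueError):
    """Estimator needs more instruments than were supplied."""


@dataclass
class Instrument:
    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    p_exposure: float
    beta_outcome: float
    se_outcome: float
    p_outcome: float

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"non-positive SE for instrument {self.snp_id}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"identical alleles for instrument {self.snp_id}")


@dataclass
class MRGeneResult:
    gene_id: str
    method: str  # wald_ratio | ivw | egger
    estimate: float
    se: float
    p: float
    n_instruments: int
    p_bonferroni_threshold: float
    significant: bool
    egger_intercept: float | None = None
    intercept_se: float | None = None


def prepare_exposures(
    grn: Grn,
    assoc: pd.DataFrame,
    ld: LdResource | None = None,
    p_max: float = 1e-5,
    clump_r2: float = 0.001,
    clump_window_bp: int = 10_000_000,
) -> dict[str, pd.DataFrame]:
    """Instrument candidates per gene: strong, independent exposure eQTLs.

    ``assoc`` needs columns ``snp, gene, effect_allele, other_allele, beta,
    se, p``.  Per gene: instruments filtered to p <= ``p_max``, then greedily
    clumped to pairwise independence (skipped when no LD resource is given).
    Genes with no surviving instrument are dropped with a log entry.
    """
    exposure = grn.records[["snp", "gene"]].merge(assoc, on=["snp", "gene"], how="inner")
    out: dict[str, pd.DataFrame] = {}
    for gene, rows in exposure.groupby("gene"):
        strong = rows[rows["p"] <= p_max]
        if strong.empty:
            logger.info("gene %s dropped: no instrument with exposure p <= %g", gene, p_max)
            continue
        if ld is not None and len(strong) > 1:
            pvals = dict(zip(strong["snp"], strong["p"]))
            kept = clump(list(strong["snp"]), pvals, ld, r2_max=clump_r2, window_bp=clump_window_bp)
            strong = strong[strong["snp"].isin(kept)]
        out[gene] = strong.sort_values("snp").reset_index(drop=True)
    return out


def harmonise(exposure: pd.DataFrame, outcome: pd.DataFrame) -> list[Instrument]:
    """Align outcome effect alleles onto the exposure's, dropping ambiguity.

    SNPs present in both tables are retained.  When the outcome's
    effect/other alleles are the exposure's swapped, the outcome beta is
    negated.  Palindromic SNPs (A/T, C/G) and unresolvable allele mismatches
    are dropped with a log entry.
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"), how="inner")
    instruments: list[Instrument] = []
    for row in merged.itertuples():
        ea_x, oa_x = row.effect_allele_x, row.other_allele_x
        ea_y, oa_y = row.effect_allele_y, row.other_allele_y
        if frozenset({ea_x, oa_x}) in PALINDROMIC:
            logger.info("SNP %s dropped: palindromic alleles %s/%s", row.snp, ea_x, oa_x)
            continue
        if (ea_y, oa_y) == (ea_x, oa_x):
            beta_y = row.beta_y
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y = -row.beta_y
        else:
            logger.info(
                "SNP %s dropped: allele mismatch %s/%s vs %s/%s", row.snp, ea_x, oa_x, ea_y, oa_y
            )
            continue
        instruments.append(
            Instrument(
                snp_id=row.snp,
                effect_allele=ea_x,
                other_allele=oa_x,
                beta_exposure=row.beta_x,
                se_exposure=row.se_x,
                p_exposure=row.p_x,
                beta_outcome=beta_y,
                se_outcome=row.se_y,
                p_outcome=row.p_y,
            )
        )
    return instruments


def wald_ratio(inst: Instrument) -> tuple[float, float, float]:
    """Single-instrument causal estimate: beta_Y / beta_X.

    SE by the first-order delta method (se_Y / |beta_X|); p from the normal
    approximation.
    """
    if inst.beta_exposure == 0:
        raise UndefinedInstrumentError(f"instrument {inst.snp_id} has zero exposure effect")
    est = inst.beta_outcome / inst.beta_exposure
    se = inst.se_outcome / abs(inst.beta_exposure)
    p = 2.0 * float(norm.sf(abs(est) / se))
    return est, se, p


def ivw(instruments: list[Instrument]) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted estimate.

    Weighted least squares of beta_Y on beta_X through the origin with
    weights 1/se_Y^2:  estimate = sum(w bx by) / sum(w bx^2),
    se = 1/sqrt(sum(w bx^2)).
    """
    if len(instruments) < 1:
        raise InsufficientInstrumentsError("IVW needs at least one instrument")
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    w = np.array([1.0 / i.se_outcome**2 for i in instruments])
    denom = float(np.sum(w * bx * bx))
    est = float(np.sum(w * bx * by)) / denom
    se = 1.0 / np.sqrt(denom)
    p = 2.0 * float(norm.sf(abs(est) / se))
    return est, se, p


def egger(instruments: list[Instrument]) -> tuple[float, float, float, float, float]:
    """MR-Egger weighted regression with intercept.

    Instruments are first oriented so every beta_X >= 0, then beta_Y is
    regressed on beta_X with weights 1/se_Y^2.  The intercept estimates the
    average directional pleiotropic effect.  Returns (slope, slope_se,
    slope_p, intercept, intercept_se).
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("Egger regression needs at least 3 instruments")
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = np.array([1.0 / i.se_outcome**2 for i in instruments])
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    cov = np.linalg.inv(xtwx)
    coef = cov @ xtwy
    intercept, slope = float(coef[0]), float(coef[1])
    intercept_se = float(np.sqrt(cov[0, 0]))
    slope_se = float(np.sqrt(cov[1, 1]))
    slope_p = 2.0 * float(norm.sf(abs(slope) / slope_se))
    return slope, slope_se, slope_p, intercept, intercept_se


def run_2smr(
    grn: Grn,
    exposure_assoc: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    ld: LdResource | None = None,
    p_max: float = 1e-5,
    alpha: float = 0.05,
    clump_r2: float = 0.001,
    clump_window_bp: int = 10_000_000,
) -> list[MRGeneResult]:
    """Full per-gene causal screen with Bonferroni-adjusted significance.

    Routing: 1 harmonised instrument -> Wald ratio; >= 2 -> IVW (the primary
    record, which drives the Bonferroni significance call); >= 3 additionally
    an MR-Egger sensitivity record for the same gene.  The significance
    threshold is alpha / (genes tested), not alpha / (records emitted).
    """
    candidates = prepare_exposures(
        grn, exposure_assoc, ld=ld, p_max=p_max, clump_r2=clump_r2, clump_window_bp=clump_window_bp
    )
    per_gene: dict[str, list[Instrument]] = {}
    for gene, exp_rows in candidates.items():
        instruments = harmonise(exp_rows, outcome_stats)
        instruments = [i for i in instruments if i.beta_exposure != 0]
        if instruments:
            per_gene[gene] = instruments
        else:
            logger.info("gene %s dropped: no harmonisable instruments", gene)
    if not per_gene:
        warnings.warn("no genes with usable instruments; empty MR result", stacklevel=2)
        return []
    threshold = alpha / len(per_gene)
    results: list[MRGeneResult] = []
    for gene, instruments in sorted(per_gene.items()):
        if len(instruments) == 1:
            est, se, p = wald_ratio(instruments[0])
            res = MRGeneResult(gene, "wald_ratio", est, se, p, 1, threshold, p < threshold)
            results.append(res)
            continue
        else:
            est, se, p = ivw(instruments)
            results.append(
                MRGeneResult(gene, "ivw", est, se, p, len(instruments), threshold, p < threshold)
            )
            if len(instruments) >= 3:
                slope, slope_se, slope_p, intercept, intercept_se = egger(instruments)
                results.append(
                    MRGeneResult(
                        gene, "egger", slope, slope_se, slope_p, len(instruments),
                        threshold, slope_p < threshold,
                        egger_intercept=intercept, intercept_se=intercept_se,
                    )
                )
    results.sort(key=lambda r: (r.p, r.gene_id))
    return results


def results_frame(results: list[MRGeneResult]) -> pd.DataFrame:
    cols = ["gene", "method", "estimate", "se", "p", "n_instruments",
            "egger_intercept", "intercept_se", "p_bonferroni_threshold", "significant"]
    rows = [
        {
            "gene": r.gene_id,
            "method": r.method,
            "estimate": r.estimate,
            "se": r.se,
            "p": r.p,
            "n_instruments": r.n_instruments,
            "egger_intercept": np.nan if r.egger_intercept is None else r.egger_intercept,
            "intercept_se": np.nan if r.intercept_se is None else r.intercept_se,
            "p_bonferroni_threshold": r.p_bonferroni_threshold,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=cols)
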