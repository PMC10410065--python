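# Methods notes

This note documents the models and procedures `pleiopipe` implements, the
parameters that matter, what the synthetic worlds do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Spatially constrained eQTL GRN

A regulatory candidate is a SNP–gene pair whose SNP-bearing restriction
fragment either contacts a fragment overlapping the gene or *is* such a
fragment. The spatial gate is presence/absence: contact lists are
symmetric and unweighted, because the gate is only ever used as a binary
filter, never quantitatively. Coordinates are 0-based half-open (BED
convention) throughout; a SNP at position *p* belongs to the unique
fragment with start ≤ p < end.

Calling proceeds in three steps: (1) SNPs with MAF < `maf_min` (default
0.05 — the common-variant convention) are removed *before* testing, so
they never enter the multiple-testing family; (2) Benjamini–Hochberg is
applied jointly over all remaining spatial candidates in one family (not
per chromosome or per gene), via `statsmodels`; (3) records with adjusted
*p* ≤ `alpha` (default 0.05) are retained and annotated. "Any
gene-overlapping fragment" satisfies the contact requirement — the
contact need not reach the TSS fragment specifically — and same-fragment
SNP–gene pairs are included by default (`include_same_fragment`), since a
SNP inside a gene's own fragment is trivially spatially proximal. Both
choices are configurable.

Interaction classes use the standard distance rule: same chromosome and
distance < 1 Mb → *cis*; ≥ 1 Mb → *trans-intrachromosomal*; different
chromosomes → *trans-interchromosomal*. Distance runs from the SNP to the
nearest gene boundary and is 0 inside the gene; exactly 1 Mb maps to
trans, because the cis window is strictly "within" 1 Mb.

## LD operations

All LD logic consumes a precomputed pairwise r² resource; missing pairs
count as r² = 0 (sparse tables are therefore safe), r²(s,s) = 1.

- **Expansion** (defaults r² ≥ 0.8, width 5,000 bp): "width" is read as a
  ±window around the index SNP, matching common tooling semantics; both
  parameters are exposed. Added SNPs are tagged with their best index
  (highest r², ties broken by distance then id).
- **Clumping** (defaults r² < 0.001, window 10 Mb — the convention of the
  standard 2SMR framework, since instrument-independence parameters are
  otherwise unstated): greedy by ascending p, ties by id; a SNP is
  accepted iff it is below the r² ceiling against every accepted SNP
  within the window.
- **Locus grouping**: single-linkage over the same edge rule; connected
  components become loci; the index SNP is the lowest-p member.

## Multi-level PPIN discovery

Level 0 is the set of genes whose GRN records carry a query SNP (the
query should be LD-expanded first; that is the caller's contract). The
PPIN is thresholded at score ≥ `min_score` (default 0.700, inclusive —
"high confidence" cutoffs are conventionally inclusive; configurable) and
walked breadth-first from the level-0 protein set: a protein reachable at
several depths is assigned its minimum depth only, so levels are
disjoint; expansion stops at level 4. Genes without a protein mapping are
skipped, not fatal. Each level's genes re-query the *full* GRN, so a
level's eQTL set can be larger than the SNPs that selected it — that is
the point: pleiotropy is read off shared regulatory inputs of the level's
genes.

**Enrichment.** For each (trait, level): universe N = distinct SNPs in
the supplied catalog (the most conservative self-contained choice — the
original universe is undefined otherwise), K = trait SNPs, n = level
eQTLs ∩ universe, k = overlap; p = P(X ≥ k), upper tail inclusive of the
observed count (standard over-representation convention). Levels whose
eQTLs miss the universe entirely are skipped with a warning. Traits pass
at p < 0.05.

**Bootstrap null.** Each iteration draws `resample_size` distinct SNPs
uniformly without replacement from the catalog universe (no LD or MAF
matching — the resampling scheme is plain random selection), reruns
level-0 construction → PPIN walk → re-query, and counts each
(trait, level) overlap. The p-value is the verbatim count formula
`#{bootstrap ≥ observed}/n_iter`, so p = 0 is attainable; a
`conservative` flag switches to (b+1)/(n+1). The default significance
threshold is 0.01, with 0.05 also in common use for this statistic; both
are supported (`BootstrapConfig.threshold`). Levels are tested without
cross-level correction, mirroring the per-level procedure. The walk is
re-run through precomputed hash lookups (`_FastDiscovery`), which makes
1,000 iterations sub-second at desk scale without changing any result.

## Two-sample Mendelian randomisation

Instruments per gene: GRN eQTLs with exposure p ≤ 1e-5, clumped, then
harmonised against the outcome table. Harmonisation keeps SNPs present in
both tables; swapped effect/other alleles negate the outcome beta;
palindromic SNPs (A/T, C/G) are dropped outright — outcome allele
frequencies are not part of the data contract, so frequency-based rescue
is impossible; unresolvable mismatches are dropped with a log entry.

Estimators (authored here, closed-form):

- Wald ratio (1 instrument): β_Y/β_X, se = se_Y/|β_X| (first-order delta
  method), normal p.
- IVW (≥ 2): weighted regression through the origin, weights 1/se_Y²;
  fixed-effects (no overdispersion scaling) — the simplest defensible
  default when the error model is unstated. IVW with a single instrument
  reduces algebraically to the Wald ratio; the tests assert this to
  machine precision.
- MR-Egger (≥ 3): weighted regression with intercept after orienting all
  β_X ≥ 0; the intercept estimates average directional pleiotropy.
  Variances come from (XᵀWX)⁻¹.

Per gene the IVW (or Wald) record is primary and drives the Bonferroni
call at `alpha / (genes tested after filtering)`; Egger is emitted as a
separate sensitivity record (`method="egger"`), never the primary call.
Whether the original convention required IVW–Egger agreement is unknown;
both are reported, neither gated on the other.

## Comorbidity

Person-level deduplication: a person is index-positive with ≥ 1 admission
carrying any index code, and contributes once to one cell of each 2×2
table. Codes are compared at the granularity supplied (no hierarchical
roll-up), and there is no age/sex adjustment — the analysis is a crude
cross-sectional screen by design. The sample OR is ad/bc, marked infinite
when bc = 0 with ad > 0 and undefined at 0/0; Fisher's two-sided p comes
from `scipy`; the 95% CI is the log-OR normal approximation with a 0.5
Haldane correction when any cell is empty. Correction defaults to BH
(Bonferroni available); records pass at adjusted p ≤ 0.05.

## Synthetic worlds: what they emulate, what they do not

The generators are pure functions of (config, seed) and register every
planted identifier in `PlantedTruth`, so downstream recovery is an
assertion, not an impression. Defaults: two 1 Mb chromosomes cut into
4 kb fragments, 60 genes of 10 kb, 400 SNPs in 4-SNP LD blocks
(adjacent-pair r² 0.9, decaying geometrically; block members within
1.5 kb gaps so the ±5 kb expansion window is exercised), 20 planted
regulatory pairs, 300 background contacts, lognormal TPM. Planted pair
p-values are 10^(−U), U ~ Uniform(6, 12) — guaranteed BH survival at desk
scale without modelling sample size; planted betas are N(μ_pair, 0.1)
with |μ| in 0.3–0.8; everything else is null-uniform. Planted SNPs have
their MAF clamped to ≥ 0.05 because the pipeline only tests common
variants. LD is represented directly as block r² matrices, not genotypes,
because the pipeline only ever consumes r².

The orchestrated demo uses a larger panel (2,000 SNPs, 100 traits of 20
SNPs, planted pairs concentrated on 5 genes). Two sizes matter and were
chosen on first principles: the catalog universe must dwarf the query set
(as in real catalogs) or the bootstrap null degenerates — a draw covering
a quarter of the universe keeps re-activating the planted genes — and
planted genes need several instruments each so the IVW/Egger paths run,
not just Wald.

The admissions generator solves the 2×2 cell probabilities exactly from
(index prevalence, marginal code rate, target OR) via the quadratic in
P(code | not index); note that every such triple strictly inside (0,1)
with OR > 0 is feasible (as q₀ → 1, q₁ → 1 for any OR), so the
infeasibility guard only fires on out-of-range inputs. Every person also
receives a generic encounter code so the cohort denominator is
recoverable from the long table, mirroring a hospitalised-population
comparison group.

Not emulated: genotype-level LD (no coalescent structure), Hi-C read
counts or contact-frequency biases, expression quantification, sample
overlap between exposure and outcome GWAS, weak-instrument bias
(exposure effects are drawn well away from zero), ICD coding error, and
age/sex structure in the cohort. Passing tests therefore certify the
*inference machinery* — gating, correction, estimators, null calibration,
recovery — under clean generative assumptions, not robustness to the
failure modes of real accessions.

## Numerical and testing choices

Determinism: every generator and the bootstrap take explicit seeds
(`numpy.random.default_rng`); writers fix column order and float format,
so identical config + seed reproduces byte-identical stage outputs. Ties
are broken lexicographically by id everywhere an order matters
(clump acceptance, best-index tagging, output sorting by level, p, then
trait/gene/code). Degenerate inputs (empty level-0 intersection, genes
with no surviving instruments, codes with no index persons) warn or log
and continue rather than abort; truly inconsistent inputs (SNP outside
all fragments, candidate pair missing from the association table) raise.

Test sizes are chosen to keep the full suite around a minute and the
acceptance script around two: exhaustive oracles run at N ≤ 12 (exact
agreement with enumeration), calibration at 200 bootstrap iterations × 50
traits, estimator recovery at 1,000 simulated genes, comorbidity coverage
at 100 cohorts of 200,000 persons. Independent oracles (step-up BH,
hypergeometric and Fisher tail enumeration, matrix-power BFS, literal
greedy clumping, transitive closure) live in the test suite and share no
code with the implementation.
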