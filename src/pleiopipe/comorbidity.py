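"""Co-occurring conditions in person-level coded health records.

For an index condition defined by one or more ICD-10 codes, every other
code present in the admissions table is cross-tabulated against the index
flag at the person level (repeat admissions count once), tested with a
two-sided Fisher exact test, and corrected for multiple testing.  The odds
ratio reported is the sample OR a*d / (b*c) with a log-scale normal 95%
confidence interval (Haldane 0.5 correction when a cell is empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm
from statsmodels.stats.multitest import multipletests


@dataclass
class CooccurrenceRecord:
    code: str
    a: int  # index & code
    b: int  # index & not code
    c: int  # not index & code
    d: int  # neither
    odds_ratio: float  # inf when bc == 0 with ad > 0, nan for 0/0
    p_fisher: float
    p_adjusted: float
    ci_low: float
    ci_high: float
    significant: bool


def build_contingency(
    admissions: pd.DataFrame, index_codes: set[str], code: str
) -> tuple[int, int, int, int]:
    """Person-level 2x2 counts of the index condition against one code.

    A person is index-positive with >= 1 admission carrying any index code;
    repeat admissions never double count.  Returns (a, b, c, d) =
    (index&code, index&!code, !index&code, !index&!code).
    """
    if code in index_codes:
        raise ValueError(f"code {code} is an index code; self-comparison skipped")
    persons = admissions["person_id"]
    index_persons = set(persons[admissions["icd10_code"].isin(index_codes)])
    code_persons = set(persons[admissions["icd10_code"] == code])
    all_persons = set(persons)
    a = len(index_persons & code_persons)
    b = len(index_persons) - a
    c = len(code_persons) - a
    d = len(all_persons) - a - b - c
    return a, b, c, d


def fisher_or(table: tuple[int, int, int, int]) -> tuple[float, float, tuple[float, float]]:
    """Sample odds ratio, two-sided Fisher exact p, and normal-theory 95% CI.

    The CI uses log(OR) +/- 1.96 * sqrt(sum 1/cell), with 0.5 added to every
    cell when any is zero.  OR is inf when b*c = 0 (and a*d > 0), nan when
    both products vanish.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    log_or = np.log((cells[0] * cells[3]) / (cells[1] * cells[2]))
    se = np.sqrt((1.0 / cells).sum())
    z = norm.ppf(0.975)
    ci = (float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)))
    return float(odds), float(p), ci


def run_comorbidity(
    admissions: pd.DataFrame,
    index_codes: set[str],
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    min_code_persons: int = 1,
) -> list[CooccurrenceRecord]:
    """Screen every non-index code for co-occurrence with the index condition.

    One record per code; the chosen correction (``fdr_bh`` or
    ``bonferroni``) is applied over all tested codes; records with adjusted
    p <= ``alpha`` are flagged significant.  Sorted by adjusted p then code.
    """
    if admissions.empty:
        raise ValueError("admissions table is empty")
    codes = sorted(set(admissions["icd10_code"]) - set(index_codes))
    counts = admissions.groupby("icd10_code")["person_id"].nunique()
    codes = [c for c in codes if counts.get(c, 0) >= min_code_persons]
    tables = [build_contingency(admissions, index_codes, c) for c in codes]
    stats = [fisher_or(t) for t in tables]
    pvals = np.array([p for _, p, _ in stats])
    if len(pvals) == 0:
        return []
    _, p_adj, _, _ = multipletests(pvals, method=correction)
    records = [
        CooccurrenceRecord(
            code=code, a=t[0], b=t[1], c=t[2], d=t[3],
            odds_ratio=odds, p_fisher=p, p_adjusted=float(pa),
            ci_low=ci[0], ci_high=ci[1], significant=bool(pa <= alpha),
        )
        for code, t, (odds, p, ci), pa in zip(codes, tables, stats, p_adj)
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.code))
    return records


def records_frame(records: list[CooccurrenceRecord]) -> pd.DataFrame:
    cols = ["code", "a", "b", "c", "d", "odds_ratio", "p_fisher", "p_adjusted",
            "ci_low", "ci_high", "significant"]
    return pd.DataFrame([r.__dict__ for r in records], columns=cols)
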