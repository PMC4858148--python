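"""BO vs AO differential expression on normalized read counts.

Counts are normalized to reads per million genome-matched reads (RPM);
each miRNA's 2x2 table [[count_BO, N_BO - count_BO], [count_AO,
N_AO - count_AO]] is tested with a two-sided Fisher exact test
(primary) and a Pearson chi-square without continuity correction
(companion). Fold-change is RPM_AO / RPM_BO; a 0.5-read pseudocount in
both conditions keeps ratios finite when either count is zero (the
pseudocount never enters the tests). Screening keeps DE-flagged miRNAs
with |log2 fold-change| >= 1.0; RT-qPCR candidate selection further
requires raw reads >= 40 in some condition and a reproduction-related
annotation term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# reproduction events recognised by candidate selection
DEFAULT_ANNOTATION_KEYWORDS = (
    "gonad development", "muscle development", "glucose metabolism",
    "fat metabolism", "insulin metabolism",
    "sex hormone synthesis and secretion",
)


@dataclass
class ScreenConfig:
    alpha_de: float = 0.05
    min_abs_log2fc: float = 1.0
    alpha_top: float = 0.01
    min_raw_reads: int = 40
    annotation_keywords: tuple[str, ...] = DEFAULT_ANNOTATION_KEYWORDS

    def __post_init__(self):
        for a in (self.alpha_de, self.alpha_top):
            if not 0.0 < a < 1.0:
                raise ValueError("significance levels must be in (0, 1)")


def normalize(count: float, total_genome_matched: float) -> float:
    """Reads per million genome-matched reads: 1e6 * count / total."""
    if total_genome_matched <= 0:
        raise ValueError("genome-matched total must be positive")
    if count > total_genome_matched:
        raise ValueError("count exceeds genome-matched total")
    return 1e6 * count / total_genome_matched


def fisher_p(count_bo: int, n_bo: int, count_ao: int, n_ao: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table; the p-value is the sum
    of hypergeometric probabilities of all tables (same margins) no more
    probable than the observed one.

    Implemented as a vectorized enumeration of the hypergeometric
    support, with a 1 + 1e-12 relative guard so exact probability ties
    are included despite floating-point rounding.
    """
    if min(count_bo, count_ao) < 0 or count_bo > n_bo or count_ao > n_ao:
        raise ValueError("counts must be non-negative and not exceed totals")
    n = n_bo + n_ao
    k = count_bo + count_ao
    dist = stats.hypergeom(n, k, n_bo)
    support = np.arange(max(0, k - n_ao), min(k, n_bo) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(count_bo)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def chisq_p(count_bo: int, n_bo: int, count_ao: int, n_ao: int) -> float:
    """Pearson chi-square p (1 df, no continuity correction) on the same
    2x2 table; degenerate tables (a zero margin) give p = 1."""
    table = np.array([[count_bo, n_bo - count_bo],
                      [count_ao, n_ao - count_ao]])
    if table.min() < 0:
        raise ValueError("negative cell in 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table, correction=False).pvalue)


def fold_change(count_bo: int, n_bo: int, count_ao: int, n_ao: int) -> float:
    """RPM_AO / RPM_BO, with a 0.5-read pseudocount in both conditions
    when either raw count is zero (ratio/log reporting only)."""
    if count_bo == 0 or count_ao == 0:
        count_bo, count_ao = count_bo + 0.5, count_ao + 0.5
    return normalize(count_ao, n_ao) / normalize(count_bo, n_bo)


def direction(fc: float) -> str:
    if fc > 1.0:
        return "up"
    if fc < 1.0:
        return "down"
    return "flat"


def de_table(counts: pd.DataFrame, n_bo: int, n_ao: int,
             screen: ScreenConfig | None = None,
             bh_correct: bool = False) -> pd.DataFrame:
    """Per-miRNA differential-expression table.

    *counts* must carry columns ``count_bo`` and ``count_ao`` indexed by
    miRNA. Output columns: raw counts, RPM in both conditions,
    fold_change (AO/BO), log2_fc, fisher_p, chisq_p, direction, de_flag
    (fisher_p < alpha, optionally BH-adjusted) and top_flag (DE and
    |log2_fc| >= threshold). fold_change/log2_fc are full precision here;
    ``round_for_output`` applies the 2-decimal file convention.
    """
    screen = screen or ScreenConfig()
    rows = []
    for mirna, r in counts.iterrows():
        cb, ca = int(r["count_bo"]), int(r["count_ao"])
        fc = fold_change(cb, n_bo, ca, n_ao)
        rows.append({
            "mirna": mirna, "count_bo": cb, "count_ao": ca,
            "rpm_bo": normalize(cb, n_bo), "rpm_ao": normalize(ca, n_ao),
            "fold_change": fc, "log2_fc": float(np.log2(fc)),
            "fisher_p": fisher_p(cb, n_bo, ca, n_ao),
            "chisq_p": chisq_p(cb, n_bo, ca, n_ao),
            "direction": direction(fc),
        })
    de = pd.DataFrame(rows).set_index("mirna")
    pvals = de["fisher_p"]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        de["fisher_p_adj"] = multipletests(pvals, method="fdr_bh")[1]
        de["de_flag"] = de["fisher_p_adj"] < screen.alpha_de
    else:
        de["de_flag"] = pvals < screen.alpha_de
    de["top_flag"] = de["de_flag"] & (de["log2_fc"].abs()
                                      >= screen.min_abs_log2fc)
    return de


def screen_top(de: pd.DataFrame, screen: ScreenConfig | None = None
               ) -> pd.DataFrame:
    """DE-flagged rows with |log2_fc| >= min_abs_log2fc (full-precision
    comparison, inclusive), sorted by log2_fc descending."""
    screen = screen or ScreenConfig()
    top = de[de["de_flag"] & (de["log2_fc"].abs() >= screen.min_abs_log2fc)]
    return top.sort_values("log2_fc", ascending=False)


def select_candidates(de: pd.DataFrame,
                      annotations: dict[str, list[str]] | None,
                      screen: ScreenConfig | None = None) -> list[str]:
    """RT-qPCR candidates: DE-flagged, raw reads >= min_raw_reads in at
    least one condition, and at least one annotation term among the
    reproduction keywords. Missing annotation entries mean no terms."""
    screen = screen or ScreenConfig()
    annotations = annotations or {}
    keywords = {k.lower() for k in screen.annotation_keywords}
    out = []
    for mirna, r in de.iterrows():
        if not r["de_flag"]:
            continue
        if max(r["count_bo"], r["count_ao"]) < screen.min_raw_reads:
            continue
        terms = {t.lower() for t in annotations.get(mirna, [])}
        if terms & keywords:
            out.append(mirna)
    return out


def round_for_output(de: pd.DataFrame) -> pd.DataFrame:
    """File-output convention: fold_change and log2_fc rounded to 2
    decimals (screening always uses the full-precision columns)."""
    out = de.copy()
    out["fold_change"] = out["fold_change"].round(2)
    out["log2_fc"] = out["log2_fc"].round(2)
    return out
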