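"""Independent reference implementations used only to check results.

These deliberately avoid the package's algorithms: folding by explicit
recursive enumeration of every nested pairing, Fisher's test by exact
rational hypergeometric arithmetic, ANOVA by textbook sums of squares.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

PAIR = {("G", "C"): 2, ("C", "G"): 2, ("A", "U"): 1, ("U", "A"): 1,
        ("G", "U"): 1, ("U", "G"): 1}


def enum_best_score(seq: str, min_loop: int = 3) -> int:
    """Maximum weighted-pair score over all nested structures, by direct
    enumeration (first position unpaired or paired with each partner)."""
    seq = seq.upper().replace("T", "U")

    def rec(i: int, j: int) -> int:
        if j <= i:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            w = PAIR.get((seq[i], seq[k]), 0)
            if w:
                best = max(best, w + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def fisher_two_sided(a: int, na: int, b: int, nb: int) -> Fraction:
    """Two-sided Fisher exact p as an exact rational: sum of
    hypergeometric probabilities not exceeding the observed one."""
    n, k = na + nb, a + b
    denom = comb(n, na)

    def weight(x: int) -> int:
        return comb(k, x) * comb(n - k, na - x)

    w_obs = weight(a)
    total = sum(w for x in range(max(0, k - nb), min(k, na) + 1)
                if (w := weight(x)) <= w_obs)
    return Fraction(total, denom)


def anova_f_p(groups) -> tuple[float, float]:
    """One-way ANOVA F and p from textbook sums of squares."""
    import numpy as np
    from scipy.stats import f as fdist
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(fdist.sf(F, df_b, df_w))


def tally_counts(sequences) -> dict[str, int]:
    """Dictionary-free recount: sort, then run-length scan."""
    out = {}
    run, n = None, 0
    for s in sorted(sequences):
        if s == run:
            n += 1
        else:
            if run is not None:
                out[run] = n
            run, n = s, 1
    if run is not None:
        out[run] = n
    return out
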