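"""Novel miRNA prediction from unannotated genome-matched tags.

A candidate precursor window is extracted around each unannotated tag
locus (the tag tried as the 5p arm and as the 3p arm), folded into a
pseudoknot-free secondary structure, and screened with the eleven
structural criteria classically used for small-RNA hairpin calling
(bulge sizes, stem pair counts, free-energy cutoff, hairpin and loop
lengths, and placement/pairing of the mature tag within the stem),
plus a minimum raw-read abundance rule.

The built-in folder is a Nussinov-style dynamic program maximizing a
weighted base-pair score (GC=2, AU=1, GU=1, minimum loop 3); its
negated score is used as the energy. This is a documented stand-in
for a thermodynamic folder: pre-computed dot-bracket structures and
energies (e.g. from RNAfold) can be supplied instead, and the energy
criterion applies to whichever energy is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# folding

_PAIR_SCORES = {
    ("G", "C"): 2.0, ("C", "G"): 2.0,
    ("A", "U"): 1.0, ("U", "A"): 1.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}

MIN_LOOP = 3

_VALID = set("ACGUT")


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def pair_score(a: str, b: str) -> float:
    return _PAIR_SCORES.get((a, b), 0.0)


def fold(sequence: str, min_loop: int = MIN_LOOP) -> tuple[str, float]:
    """Fold *sequence* into a nested structure of maximum weighted pair score.

    Returns ``(dot_bracket, energy)`` where energy is the negated score
    (GC pairs weight 2, AU and GU weight 1), so more negative means a
    more stable structure.

    Raises ``ValueError`` for sequences shorter than 10 nt or containing
    characters outside ACGU/T.
    """
    seq = _rna(sequence)
    n = len(seq)
    if n < 10:
        raise ValueError(f"sequence too short to fold ({n} nt < 10)")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    # pairability/score matrix; S[i, j] (i < j) is 0 where not pairable
    # or where the closed loop would be smaller than min_loop
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    S = np.zeros((n, n))
    for (a, b), w in _PAIR_SCORES.items():
        S[np.ix_(enc == ord(a), enc == ord(b))] = w
    for i in range(n):
        S[i, i:min(n, i + min_loop + 1)] = 0.0

    dp = np.zeros((n, n))
    # diagonals: dp[i, i+l]
    for l in range(min_loop + 1, n):
        i = np.arange(0, n - l)
        j = i + l
        best = np.maximum(dp[i + 1, j], dp[i, j - 1])
        pair = np.where(S[i, j] > 0, dp[i + 1, j - 1] + S[i, j], -np.inf)
        best = np.maximum(best, pair)
        # bifurcation: max over k in (i, j): dp[i, k] + dp[k+1, j]
        for m in range(min_loop + 1, l - min_loop - 1):
            k = i + m
            best = np.maximum(best, dp[i, k] + dp[k + 1, j])
        dp[i, j] = best

    # traceback (deterministic preference: pair > i-unpaired > j-unpaired > split)
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        v = dp[i, j]
        if v == 0:
            continue
        if S[i, j] > 0 and v == dp[i + 1, j - 1] + S[i, j]:
            struct[i], struct[j] = "(", ")"
            stack.append((i + 1, j - 1))
        elif v == dp[i + 1, j]:
            stack.append((i + 1, j))
        elif v == dp[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if v == dp[i, k] + dp[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
            else:  # pragma: no cover - recurrence guarantees a branch
                raise AssertionError("traceback failed")
    return "".join(struct), float(0.0 - dp[0, n - 1])


# ---------------------------------------------------------------------------
# structure parsing

def pair_table(structure: str) -> list[int]:
    """Return partner index per position (-1 if unpaired); errors on
    unbalanced brackets."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[j], pt[i] = i, j
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


@dataclass(frozen=True)
class Bulge:
    """Maximal unpaired run interrupting the stem, between two
    consecutive stem pairs; ``size`` counts nucleotides on both arms."""

    positions5: tuple[int, ...]
    positions3: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.positions5) + len(self.positions3)

    @property
    def asymmetry(self) -> int:
        return abs(len(self.positions5) - len(self.positions3))

    @property
    def biased(self) -> bool:
        return (len(self.positions5) == 0) != (len(self.positions3) == 0)

    @property
    def positions(self) -> tuple[int, ...]:
        return self.positions5 + self.positions3


@dataclass(frozen=True)
class HairpinGeometry:
    pairs: tuple[tuple[int, int], ...]  # outermost first
    loop: tuple[int, int]               # [start, end) of terminal loop
    bulges: tuple[Bulge, ...]

    @property
    def outer_span(self) -> tuple[int, int]:
        i, j = self.pairs[0]
        return i, j

    @property
    def hairpin_len(self) -> int:
        i, j = self.pairs[0]
        return j - i + 1

    @property
    def loop_len(self) -> int:
        return self.loop[1] - self.loop[0]


def parse_hairpin(structure: str) -> HairpinGeometry | None:
    """Decompose a dot-bracket string into stem pairs / terminal loop /
    bulges; ``None`` if the structure is not a single hairpin (no pairs,
    or more than one terminal loop / any multi-branching)."""
    pt = pair_table(structure)
    pairs = [(i, j) for i, j in enumerate(pt) if j > i]
    if not pairs:
        return None
    pairs.sort()
    # single nested chain: each pair strictly inside the previous one
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j2 < j1):
            return None
    a, b = pairs[-1]  # innermost pair closes the terminal loop
    bulges = []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        p5 = tuple(range(i1 + 1, i2))
        p3 = tuple(range(j2 + 1, j1))
        if p5 or p3:
            bulges.append(Bulge(p5, p3))
    return HairpinGeometry(tuple(pairs), (a + 1, b), tuple(bulges))


# ---------------------------------------------------------------------------
# candidates and criteria

@dataclass
class HairpinCandidate:
    """A candidate precursor window with the mature tag placed in it."""

    precursor: str
    mature: str
    mature_start: int
    arm: str                      # "5p" | "3p"
    structure: str | None = None
    energy: float | None = None
    locus: tuple[int, int] | None = None   # genomic, 0-based half-open
    strand: str = "+"

    @property
    def mature_end(self) -> int:
        return self.mature_start + len(self.mature)

    def folded(self, fold_fn=fold) -> "HairpinCandidate":
        if self.structure is not None:
            return self
        structure, energy = fold_fn(self.precursor)
        return replace(self, structure=structure, energy=energy)


CRITERIA = (
    "c1_stem_bulge_len", "c2_stem_pairs", "c3_energy", "c4_hairpin_len",
    "c5_loop_len", "c6_mature_bulge_len", "c7_mature_biased_errors",
    "c8_mature_biased_bulges", "c9_mature_errors", "c10_mature_pairs",
    "c11_mature_in_stem_pct",
)


@dataclass(frozen=True)
class CriteriaThresholds:
    """Inclusive thresholds of the eleven hairpin criteria."""

    max_stem_bulge_len: int = 12        # (1)  nt in one stem bulge      <=
    min_stem_pairs: int = 16            # (2)  base pairs in stem        >=
    max_energy: float = -15.0           # (3)  free energy, kcal/mol     <=
    min_hairpin_len: int = 50           # (4)  stems + terminal loop     >=
    max_loop_len: int = 20              # (5)  terminal loop length      <=
    max_mature_bulge_len: int = 8       # (6)  nt in one mature bulge    <=
    max_mature_biased_errors: int = 4   # (7)  biased errors / bulge     <=
    max_mature_biased_bulges: int = 2   # (8)  biased bulges in mature   <=
    max_mature_errors: int = 7          # (9)  errors in mature region   <=
    min_mature_pairs: int = 12          # (10) base pairs in mature      >=
    min_mature_in_stem_pct: float = 80.0  # (11) % of mature in stem     >=


DEFAULT_THRESHOLDS = CriteriaThresholds()


@dataclass
class CriteriaReport:
    checks: dict[str, bool]
    values: dict[str, float]
    overall: bool
    reason: str | None = None  # set when not evaluable ("not a hairpin")

    @classmethod
    def not_a_hairpin(cls) -> "CriteriaReport":
        return cls({c: False for c in CRITERIA}, {}, False, "not a hairpin")


def evaluate_criteria(candidate: HairpinCandidate,
                      thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
                      ) -> CriteriaReport:
    """Measure the eleven structural features of *candidate* and compare
    each against its inclusive threshold; overall pass is their conjunction.

    Feature definitions: the terminal loop is the unpaired run closed by
    the innermost pair; the stem is everything between the outermost pair
    ends that is not terminal loop; a bulge is a maximal unpaired stem run
    between consecutive pairs, sized over both arms; a biased bulge has
    unpaired nucleotides on one arm only; mature "errors" are unpaired
    mature positions; "biased errors in one bulge" is the largest arm
    asymmetry among bulges touching the mature region.
    """
    if candidate.structure is None or candidate.energy is None:
        raise ValueError("candidate must carry structure and energy; call .folded()")
    if len(candidate.structure) != len(candidate.precursor):
        raise ValueError("structure length != sequence length")
    m0, m1 = candidate.mature_start, candidate.mature_end
    if m0 < 0 or m1 > len(candidate.precursor):
        raise ValueError("mature interval outside precursor")

    geom = parse_hairpin(candidate.structure)
    if geom is None:
        return CriteriaReport.not_a_hairpin()

    lo, hi = geom.outer_span
    loop0, loop1 = geom.loop
    mature = range(m0, m1)
    pt = pair_table(candidate.structure)

    mature_bulges = [b for b in geom.bulges
                     if any(m0 <= p < m1 for p in b.positions)]
    n_mature_pairs = sum(1 for p in mature if pt[p] >= 0)
    n_mature_errors = sum(1 for p in mature if pt[p] < 0)
    in_stem = sum(1 for p in mature
                  if lo <= p <= hi and not (loop0 <= p < loop1))
    values = {
        "c1_stem_bulge_len": max((b.size for b in geom.bulges), default=0),
        "c2_stem_pairs": len(geom.pairs),
        "c3_energy": candidate.energy,
        "c4_hairpin_len": geom.hairpin_len,
        "c5_loop_len": geom.loop_len,
        "c6_mature_bulge_len": max((b.size for b in mature_bulges), default=0),
        "c7_mature_biased_errors": max((b.asymmetry for b in mature_bulges),
                                       default=0),
        "c8_mature_biased_bulges": sum(b.biased for b in mature_bulges),
        "c9_mature_errors": n_mature_errors,
        "c10_mature_pairs": n_mature_pairs,
        "c11_mature_in_stem_pct": 100.0 * in_stem / max(1, m1 - m0),
    }
    t = thresholds
    checks = {
        "c1_stem_bulge_len": values["c1_stem_bulge_len"] <= t.max_stem_bulge_len,
        "c2_stem_pairs": values["c2_stem_pairs"] >= t.min_stem_pairs,
        "c3_energy": values["c3_energy"] <= t.max_energy,
        "c4_hairpin_len": values["c4_hairpin_len"] >= t.min_hairpin_len,
        "c5_loop_len": values["c5_loop_len"] <= t.max_loop_len,
        "c6_mature_bulge_len": values["c6_mature_bulge_len"] <= t.max_mature_bulge_len,
        "c7_mature_biased_errors":
            values["c7_mature_biased_errors"] <= t.max_mature_biased_errors,
        "c8_mature_biased_bulges":
            values["c8_mature_biased_bulges"] <= t.max_mature_biased_bulges,
        "c9_mature_errors": values["c9_mature_errors"] <= t.max_mature_errors,
        "c10_mature_pairs": values["c10_mature_pairs"] >= t.min_mature_pairs,
        "c11_mature_in_stem_pct":
            values["c11_mature_in_stem_pct"] >= t.min_mature_in_stem_pct,
    }
    return CriteriaReport(checks, values, all(checks.values()))


# ---------------------------------------------------------------------------
# window extraction

_COMP = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def extract_candidates(locus: tuple[int, int], strand: str, genome: str,
                       mature: str, flank: int = 100,
                       ) -> list[HairpinCandidate]:
    """Extract the two precursor windows around a tag locus: one with the
    tag as the 5p arm (flank downstream in transcript orientation) and one
    as the 3p arm (flank upstream). Windows truncate at genome ends."""
    start, end = locus
    out = []
    if strand == "+":
        a = genome[start:min(len(genome), end + flank)]
        out.append(HairpinCandidate(a, mature, 0, "5p",
                                    locus=locus, strand=strand))
        b0 = max(0, start - flank)
        b = genome[b0:end]
        out.append(HairpinCandidate(b, mature, start - b0, "3p",
                                    locus=locus, strand=strand))
    else:
        a0 = max(0, start - flank)
        a = revcomp(genome[a0:end])
        out.append(HairpinCandidate(a, mature, 0, "5p",
                                    locus=locus, strand=strand))
        b = revcomp(genome[start:min(len(genome), end + flank)])
        out.append(HairpinCandidate(b, mature, len(b) - len(mature), "3p",
                                    locus=locus, strand=strand))
    return out


# ---------------------------------------------------------------------------
# novel calling

@dataclass
class NovelCall:
    tag: str
    counts: dict[str, int]
    candidate: HairpinCandidate
    report: CriteriaReport


def call_novel(tags: dict[str, dict[str, int]],
               loci: dict[str, list[tuple[tuple[int, int], str]]],
               genome: str,
               min_reads: int = 10,
               thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
               flank: int = 100,
               fold_results: dict[str, tuple[str, float]] | None = None,
               ) -> list[NovelCall]:
    """Call novel miRNAs among unannotated genome-matched tags.

    A tag is called iff its maximum per-library raw read count is at least
    ``min_reads`` and at least one extracted window passes all eleven
    criteria; the reported candidate is the passing one with the lowest
    energy (ties prefer the 5p-arm window).

    *fold_results* optionally maps precursor sequences to externally
    computed ``(dot_bracket, energy)`` records, bypassing the built-in
    folder for those windows.
    """
    calls = []
    for tag, counts in tags.items():
        if max(counts.values(), default=0) < min_reads:
            continue
        passing: list[tuple[HairpinCandidate, CriteriaReport]] = []
        for locus, strand in loci.get(tag, []):
            for cand in extract_candidates(locus, strand, genome, tag, flank):
                if fold_results and cand.precursor in fold_results:
                    s, e = fold_results[cand.precursor]
                    cand = replace(cand, structure=s, energy=e)
                else:
                    cand = cand.folded()
                report = evaluate_criteria(cand, thresholds)
                if report.overall:
                    passing.append((cand, report))
        if passing:
            cand, report = min(
                passing, key=lambda cr: (cr[0].energy, cr[0].arm != "5p"))
            calls.append(NovelCall(tag, dict(counts), cand, report))
    return calls
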