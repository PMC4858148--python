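"""Conserved-miRNA annotation of unique tags and genome matching.

A tag is a conserved miRNA iff it equals a catalog mature sequence
exactly (T and U are interchangeable throughout). Genome matching is
exact substring search on both strands; the per-library total of
genome-matched reads is the normalization denominator used downstream.
Fluid presence uses the strict raw-reads > 10 rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hairpin_discovery import revcomp
from .preprocess import TagCounts

STATUS_CONSERVED = "conserved"
STATUS_EXCLUDED = "excluded"
STATUS_GENOME = "genome_matched_unannotated"
STATUS_UNMATCHED = "unmatched"


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class AnnotatedCounts:
    library_id: str
    mirna_counts: dict[str, int]                 # catalog id -> raw reads
    tag_status: dict[str, str]
    tag_loci: dict[str, list[tuple[tuple[int, int], str]]]
    genome_matched_total: int


def build_catalog_index(catalog: dict[str, str]) -> dict[str, str]:
    """Map mature sequence (DNA alphabet) -> catalog id; errors listing
    any ids that share one mature sequence (the caller must resolve the
    ambiguity, otherwise reads would be double-counted)."""
    index: dict[str, str] = {}
    collisions: dict[str, list[str]] = {}
    for mid, seq in catalog.items():
        key = _dna(seq)
        if key in index:
            collisions.setdefault(key, [index[key]]).append(mid)
        else:
            index[key] = mid
    if collisions:
        msg = "; ".join(f"{seq}: {ids}" for seq, ids in collisions.items())
        raise ValueError(f"duplicate mature sequences in catalog: {msg}")
    return index


def find_loci(genome: str, tag: str) -> list[tuple[tuple[int, int], str]]:
    """All exact occurrences of *tag* on either genome strand, as 0-based
    half-open plus-strand intervals with strand."""
    loci = []
    for query, strand in ((_dna(tag), "+"), (revcomp(_dna(tag)), "-")):
        i = genome.find(query)
        while i != -1:
            loci.append(((i, i + len(query)), strand))
            i = genome.find(query, i + 1)
    return loci


def annotate_tags(tags: TagCounts, catalog: dict[str, str],
                  genome: str | None = None,
                  exclusion: dict[str, str] | None = None) -> AnnotatedCounts:
    """Classify each unique tag as conserved / excluded / genome-matched
    unannotated / unmatched, accumulate raw read counts per catalog
    miRNA, and compute the genome-matched read total.

    A tag matching multiple genomic loci contributes its full read count
    once to the genome-matched total. Tags matching an entry of the
    optional exclusion catalog (e.g. user-supplied rRNA/tRNA sequences)
    never enter novel discovery.
    """
    index = build_catalog_index(catalog)
    excl = {_dna(s) for s in (exclusion or {}).values()}
    mirna_counts = {mid: 0 for mid in catalog}
    status: dict[str, str] = {}
    loci: dict[str, list] = {}
    genome_total = 0
    for tag, n in tags.counts.items():
        key = _dna(tag)
        hits = find_loci(genome, key) if genome is not None else []
        if hits:
            loci[tag] = hits
        if key in index:
            mirna_counts[index[key]] += n
            status[tag] = STATUS_CONSERVED
            # catalog sequences are genomic: count toward the denominator
            # even when no genome was supplied for locus search
            genome_total += n
        elif key in excl:
            status[tag] = STATUS_EXCLUDED
            genome_total += n if hits else 0
        elif hits:
            status[tag] = STATUS_GENOME
            genome_total += n
        else:
            status[tag] = STATUS_UNMATCHED
    return AnnotatedCounts(tags.library_id, mirna_counts, status, loci,
                           genome_total)


def unannotated_tags(libraries: dict[str, tuple[TagCounts, AnnotatedCounts]]
                     ) -> tuple[dict[str, dict[str, int]], dict[str, list]]:
    """Pool genome-matched unannotated tags across libraries for novel
    discovery: per-tag per-library raw read counts plus genomic loci.

    *libraries* maps library id -> (TagCounts, AnnotatedCounts) as
    produced by ``collapse`` and ``annotate_tags`` on the same library.
    """
    counts: dict[str, dict[str, int]] = {}
    loci: dict[str, list] = {}
    for lib, (tags, ann) in libraries.items():
        for tag, st in ann.tag_status.items():
            if st != STATUS_GENOME:
                continue
            counts.setdefault(tag, {})[lib] = tags.counts[tag]
            if tag not in loci:
                loci[tag] = ann.tag_loci[tag]
    for tag, per_lib in counts.items():
        for lib in libraries:
            per_lib.setdefault(lib, libraries[lib][0].counts.get(tag, 0))
    return counts, loci


@dataclass
class PresenceCall:
    mirna: str
    detected_serum: bool
    detected_plasma: bool

    @property
    def presence_class(self) -> str:
        if self.detected_serum and self.detected_plasma:
            return "common"
        if self.detected_serum:
            return "serum_specific"
        if self.detected_plasma:
            return "plasma_specific"
        return "not_detected"


def classify_presence(serum_counts: dict[str, dict[str, int]],
                      plasma_counts: dict[str, dict[str, int]],
                      min_reads: int = 10) -> list[PresenceCall]:
    """Per-miRNA fluid presence: detected in a fluid iff raw reads are
    strictly greater than *min_reads* in at least one condition of that
    fluid; classes common / serum_specific / plasma_specific /
    not_detected follow from the two flags."""
    mirnas = sorted(set(serum_counts) | set(plasma_counts))
    calls = []
    for m in mirnas:
        s = max(serum_counts.get(m, {}).values(), default=0)
        p = max(plasma_counts.get(m, {}).values(), default=0)
        calls.append(PresenceCall(m, s > min_reads, p > min_reads))
    return calls


def count_matrix(annotated: dict[str, AnnotatedCounts]):
    """miRNA x library raw-count table plus the per-library genome-matched
    totals (the DE normalization denominators)."""
    import pandas as pd
    libs = list(annotated)
    mat = pd.DataFrame({lib: pd.Series(a.mirna_counts)
                        for lib, a in annotated.items()}).fillna(0).astype(int)
    totals = pd.Series({lib: annotated[lib].genome_matched_total
                        for lib in libs}, name="genome_matched_total")
    return mat.rename_axis("mirna"), totals
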