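"""Raw small-RNA read cleaning and tag collapsing.

Cleaning removes poor-quality reads, adapter-polluted reads and
inserts outside the 18-35 nt window, in that order: (i) reads whose
mean Phred score is below ``min_mean_q`` are dropped as low quality;
(ii) the 3' adapter is located by exact match of its first
``adapter_probe`` nucleotides (leftmost occurrence) and the read is
trimmed there; (iii) reads with no adapter hit are dropped as adapter
pollution (optionally kept untrimmed), and trimmed inserts shorter
than ``min_len``, longer than ``max_len`` or containing N are dropped.
The per-filter discard tally partitions raw - clean exactly.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DISCARD_CATEGORIES = ("low_quality", "no_adapter", "too_short", "too_long",
                      "contains_n")


@dataclass
class CleanReadSet:
    library_id: str
    sequences: list[str]
    n_raw: int
    tally: dict[str, int] = field(default_factory=dict)

    @property
    def n_clean(self) -> int:
        return len(self.sequences)


@dataclass
class TagCounts:
    library_id: str
    counts: dict[str, int]

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _fastq_records(source):
    """Yield (title, seq, qual) from a path, handle, or FASTQ text."""
    if isinstance(source, str) and (not source or source.startswith("@")
                                    or "\n" in source):
        source = io.StringIO(source)
    if isinstance(source, str):
        with open(source) as fh:
            yield from FastqGeneralIterator(fh)
        return
    if hasattr(source, "read"):
        yield from FastqGeneralIterator(source)
        return
    yield from source  # already an iterable of record tuples


def clean_reads(source, adapter: str, library_id: str = "lib",
                min_mean_q: float = 20.0, min_len: int = 18,
                max_len: int = 35, keep_unmatched_adapter: bool = False,
                adapter_probe: int = 8) -> CleanReadSet:
    """Clean raw FASTQ reads; see module docstring for the filter chain.

    Raises ``ValueError`` (naming the record index) on malformed records
    where sequence and quality lengths disagree, and if *adapter* is empty.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    probe = adapter[:adapter_probe].upper()
    min_q_sum_cache: dict[int, float] = {}
    kept: list[str] = []
    tally = Counter()
    n_raw = 0
    records = iter(_fastq_records(source))
    while True:
        try:
            _title, seq, qual = next(records)
        except StopIteration:
            break
        except ValueError as err:  # parser-level breakage (index = n_raw)
            raise ValueError(f"malformed FASTQ record {n_raw}: {err}") from err
        idx, n_raw = n_raw, n_raw + 1
        if len(seq) != len(qual):
            raise ValueError(
                f"malformed FASTQ record {idx}: sequence length {len(seq)} "
                f"!= quality length {len(qual)}")
        if not seq:
            raise ValueError(f"malformed FASTQ record {idx}: empty sequence")
        # mean Phred = mean(ord - 33); compare against a cached threshold sum
        thr = min_q_sum_cache.get(len(qual))
        if thr is None:
            thr = (min_mean_q + 33.0) * len(qual)
            min_q_sum_cache[len(qual)] = thr
        if sum(qual.encode()) < thr:
            tally["low_quality"] += 1
            continue
        seq = seq.upper()
        hit = seq.find(probe)
        if hit == -1:
            if not keep_unmatched_adapter:
                tally["no_adapter"] += 1
                continue
            insert = seq
        else:
            insert = seq[:hit]
        if len(insert) < min_len:
            tally["too_short"] += 1
        elif len(insert) > max_len:
            tally["too_long"] += 1
        elif "N" in insert:
            tally["contains_n"] += 1
        else:
            kept.append(insert)
    tally = {k: tally.get(k, 0) for k in DISCARD_CATEGORIES}
    return CleanReadSet(library_id, kept, n_raw, tally)


def collapse(clean: CleanReadSet) -> TagCounts:
    """Collapse identical clean reads into unique tags with read counts;
    counts conserve the clean total."""
    return TagCounts(clean.library_id, dict(Counter(clean.sequences)))


def length_histogram(clean: CleanReadSet) -> dict[int, float]:
    """Read-length distribution of the clean set as percentages
    (summing to 100); errors on an empty set."""
    if not clean.sequences:
        raise ValueError("length histogram undefined for an empty read set")
    c = Counter(len(s) for s in clean.sequences)
    n = clean.n_clean
    return {length: 100.0 * k / n for length, k in sorted(c.items())}


def summary_frame(clean: CleanReadSet, tags: TagCounts):
    import pandas as pd
    row = {"library": clean.library_id, "raw": clean.n_raw,
           "clean": clean.n_clean, "n_unique": tags.n_unique}
    row.update(clean.tally)
    return pd.DataFrame([row])
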