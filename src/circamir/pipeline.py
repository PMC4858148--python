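"""End-to-end composition of the pipeline stages.

Convenience wrappers that run clean -> collapse -> annotate on each
library, assemble the count matrix with its genome-matched
denominators, run the BO vs AO tests per fluid, and call novel miRNAs
from the pooled unannotated tags. Each stage remains individually
usable; these functions only wire them together.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import annotate, diff_expression, hairpin_discovery, preprocess
from .synthetic_data import Reference, SimulationConfig


@dataclass
class LibraryResult:
    clean: preprocess.CleanReadSet
    tags: preprocess.TagCounts
    annotated: annotate.AnnotatedCounts


def process_library(fastq_source, library_id: str, adapter: str,
                    catalog: dict[str, str], genome: str | None = None,
                    exclusion: dict[str, str] | None = None,
                    **clean_kwargs) -> LibraryResult:
    clean = preprocess.clean_reads(fastq_source, adapter,
                                   library_id=library_id, **clean_kwargs)
    tags = preprocess.collapse(clean)
    ann = annotate.annotate_tags(tags, catalog, genome, exclusion)
    return LibraryResult(clean, tags, ann)


def de_between_conditions(results: dict[str, LibraryResult], fluid: str,
                          screen: diff_expression.ScreenConfig | None = None,
                          bh_correct: bool = False) -> pd.DataFrame:
    """BO vs AO differential expression for one fluid from processed
    libraries named ``{fluid}_BO`` / ``{fluid}_AO``."""
    bo, ao = results[f"{fluid}_BO"], results[f"{fluid}_AO"]
    counts = pd.DataFrame({
        "count_bo": pd.Series(bo.annotated.mirna_counts),
        "count_ao": pd.Series(ao.annotated.mirna_counts),
    }).fillna(0).astype(int)
    return diff_expression.de_table(
        counts, bo.annotated.genome_matched_total,
        ao.annotated.genome_matched_total, screen, bh_correct)


def discover_novel(results: dict[str, LibraryResult], genome: str,
                   min_reads: int = 10, **kwargs):
    """Pool unannotated genome-matched tags across libraries and call
    novel miRNAs."""
    pooled = {lib: (r.tags, r.annotated) for lib, r in results.items()}
    tag_counts, tag_loci = annotate.unannotated_tags(pooled)
    return hairpin_discovery.call_novel(tag_counts, tag_loci, genome,
                                        min_reads=min_reads, **kwargs)


def run_synthetic(config: SimulationConfig,
                  libraries=("serum_BO", "serum_AO", "plasma_BO", "plasma_AO"),
                  ) -> tuple[Reference, dict[str, LibraryResult], "pd.DataFrame"]:
    """Simulate reference + reads and push every library through
    cleaning, collapsing and annotation. Returns the reference, the
    per-library results and the table of true per-library counts."""
    from .synthetic_data import make_reference, simulate_reads
    ref = make_reference(config)
    reads = simulate_reads(ref, config, libraries)
    results = {
        lib: process_library(reads.fastq[lib], lib, config.adapter,
                             ref.catalog, ref.genome)
        for lib in libraries
    }
    return ref, results, reads.true_counts
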