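"""Ground-truth synthetic inputs for the serum/plasma small-RNA pipeline.

Emulates the study design the pipeline targets: two pubertal stages
(BO = before onset, AO = after onset) sampled in two fluids (serum,
plasma), a catalog of conserved mature miRNAs planted in hairpin
context in a synthetic genome, planted novel precursors that satisfy
the eleven structural hairpin criteria by construction, decoy
precursors that each violate exactly one recorded criterion,
adapter-contaminated and sub-18-nt junk reads, and weekly (10-16 wk)
Cq profiles with stage-onset temporal patterns.

Everything is deterministic given ``SimulationConfig.seed``.

Design notes (see docs/methods.md): planted novel/decoy stems are
G/C-only with A-only loops and A-only spacers so their base-pairing
optimum is unique inside any extraction window; read counts follow a
negative-binomial-like Gamma-multinomial model so per-library totals
are conserved exactly; the Cq scale is exact (one cycle = one
expression doubling) with additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hairpin_discovery as hp

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
LIBRARIES = ("serum_BO", "serum_AO", "plasma_BO", "plasma_AO")
CONDITIONS = ("BO", "AO")
FLUIDS = ("serum", "plasma")
QPCR_WEEKS = (10, 11, 12, 13, 14, 15, 16)

# AO/BO fold-changes cycled over conserved miRNAs; spans the 0.09-16.5
# range reported for strongly changed circulating miRNAs at puberty onset
FOLD_CHANGE_CYCLE = (16.5, 5.8, 3.8, 2.0, 1.0, 1.0, 0.5, 0.24, 0.15, 0.09)

# the nine RT-qPCR candidates: seven with the sustained-onset ("panel")
# profile and two with the transient rise-then-fall profile
DEFAULT_QPCR_PATTERNS = {
    "gga-miR-29c": "panel", "gga-miR-217": "panel", "gga-miR-375": "panel",
    "gga-miR-215": "panel", "gga-miR-19b": "panel", "gga-miR-133a": "panel",
    "gga-let-7a": "panel",
    "gga-miR-155": "transient", "gga-miR-9": "transient",
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_conserved: int = 20
    n_novel_true: int = 5
    n_novel_decoy: int = 5
    depth_per_library: int = 1_000_000
    length_mode_range: tuple[int, int] = (20, 24)
    junk_fraction: float = 0.1
    dispersion: float = 0.1
    # abundance weights (nominal RPM scale, log-uniform draws): stage-
    # changed miRNAs and novel hairpins sit at moderate abundance while
    # flat background miRNAs dominate the library, as the most abundant
    # circulating miRNAs do in real serum; the dominant flat background
    # keeps the compositional bias of RPM ratios negligible, so planted
    # fold-changes are recoverable from normalized counts
    changed_rpm_range: tuple[float, float] = (50.0, 500.0)
    background_rpm_range: tuple[float, float] = (1_000.0, 100_000.0)
    n_changed: int | None = None            # default: n_conserved // 2
    fold_changes: dict[str, float] | None = None
    genome_size: int = 100_000
    spacer: int = 200
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    flank: int = 100
    qpcr_patterns: dict[str, str] | None = None
    qpcr_noise_sd: float = 0.15
    qpcr_step_cq: float = 2.0
    qpcr_replicates: int = 6

    def __post_init__(self):
        if not 0.0 <= self.junk_fraction <= 1.0:
            raise ValueError("junk_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.fold_changes is not None:
            bad = {k: v for k, v in self.fold_changes.items() if v <= 0}
            if bad:
                raise ValueError(f"fold_changes must be strictly positive: {bad}")


@dataclass
class TruthRecord:
    mirna: str
    kind: str                      # conserved | novel_true | novel_decoy
    mature: str
    locus: tuple[int, int]         # genomic interval of the mature tag
    strand: str
    base_rpm: float
    fold_change: float
    compliant: bool
    violated_criterion: str | None = None
    qpcr_pattern: str | None = None


@dataclass
class Reference:
    genome: str
    catalog: dict[str, str]        # conserved id -> mature sequence (RNA)
    truth: list[TruthRecord]

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.mirna: t for t in self.truth}


class ReferenceGenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# hairpin construction

@dataclass
class BuiltHairpin:
    sequence: str
    structure: str
    mature_start: int
    mature_len: int

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_start:self.mature_start + self.mature_len]


def build_hairpin(elements, loop_len: int, mature_start: int, mature_len: int,
                  rng: np.random.Generator | None = None) -> BuiltHairpin:
    """Assemble a hairpin from stem *elements* listed outermost-first.

    Elements: ``("pair", n)`` adds n G/C base pairs (5' base drawn at
    random, complement on the 3' arm), ``("bulge", k5, k3)`` adds k5/k3
    unpaired A's on the respective arms, ``("ext5", k)`` / ``("ext3", k)``
    add unpaired A flanks outside the outermost pair. The terminal loop
    is ``loop_len`` A's. A's never pair with G/C, so the built structure
    is the unique pairing optimum of the built sequence.
    """
    rng = rng or np.random.default_rng(0)
    s5, s3, d5, d3 = [], [], [], []
    ext5 = ext3 = 0
    for el in elements:
        if el[0] == "pair":
            n = el[1]
            bases = rng.choice(list("GC"), size=n)
            s5.append("".join(bases))
            s3.append("".join("C" if b == "G" else "G" for b in bases[::-1]))
            d5.append("(" * n)
            d3.append(")" * n)
        elif el[0] == "bulge":
            k5, k3 = el[1], el[2]
            s5.append("A" * k5)
            s3.append("A" * k3)
            d5.append("." * k5)
            d3.append("." * k3)
        elif el[0] == "ext5":
            ext5 += el[1]
        elif el[0] == "ext3":
            ext3 += el[1]
        else:
            raise ValueError(f"unknown element {el!r}")
    seq = ("A" * ext5 + "".join(s5) + "A" * loop_len
           + "".join(reversed(s3)) + "A" * ext3)
    struct = ("." * ext5 + "".join(d5) + "." * loop_len
              + "".join(reversed(d3)) + "." * ext3)
    return BuiltHairpin(seq, struct, mature_start, mature_len)


def compliant_hairpin(rng: np.random.Generator) -> BuiltHairpin:
    """A precursor passing all eleven criteria with margin >= 2 everywhere:
    25 G/C stem pairs, 8-nt loop, 22-nt fully paired mature on the 5p arm."""
    return build_hairpin([("pair", 25)], loop_len=8,
                         mature_start=0, mature_len=22, rng=rng)


# each decoy kind violates exactly the named criterion, by >= 2 units,
# while passing the other ten with slack (counts verified in tests and
# re-verified structurally at generation time)
DECOY_SPECS: dict[str, tuple[list, int, int, int]] = {
    "c1_stem_bulge_len": ([("pair", 18), ("bulge", 8, 8), ("pair", 4)], 8, 0, 18),
    "c2_stem_pairs": ([("pair", 7), ("bulge", 3, 3), ("pair", 7)], 18, 0, 20),
    "c4_hairpin_len": ([("pair", 17)], 10, 0, 18),
    "c5_loop_len": ([("pair", 20)], 23, 0, 20),
    "c6_mature_bulge_len": ([("pair", 8), ("bulge", 5, 5), ("pair", 14)], 8, 0, 22),
    "c7_mature_biased_errors": ([("pair", 8), ("bulge", 6, 0), ("pair", 10)], 10, 0, 22),
    "c8_mature_biased_bulges":
        ([("pair", 4), ("bulge", 1, 0)] * 4 + [("pair", 4)], 10, 0, 24),
    "c11_mature_in_stem_pct": ([("ext5", 5), ("pair", 20)], 12, 0, 20),
}


def decoy_hairpin(kind: str, rng: np.random.Generator) -> BuiltHairpin:
    elements, loop_len, m0, mlen = DECOY_SPECS[kind]
    return build_hairpin(elements, loop_len, m0, mlen, rng=rng)


# ---------------------------------------------------------------------------
# reference assembly

_CONSERVED_LENGTH_WEIGHTS = {20: 1, 21: 2, 22: 4, 23: 2, 24: 1}


def _random_mature(rng: np.random.Generator) -> str:
    lengths = list(_CONSERVED_LENGTH_WEIGHTS)
    w = np.array(list(_CONSERVED_LENGTH_WEIGHTS.values()), dtype=float)
    n = int(rng.choice(lengths, p=w / w.sum()))
    return "".join(rng.choice(list("ACGT"), size=n))


def _conserved_hairpin(mature: str, rng: np.random.Generator) -> tuple[str, int]:
    """Mature embedded in a simple stem-loop context (mature / 8-nt loop /
    reverse complement); returns (precursor, mature offset)."""
    del rng
    return mature + "ACAACTTA"[:8] + hp.revcomp(mature), 0


def _default_fold_changes(ids: list[str], n_changed: int) -> dict[str, float]:
    fcs = {m: 1.0 for m in ids}
    fcs.update({m: FOLD_CHANGE_CYCLE[i % len(FOLD_CHANGE_CYCLE)]
                for i, m in enumerate(ids[:n_changed])})
    return fcs


def _occurrences(genome: str, tag: str) -> list[int]:
    out, i = [], genome.find(tag)
    while i != -1:
        out.append(i)
        i = genome.find(tag, i + 1)
    return out


def make_reference(config: SimulationConfig, max_retries: int = 50) -> Reference:
    """Build the synthetic genome, conserved-miRNA catalog and truth table.

    Every planted novel precursor is verified to pass (and every decoy to
    fail, on exactly its recorded criterion) a full extract -> fold ->
    evaluate round trip in its final genomic context; entities whose
    random draw breaks that (or collides with another planted sequence)
    are regenerated, with a bounded retry budget.
    """
    rng = np.random.default_rng([config.seed, 0])
    # per-side inter-locus spacer; inert (non-pairing) in the transcript
    # orientation of each planted hairpin: A around plus-strand plants,
    # T around minus-strand plants (revcomp(T) = A in extraction windows)
    side = max(config.spacer // 2, config.flank)

    entities = []  # (id, kind, precursor, mature_offset_in_precursor,
    #                mature_len, strand, compliant, violated)
    for i in range(config.n_conserved):
        for attempt in range(max_retries):
            mature = _random_mature(rng)
            if all(mature != e[2][e[3]:e[3] + e[4]] for e in entities):
                break
        else:
            raise ReferenceGenerationError("could not draw a unique mature")
        prec, off = _conserved_hairpin(mature, rng)
        strand = "+" if i % 4 else "-"
        entities.append((f"gga-miR-sim{i + 1}", "conserved", prec, off,
                         len(mature), strand, True, None))
    for i in range(config.n_novel_true):
        bh = compliant_hairpin(rng)
        strand = "+" if i % 2 == 0 else "-"
        entities.append((f"novel-{i + 1}", "novel_true", bh.sequence,
                         bh.mature_start, bh.mature_len, strand, True, None))
    decoy_kinds = list(DECOY_SPECS)
    for i in range(config.n_novel_decoy):
        kind = decoy_kinds[i % len(decoy_kinds)]
        bh = decoy_hairpin(kind, rng)
        strand = "+" if i % 2 == 0 else "-"
        entities.append((f"decoy-{i + 1}", "novel_decoy", bh.sequence,
                         bh.mature_start, bh.mature_len, strand, False, kind))

    for attempt in range(max_retries):
        genome_parts, layout = [], []
        pos = 0
        for ent in entities:
            _, _, prec, off, mlen, strand, _, _ = ent
            seg = prec if strand == "+" else hp.revcomp(prec)
            pad = ("A" if strand == "+" else "T") * side
            genome_parts += [pad, seg, pad]
            pos += side
            if strand == "+":
                locus = (pos + off, pos + off + mlen)
            else:
                locus = (pos + len(prec) - off - mlen, pos + len(prec) - off)
            layout.append((ent, (pos, pos + len(prec)), locus))
            pos += len(prec) + side
        genome = "".join(genome_parts)
        if len(genome) < config.genome_size:
            genome += "A" * (config.genome_size - len(genome))

        bad = _verify_layout(genome, layout, config)
        if bad is None:
            break
        # regenerate the offending entity with fresh random draws
        idx = next(i for i, e in enumerate(entities) if e[0] == bad)
        eid, kind, _, _, _, strand, compliant, violated = entities[idx]
        if kind == "conserved":
            mature = _random_mature(rng)
            prec, off = _conserved_hairpin(mature, rng)
            entities[idx] = (eid, kind, prec, off, len(mature), strand,
                             compliant, violated)
        elif kind == "novel_true":
            bh = compliant_hairpin(rng)
            entities[idx] = (eid, kind, bh.sequence, bh.mature_start,
                             bh.mature_len, strand, compliant, violated)
        else:
            bh = decoy_hairpin(violated, rng)
            entities[idx] = (eid, kind, bh.sequence, bh.mature_start,
                             bh.mature_len, strand, compliant, violated)
    else:
        raise ReferenceGenerationError(
            f"reference verification failed after {max_retries} retries")

    truth, catalog = [], {}
    ids = [e[0] for e in entities if e[1] == "conserved"]
    n_changed = (config.n_conserved // 2 if config.n_changed is None
                 else config.n_changed)
    fcs = _default_fold_changes(ids, n_changed)
    if config.fold_changes:
        fcs.update(config.fold_changes)
    changed_ids = set(ids[:n_changed])
    for ent, _, locus in layout:
        eid, kind, prec, off, mlen, strand, compliant, violated = ent
        mature = prec[off:off + mlen]
        if kind == "conserved" and eid not in changed_ids:
            rpm_lo, rpm_hi = config.background_rpm_range
        else:
            rpm_lo, rpm_hi = config.changed_rpm_range
        base_rpm = float(np.exp(rng.uniform(math.log(rpm_lo), math.log(rpm_hi))))
        fc = fcs.get(eid, 1.0)
        truth.append(TruthRecord(eid, kind, mature, locus, strand, base_rpm,
                                 fc, compliant, violated))
        if kind == "conserved":
            catalog[eid] = mature.replace("T", "U")
    return Reference(genome, catalog, truth)


def _verify_layout(genome: str, layout, config: SimulationConfig) -> str | None:
    """Check collisions and the novel/decoy fold round trip; return the id
    of the first offending entity, or None if the layout is valid."""
    footprints = {ent[0]: span for ent, span, _ in layout}
    for ent, span, locus in layout:
        eid, kind, prec, off, mlen, strand, compliant, violated = ent
        mature = prec[off:off + mlen]
        occ = [(p, "+") for p in _occurrences(genome, mature)]
        occ += [(p, "-") for p in _occurrences(genome, hp.revcomp(mature))]
        for p, _ in occ:
            inside_own = span[0] <= p and p + mlen <= span[1]
            if not inside_own:
                return eid
        if kind == "conserved":
            continue
        cands = [c.folded() for c in hp.extract_candidates(
            locus, strand, genome, mature, config.flank)]
        reports = [hp.evaluate_criteria(c) for c in cands]
        if kind == "novel_true":
            if not any(r.overall for r in reports):
                return eid
        else:
            if any(r.overall for r in reports):
                return eid
            planted = next(r for c, r in zip(cands, reports) if c.arm == "5p")
            failed = {k for k, ok in planted.checks.items() if not ok}
            if planted.reason is not None or failed != {violated}:
                return eid
    return None


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class SimulatedReads:
    fastq: dict[str, str]               # library id -> FASTQ text
    true_counts: pd.DataFrame           # index miRNA id, columns library ids


def simulate_counts(reference: Reference, config: SimulationConfig,
                    rng: np.random.Generator,
                    libraries=LIBRARIES) -> pd.DataFrame:
    """Draw per-library species counts: Gamma(1/dispersion) intensities
    around base abundance x fold-change (AO only), then a multinomial of
    depth - junk reads, so counts conserve the per-library total exactly
    while carrying negative-binomial-like overdispersion."""
    ids = [t.mirna for t in reference.truth]
    base = np.array([t.base_rpm for t in reference.truth])
    fc = np.array([t.fold_change for t in reference.truth])
    n_junk = round(config.depth_per_library * config.junk_fraction)
    n_real = config.depth_per_library - n_junk
    if n_real < len(ids):
        raise ValueError(
            f"depth {config.depth_per_library} too small for {len(ids)} species")
    out = {}
    for lib in libraries:
        mean = base * fc if lib.endswith("AO") else base
        if config.dispersion > 0:
            lam = rng.gamma(1.0 / config.dispersion, mean * config.dispersion)
            lam = np.where(lam <= 0, 1e-12, lam)
        else:
            lam = mean
        out[lib] = rng.multinomial(n_real, lam / lam.sum())
    return pd.DataFrame(out, index=ids)


def simulate_reads(reference: Reference, config: SimulationConfig,
                   libraries=LIBRARIES) -> SimulatedReads:
    """Generate one FASTQ per library (Phred+33, fixed read length):
    species reads are mature + 3' adapter (+A padding), junk is half
    adapter-dimer reads and half 10-17 nt fragments, per-library totals
    equal ``depth_per_library``, identical seeds give identical bytes."""
    rng = np.random.default_rng([config.seed, 1])
    counts = simulate_counts(reference, config, rng, libraries)
    rl = config.read_length
    n_junk = round(config.depth_per_library * config.junk_fraction)
    n_dimer = n_junk // 2
    n_frag = n_junk - n_dimer
    species_reads = {
        t.mirna: (t.mature + config.adapter + "A" * rl)[:rl]
        for t in reference.truth
    }
    dimer_read = (config.adapter + "A" * rl)[:rl]
    qual = "I" * rl
    fastq = {}
    for lib in libraries:
        seqs = np.repeat(
            np.array([species_reads[i] for i in counts.index], dtype=object),
            counts[lib].to_numpy(),
        )
        frag_lens = rng.integers(10, 18, size=n_frag)
        frags = np.array(
            ["".join(rng.choice(list("ACGT"), size=k)) for k in frag_lens],
            dtype=object,
        )
        frags = np.array([(f + config.adapter + "A" * rl)[:rl] for f in frags],
                         dtype=object)
        reads = np.concatenate([
            seqs,
            np.array([dimer_read] * n_dimer, dtype=object),
            frags,
        ])
        reads = reads[rng.permutation(len(reads))]
        fastq[lib] = "\n".join(
            f"@{lib}_{i}\n{s}\n+\n{qual}" for i, s in enumerate(reads)
        ) + "\n"
    return SimulatedReads(fastq, counts)


# ---------------------------------------------------------------------------
# qPCR simulation

def simulate_qpcr(config: SimulationConfig, weeks=QPCR_WEEKS,
                  replicates: int | None = None,
                  reference_id: str = "U6") -> pd.DataFrame:
    """Weekly Cq table for the candidate panel plus the U6 reference.

    Patterns (Cq scale, one cycle per expression doubling): "panel" =
    flat weeks 10-12, Cq drop of ``qpcr_step_cq`` at week 13 sustained
    through 16; "transient" = same drop at 13-14, back to the early
    level at 15-16; "flat" = constant. U6 is constant up to noise.
    """
    replicates = config.qpcr_replicates if replicates is None else replicates
    if replicates < 2:
        raise ValueError("at least 2 replicates required (ANOVA undefined)")
    patterns = config.qpcr_patterns or DEFAULT_QPCR_PATTERNS
    onset = 13
    rng = np.random.default_rng([config.seed, 2])
    rows = []
    base_cq = {m: float(rng.uniform(24.0, 28.0)) for m in patterns}
    for mirna, pat in patterns.items():
        for w in weeks:
            if pat == "panel":
                mu = base_cq[mirna] - (config.qpcr_step_cq if w >= onset else 0.0)
            elif pat == "transient":
                mu = base_cq[mirna] - (
                    config.qpcr_step_cq if w in (onset, onset + 1) else 0.0)
            elif pat == "flat":
                mu = base_cq[mirna]
            else:
                raise ValueError(f"unknown qPCR pattern {pat!r}")
            for r in range(replicates):
                rows.append((mirna, w, r,
                             mu + rng.normal(0.0, config.qpcr_noise_sd)))
    for w in weeks:
        for r in range(replicates):
            rows.append((reference_id, w, r,
                         15.0 + rng.normal(0.0, config.qpcr_noise_sd)))
    return pd.DataFrame(rows, columns=["mirna", "stage_week", "replicate", "cq"])


# ---------------------------------------------------------------------------
# on-disk outputs

def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def truth_frame(reference: Reference) -> pd.DataFrame:
    return pd.DataFrame([
        {"mirna": t.mirna, "kind": t.kind, "mature": t.mature,
         "start": t.locus[0], "end": t.locus[1], "strand": t.strand,
         "base_rpm": t.base_rpm, "fold_change": t.fold_change,
         "compliant": t.compliant,
         "violated_criterion": t.violated_criterion or ""}
        for t in reference.truth
    ])


def write_outputs(outdir, reference: Reference, reads: SimulatedReads,
                  cq: pd.DataFrame) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", {"chr_sim": reference.genome})
    write_fasta(outdir / "catalog.fa", reference.catalog)
    truth_frame(reference).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    reads.true_counts.rename_axis("mirna").to_csv(
        outdir / "true_counts.tsv", sep="\t")
    for lib, text in reads.fastq.items():
        (outdir / f"{lib}.fastq").write_text(text)
    cq.to_csv(outdir / "cq.tsv", sep="\t", index=False)
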