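# Methods

`circamir` implements the computational arm of a circulating small-RNA
biomarker study in chicken: serum and plasma small-RNA libraries from
hens before (BO) and after (AO) puberty onset are cleaned, annotated
against a mature-miRNA catalog, screened for novel miRNA hairpins,
tested for BO-vs-AO differential expression, and followed up with
RT-qPCR relative quantification across weekly stages (10–16 weeks) to
select a temporal biomarker panel. Because the study design pools
animals into one library per condition, the statistics are count-based
(Fisher / chi-square on sequencing depth), not replicate-based.

## Read cleaning (`preprocess`)

Reads are dropped as *low quality* when their mean Phred score is below
20 (configurable; base-calling pipelines vary and the cleaning
criterion is deliberately explicit). The 3' adapter is located by exact
match of its first 8 nt, leftmost occurrence; the insert is the prefix
before the hit. Reads with no adapter hit are counted as *adapter
pollution* and discarded by default (an option keeps them untrimmed,
for libraries where inserts can span the full read). Inserts shorter
than 18 nt (this includes adapter dimers, which trim to length 0),
longer than 35 nt, or containing N are discarded. The per-filter tally
partitions `raw − clean` exactly, and the 18–35 nt window mirrors the
gel-excision range of the library protocol. No mismatch-tolerant or
quality-aware trimming is attempted: at desk scale the exact-prefix
rule is transparent and testable, and the simulator writes exact
adapters.

Unique-tag collapsing is an exact count; the length histogram is
reported in percent of clean reads.

## Annotation (`annotate`)

A tag is a **conserved miRNA** iff it equals a catalog mature sequence
exactly, with T/U treated as identical everywhere. Catalogs with two
ids sharing one mature sequence are rejected rather than silently
double-counted. Genome matching is exact substring search on both
strands; a tag matching several loci still contributes its read count
once to the per-library **genome-matched total**, which is the
normalization denominator downstream (how multi-mappers should enter
that denominator is genuinely open; counting reads once is the choice
here and is configurable by pre-filtering). The rRNA/tRNA/sn(o)RNA
databases used by vendor pipelines are replaced by an optional
user-supplied exclusion FASTA; excluded tags never enter novel
discovery. Fluid presence uses the strict rule raw reads > 10 in at
least one condition of a fluid; the boundary (10 reads exactly →
not detected) is asserted in tests.

## Novel miRNA discovery (`hairpin_discovery`)

Candidate precursors are extracted around each unannotated
genome-matched tag locus: a window with the tag as the 5p arm
(`[start, end + flank)`) and one with the tag as the 3p arm
(`[start − flank, end)`), flank 100 nt, reverse-complemented for
minus-strand loci. The flank bounds precursor length comfortably above
the ≥ 50 nt hairpin criterion; both arms are tried because the arm the
original pipeline required is unknown.

**Folding.** The built-in folder is a Nussinov-style dynamic program
maximizing a weighted pair score (GC = 2, AU = 1, GU = 1; minimum loop
3), with deterministic traceback; its negated score serves as the
energy. This is a documented stand-in for a thermodynamic
nearest-neighbor folder, and the module accepts precomputed
dot-bracket/energy records (e.g. RNAfold output) instead; the −15
kcal/mol energy criterion applies to whichever energy is supplied.
With the built-in score the −15 cutoff is a calibrated stand-in: any
16-pair stem already scores ≤ −16, so the cutoff mainly rejects
poorly paired windows.

**Criteria.** The eleven structural criteria, all inclusive: stem
bulge ≤ 12 nt; stem pairs ≥ 16; energy ≤ −15; hairpin length
(outermost-pair span: both stems + terminal loop) ≥ 50; terminal loop
≤ 20; mature-region bulge ≤ 8 nt; biased errors in one mature bulge
≤ 4; biased bulges in the mature region ≤ 2; mature errors (unpaired
mature positions) ≤ 7; mature pairs ≥ 12; mature-in-stem ≥ 80%.
Feature definitions: the terminal loop is the unpaired run closed by
the innermost pair; a bulge is a maximal unpaired run between
consecutive stem pairs, sized over both arms; a biased bulge has
unpaired nucleotides on one arm only; "biased errors in one bulge" —
undefined in the source material — is taken as the largest arm
asymmetry among mature-region bulges, consistent with vendor-style
criteria, and is configurable. Structures with more than one terminal
loop are rejected as "not a hairpin" rather than re-folded under
constraints. A tag is called novel iff some window passes all eleven
criteria and its raw reads reach 10 in at least one library; among
passing windows the lowest-energy one is reported (ties prefer 5p).

## Differential expression (`diff_expression`)

RPM = 10⁶ × count / genome-matched total. Each miRNA's 2×2 table
(count vs. remaining genome-matched reads, BO vs. AO) is tested with a
two-sided Fisher exact test — implemented as a vectorized enumeration
of the hypergeometric support with a 1 + 1e-12 tie guard so that
exact probability ties are handled identically to rational
arithmetic — and with Pearson's chi-square (1 df, no continuity
correction) as companion. Fisher gates the DE flag (alpha 0.05); no
multiple-testing correction by default, mirroring the study design,
with Benjamini–Hochberg available behind a flag (the corrected DE set
is provably a subset of the uncorrected one). Fold-change is
RPM_AO / RPM_BO with a 0.5-read pseudocount in both conditions when
either count is zero (ratio reporting only — never the tests). Output
files round fold-change and log2 to 2 decimals; screening always uses
full precision. The candidate screen keeps DE miRNAs with
|log2FC| ≥ 1.0; RT-qPCR candidate selection additionally requires raw
reads ≥ 40 in some condition and an annotation term among the
reproduction-event keywords (gonad development, muscle development,
glucose/fat/insulin metabolism, sex hormone synthesis and secretion).

Chi-square tracks Fisher within ~10% for moderate p with all cells
≥ 50, but the normal approximation drifts beyond that in the far tail
(p ≲ 0.01); tests assert relative agreement only where the asymptotics
support it and order-of-magnitude agreement in the tail.

## RT-qPCR (`qpcr`)

ΔCq = Cq_miRNA − Cq_U6, using the stage-mean U6 (plate pairing is
unknown; per-replicate pairing is available). Relative level per stage
is 2^−ΔΔCq against the week-10 baseline (the earliest sampled stage;
the original normalization stage is unstated). Levels are invariant
under any constant Cq shift. Reference validation requires every
pairwise stage-mean U6 difference < 0.6 cycles. Stage comparisons use
one-way fixed-effects ANOVA (two-group ANOVA ≡ t², used for adjacent
weeks); identically constant data give p = 1 by convention.

**Panel rule.** A candidate is a biomarker iff (i) *early stability*:
no significant expression change across weeks 10–12; (ii) *onset
jump*: the 12→13 week comparison is significant at 0.01 with rising
expression; (iii) *sustained*: no week after 13 falls significantly
below the week-13 level ("until first egg" is mapped to the last
sampled week, 16). Demoting calls (early instability, post-onset
drops) additionally require a minimum effect of 1 Cq (2-fold): with a
truly flat profile the ANOVA p-value is uniform, so a pure p ≥ 0.05
stability rule would spuriously reject ~5% of genuinely stable
candidates per miRNA and a nine-member panel would essentially never
be recovered exactly; requiring significance *and* a ≥ 2-fold effect
makes the rule a test of meaningful change, which is what the
published wording describes. `min_effect_cq=0` restores the literal
significance-only rule. The ambiguous "relatively low and stable
(P < 0.05) in early period" is read as a stability statement by
default; a `low_level` mode implements the alternative reading (early
expression significantly below post-onset).

## Synthetic data (`synthetic_data`)

The generator's defaults are the study conditions at desk scale: four
libraries (serum/plasma × BO/AO), 10⁶ reads each, 10% junk (half
adapter dimers, half 10–17 nt fragments — exercising both cleaning
filters), insert lengths 20–24 nt peaking at 22, planted AO/BO
fold-changes cycling through 16.5 … 0.09 (the published extreme
range), and Cq profiles with a 2-cycle onset step at week 13, noise
sd 0.15 (0.2 in the stress fixtures), 6 replicates.

*Counts.* Negative-binomial-like dispersion (default 0.1; the pooled
design gives no replicate variance estimate, so this is an explicit
choice) is realized as per-species Gamma(1/φ, φμ) intensities followed
by one multinomial draw of depth − junk reads, so per-library totals
are conserved exactly while marginal counts are overdispersed.
Fold-changes are planted on half the conserved miRNAs at moderate
abundance (50–500 weight units) against flat high-abundance background
miRNAs (10³–10⁵), the way a few stable species dominate real serum
libraries; the dominant flat background keeps the compositional bias
of RPM ratios below ~0.05 in log2, so planted fold-changes are
recoverable from normalized counts.

*Genome.* 100 kb with planted hairpin loci separated by ≥ 100 nt
inert spacers. Novel and decoy hairpins use G/C-only stems with A-only
loops, flanked by spacers that read as A in the transcript orientation
of each hairpin (A on the plus strand, T around minus-strand plants):
A pairs with nothing in a G/C/A alphabet, so the planted structure is
the *unique* pairing optimum inside any extraction window.
`make_reference` additionally round-trips every planted novel/decoy
hairpin through extract → fold → evaluate in its final genomic context
and regenerates entities that collide or misfold (bounded retries).
Compliant hairpins are 25-pair stems (every criterion passed with
margin ≥ 2); each decoy violates exactly one recorded criterion by
≥ 2 units. Single-criterion decoys are constructible for criteria
1, 2, 4, 5, 6, 7, 8 and 11; the energy criterion cannot be violated
alone under the pair-count score (16 stem pairs force energy ≤ −16),
and single violations of the mature-errors and mature-pairs criteria
are arithmetically impossible for mature lengths ≥ 18 at the required
margins — all eleven boundaries are instead exercised directly on
hand-built structures in the tests.

*What the simulator does not emulate:* sequencing errors, ligation and
hexamer bias, isomiRs, fluid-specific exosome sorting, genome-wide
sequence realism (the non-pairing background is deliberately
artificial), or biological replicate structure (the pooled design is
the default; per-library replicates exist as an option). Passing the
synthetic suites therefore demonstrates the correctness of the
*computations* under the stated count and structure models, not
robustness to real-library artifacts.

## Problem sizes

Desk-scale defaults used by the test-suite fixtures: 12–20 conserved
miRNAs, 4–5 novel and 4–5 decoy hairpins, 30 k–10⁶ reads per library.
The end-to-end recovery checks run 20 seeds at depth 10⁶ serum reads
per condition; the panel-rule check runs 100 seeds of the 9-candidate
Cq fixture. These sizes were chosen so the whole suite runs on one
CPU in minutes while keeping every rate estimate comfortably powered.

## Known limitations

- The built-in energy is a pair-count surrogate; absolute energies are
  not thermodynamic (use the external-fold pathway for that).
- Fisher on pooled libraries detects arbitrarily small proportion
  shifts at high depth; with overdispersed counts most abundant
  species become "significant", as in the original design — the
  |log2FC| screen, not the p-value, carries the biological filtering.
- Exact substring matching only: no isomiR grouping or
  mismatch-tolerant alignment.
- The 2^−ΔΔCq model assumes perfect amplification efficiency and a
  single stable reference gene.
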