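# Methods

## Problem and model

A fusion transcript joins sequence from two distinct genes, produced by
genomic rearrangement (deletion, inversion, translocation, duplication)
or, rarely, trans-splicing. In germline disease cohorts the signal is
faint: causative events can be mosaic or expressed from one allele, the
assayed tissue is usually a surrogate (blood), and fusion callers'
default filters — tuned on tumor and cell-line data — remove exactly the
low-support candidates of interest. `germfuse` therefore treats fusion
calling as a *curation* problem: start from the caller's unfiltered
output, keep everything with minimal dual-class read evidence, remove
what population frequency says is noise, and explain the remainder with
sequence alignment and gene-model annotation rather than with
support-count heuristics.

The pipeline is a fixed-order composition of total functions, each
returning a partition of its input (kept ∪ removed = input, disjoint,
order-preserving):

    depth → normal-control DB → cohort recurrence → categorization → phenotype

Candidates removed at an early stage are never re-examined later; every
input candidate appears in the final report with exactly one removing
stage or one category.

## Filters

**Read-support (depth).** Kept iff `split_reads ≥ min_split` and
`spanning_reads ≥ min_spanning`, defaults (1, 1). Split pairs have one
member mapping across the junction; spanning pairs have one member on
each side. Requiring both classes at the lowest level retains mosaic and
lowly expressed events while still rejecting single-signature artifacts.
The filter is idempotent and monotone in both thresholds; setting (3, 2)
reproduces typical caller defaults for comparison.

**Normal-control database.** Control observations are keyed by the
canonical breakpoint-coordinate pair (sides ordered by natural
chromosome order, then position, so reciprocal events at different
coordinates keep distinct keys). A key qualifies for removal when a
*single control specimen* reports it with total (split + spanning) reads
≥ `min_reads`. The default `min_reads = 2` encodes the observation that
control-cohort fusion events overwhelmingly carry a single supporting
read, the signature of recurrent alignment artifacts; one read is
insufficient evidence that an event genuinely occurs in controls.
Per-specimen counting is the default; pooling across specimens is
available (`pool_samples=True`) but conflates many weak observations
with one strong one. Matching is exact by default; a ±`fuzz_bp` window
on both positions accommodates callers with imprecise junction
coordinates. All observations (including sub-threshold ones) are
retained for support-distribution histograms.

**Cohort recurrence.** A key observed in ≥ 2 distinct patients is
removed from *all* of them: cohort patients are unrelated and expected
to carry rare, distinct disorders, so a shared event is a platform
artifact or a population polymorphism regardless of which sample it was
seen in first. Within-patient duplicates do not trigger removal.

## Alignment evidence

Three queries per candidate: the full fusion contig and the decoupled
5′/3′ segments. Alignments (external nucleotide aligner at word size 7,
e-value ≤ 1 — small enough to seed on short segments — or precomputed
12-column tabular records) are gated at **identity ≥ 90 %** and **query
coverage ≥ 75 %**, with coverage = (q_end − q_start + 1) / query length.
The gate reads "keep iff both thresholds met": the permissive alternative
(drop only when both fail) would keep perfect half-coverage matches and
make the unbroken-alignment categories meaningless. Per (query,
database) the top bitscore hit is selected; ties are all retained and
the candidate is marked `ambiguous_alignment`.

"Unbroken" means a single alignment block covering ≥ `unbroken_coverage`
(default 0.75, deliberately the same threshold) of the full-length
query. Genome hits are assigned to every gene whose span overlaps the
subject interval; transcriptome hits resolve through transcript → gene.

## Decision tree

Branches are evaluated in fixed precedence A > B > C > D > E > F > G > H;
the order resolves overlaps conservatively, exhausting exclusion and
single-sequence explanations before any fusion call:

- **A — abundant-gene exclusion**: any segment gene matches the
  abundant-blood list (bundled default: globin loci and T-cell receptor
  loci, glob patterns, user-replaceable). Tested on segment-level gene
  assignments, the same resolution the rest of the tree consumes.
- **B — known transcript**: unbroken full-length transcriptome hit.
- **C — genomic sequence**: unbroken full-length genome hit.
- **D — likely artifact**: no alignment at all; or only one segment
  aligns; or the best *pre-gate* full-query hit covers < 25 % of it.
  The 25 % clause must be measured on raw hits: a genuine fusion's full
  query aligns as two ~50 %-coverage halves, which the 75 % gate removes.
- **E — novel single-gene transcript**: both segments within one gene's
  boundaries without a full transcript match.
- **F — immunoglobulin diversity**: both segments in (different)
  immunoglobulin loci (bundled default: IGH/IGK/IGL prefixes).
- **G — interchromosomal fusion**: segment chromosomes disjoint.
- **H — intrachromosomal fusion**: otherwise. Gene-less same-chromosome
  region pairs are still H (two distinct regions), not artifacts.

Flags: `read_through` (H only) when the two genes are adjacent — no
third gene's span lies entirely between them, strand-agnostic; a
stricter same-strand collinear test is reported separately as
`read_through_strict`. `homologous` (G and H) when the partners are a
listed duplicated-gene pair; a gene is its own homolog by convention, so
single-locus duplication artifacts are flagged rather than passed.

## Breakpoint annotation and reading frame

For a 5′-side breakpoint the junction-facing edge is the exon's
transcriptional 3′ end (genomic end on `+`, start on `-`); for a 3′-side
breakpoint, the exon's transcriptional 5′ start. When several
transcripts overlap a position the chooser prefers one where the
position is a junction-facing edge, then longest CDS, then smallest
transcript id — deterministic and biased toward the splicing-consistent
interpretation.

`cds_offset` counts coding nucleotides transcriptionally upstream of the
junction: inclusive of the breakpoint base on the 5′ side (the junction
lies just past it), exclusive on the 3′ side. The junction is **in
frame** iff both sides sit at exon boundaries with defined offsets and
`(offset5 − offset3) mod 3 = 0` — the downstream partner's native codon
phase is preserved. Conventions for degenerate cases: offset is
undefined (frame `not_applicable`) for non-coding transcripts, for a 5′
junction that includes no coding base (UTR-only), and for a 3′ junction
with no coding base downstream; a 3′ junction upstream of the start
codon yields offset 0 (the native ORF is intact downstream). The
implementation is validated against a translation oracle: splice the two
coding fragments, translate, and ask whether the downstream partner's
native peptide reappears intact.

Genomic separation is `|pos5 − pos3|` on a shared chromosome and NA
(undefined) otherwise; per-category report medians use the lower-median
convention (the ⌈n/2⌉-th order statistic), stated in the attrition-table
header.

## Phenotype prioritization

Published pathway/interaction-network p-values from external phenotype
tools are not reimplemented (they require external pathway and
interaction databases); the scorer interface is pluggable and the report
carries the rank-score plus a free-text evidence column. The default
scorer is Resnik-style: IC(term) = −log(fraction of panel genes
annotated to the term or a descendant, annotations propagated to
ancestors), and similarity = mean over patient terms of the maximum IC
of the most informative common ancestor with any gene term. The root's
IC is 0, so semantically unrelated term sets score 0.

Genes are ranked by descending score with minimum-rank ties (ties never
worsen a gene); rank-score = rank / N scored genes, making the statistic
invariant under any strictly monotone transform of the raw scores. A
candidate inherits the better (smaller) rank-score of its two partners —
the paper-level behavior of flagging a fusion by its most
phenotype-relevant gene; combining the pair differently (mean, product)
is a one-line scorer change. The default shortlist cutoff is 0.05,
configurable; all scored candidates stay in the report because final
review is a human step.

## Synthetic fixtures

The generator emulates the pipeline's *inputs*, not sequencing: planted
candidate tables and synthesized alignment records at the table level,
so tests need no aligner binary and no downloads (an integration test
exercises the external aligner when present). The toy reference is two
chromosomes (~60 kb and ~25 kb) and 17 single-transcript genes chosen to
cover every branch: a globin-like gene, two immunoglobulin loci, a
near-identical duplicated pair separated by an intervening gene, two
adjacent same-strand genes (read-through substrate), and multi-exon
coding genes on both strands and chromosomes. Exon lengths are fixed
templates whose cumulative coding offsets cover all residues mod 3 — so
in-frame and out-of-frame junction pairs exist for every seed — while
intron/intergenic sizes and all nucleotide sequence are drawn from the
seed.

Default cohort: 4 patients × 29 candidates (10 removed at depth, 5 at
the normal DB, 1 cohort-recurrent, 13 categorized covering all eight
categories and both flags), 6 controls with ~80 % single-read background
events plus designated events shared with patients at 3 reads (must be
removed) and at 1 read (must survive). The small per-patient counts are
chosen for sub-second tests; they exercise every code path of the
production-scale workflow. A 100-gene phenotype panel over a 29-term
toy ontology plants one signal gene whose fusions rank top 1 %.

What passing tests do **not** show about real data: toy sequences are
i.i.d. random (no repeats, homopolymers or paralog families beyond the
planted pair), alignment records are synthesized rather than produced by
a real aligner against a real genome, every gene has one transcript
(the multi-transcript chooser is exercised only by overlap cases), and
control cohorts are orders of magnitude smaller than the
normal-tissue databases real deployments need. The category logic,
filter contracts and frame arithmetic transfer; recall/precision on real
cohorts does not follow from these tests.

## Numerical and design choices

- Coordinates 1-based both-inclusive everywhere; report headers say so.
- Candidate ids are deterministic (`sample:row-ordinal`) so reruns are
  byte-identical; no timestamps in outputs.
- Strand vocabulary normalized to {forward, reverse} from `+,-,f,r` and
  two-character orientation tokens on ingest.
- Raw-caller column layout is configurable (`column_map`) around a
  documented default, since raw archives vary.
- Malformed candidate rows are collected and reported per row; a file
  fails hard only when > 50 % of its data rows are unparseable.
- A query length missing from the sequence set is inferred as the
  maximum observed `q_end` — a lower bound, making coverage an upper
  bound (the permissive direction for precomputed hits).
- The normal-DB threshold is recorded in the database header and the run
  manifest; every pipeline threshold lands in the report header.

## Known limitations

- No splice-site motif scanning or protein-domain annotation of fusion
  products; frame calls are purely arithmetic on annotated CDS.
- Exon numbering follows the supplied GTF; published reports may mix
  annotation sources, so cross-referencing printed exon numbers requires
  the matching release.
- The normal-control database matches on exact (or fuzz-windowed)
  coordinates; a gene-pair-level mode catches coordinate-shifted
  recurrences but also removes distinct events between the same genes.
- The default similarity scorer is intentionally simple; it is a ranking
  device, not a calibrated probability of phenotype relevance.
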