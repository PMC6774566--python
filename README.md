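# germfuse

Curation of candidate gene-fusion transcripts in **germline** RNA-seq.

Fusion callers were trained on tumor, cell-line or simulated data, and
their default filters discard the low-support events that matter in rare
inherited disease, where mosaicism, mono-allelic expression and surrogate
tissues (usually blood) depress supporting-read counts. `germfuse`
replaces those filters with a workflow tailored to germline data: keep
everything with minimal dual-class read evidence, remove what recurs in
unaffected controls or across unrelated patients, explain the remainder
biologically with an alignment-pattern decision tree, and rank the
surviving fusion candidates by phenotype relevance.

It is written for genome scientists triaging fusion-caller output in
diagnostic or research settings: the input is a per-sample candidate
table (a raw caller dialect or a documented generic TSV), pairwise
alignments of the candidate sequences against a genome and a
transcriptome (standard 12-column tabular records, produced by any
nucleotide aligner or by the bundled wrapper), gene models (GTF), and
optional gene lists, homolog pairs, control cohorts and phenotype terms.

## The method

1. **Read-support filter.** A candidate must have ≥ 1 *split* read pair
   (one member mapping across the junction) **and** ≥ 1 *spanning* read
   pair (one member on each side) — far more inclusive than typical
   caller defaults (3 split / 2 supporting), but still demanding both
   evidence classes.
2. **Normal-control database.** Events seen in any unaffected control
   specimen with ≥ 2 supporting reads are removed as recurrent artifacts
   or constitutive fusions (most control events carry a single read, the
   signature of alignment noise). Events recurring across ≥ 2 unrelated
   cohort patients are also removed.
3. **Categorization.** Each candidate contributes three queries — the
   full fusion contig and the decoupled 5′/3′ segments — aligned with
   word size 7 and e-value 1; hits under 90 % identity or 75 % query
   coverage are discarded. A fixed-precedence decision tree then assigns
   exactly one category: abundant-blood-gene exclusion; known transcript
   (unbroken full-length transcriptome alignment); genomic sequence;
   likely artifact (no or partial alignment); novel single-gene
   transcript; immunoglobulin diversity; interchromosomal fusion;
   intrachromosomal fusion. Intrachromosomal candidates between
   neighboring genes are flagged as potential read-through; paralogous
   partners (Duplicated Genes Database style pairs) are flagged as
   homologous.
4. **Annotation.** Breakpoints are located against the gene models:
   exon-boundary status, genomic separation, and reading frame. A
   junction at coding exon edges is *in frame* iff
   `(offset5 − offset3) mod 3 = 0`, where `offsetX` counts coding
   nucleotides transcriptionally upstream of the junction.
5. **Prioritization.** Disease genes are scored for semantic similarity
   between patient and gene phenotype terms (pluggable scorer; the
   default is Resnik-style information content of the most informative
   common ancestor) and ranked. A gene's **rank-score** is
   `rank / N_scored_genes` — 0.01 means top 1 % of all scored disease
   genes. A fusion candidate inherits the better rank-score of its two
   partners.

## Worked example

Everything below runs from a self-contained synthetic bundle — a toy
two-chromosome reference with ~17 genes covering every decision-tree
branch, four patients, and a six-sample control cohort:

```bash
germfuse simulate --seed 7 --out demo
germfuse run \
    --candidates demo/P01.tsv --candidates demo/P02.tsv \
    --candidates demo/P03.tsv --candidates demo/P04.tsv \
    --controls demo/C01.tsv --controls demo/C02.tsv \
    --controls demo/C03.tsv --controls demo/C04.tsv \
    --controls demo/C05.tsv --controls demo/C06.tsv \
    --gtf demo/models.gtf --genome-aln demo/genome_aln.tsv \
    --tx-aln demo/tx_aln.tsv --homologs demo/homologs.tsv \
    --out demo/out
```

which prints the per-patient attrition table:

```
sample  n_input  removed_depth  removed_normal_db  removed_cohort  n_categorized ...
   P01       29             10                  5               1             13
   P02       29             10                  5               1             13
   P03       29             10                  5               1             13
   P04       29             10                  5               1             13
```

Each patient starts with 29 raw candidates; 10 lack one of the two read
classes, 5 match the control database, 1 recurs across patients, and the
remaining 13 are categorized (per patient: 1 abundant-gene exclusion,
1 known transcript, 1 genomic sequence, 2 likely artifacts, 1 novel
single-gene transcript, 1 immunoglobulin event, 2 interchromosomal and
4 intrachromosomal fusions — one flagged read-through, one flagged
homologous). `demo/out/report.tsv` lists every candidate with its
disposition, category, partner genes, exon-boundary status, frame call
and on-chromosome separation; `demo/truth.tsv` carries the planted
labels for comparison.

The same objects are available as a library:

```python
from germfuse import Breakpoint, Side, Strand, genomic_separation

bp5 = Breakpoint("chr8", 119592952, Strand.REVERSE, Side.FIVE_PRIME)
bp3 = Breakpoint("chr8", 118849438, Strand.REVERSE, Side.THREE_PRIME)
genomic_separation(bp5, bp3)   # 743514 (bp); None for interchromosomal
```

## Layout

- `germfuse.fusion_io` — candidate model, table/list readers, report writer
- `germfuse.genemodels` — GTF-backed interval-queryable gene models
- `germfuse.filters` — depth, normal-control and cohort-recurrence filters
- `germfuse.alignment` — queries, tabular-hit gating, alignment summaries
- `germfuse.annotate` — exon boundaries, reading frame, separation, neighbors
- `germfuse.categorize` — the decision tree and per-category count summaries
- `germfuse.pipeline` — stage orchestration, report and attrition tables
- `germfuse.prioritize` — semantic-similarity scoring and rank-scores
- `germfuse.simulate` — deterministic synthetic references, cohorts and truth

See `docs/methods.md` for the model, conventions, parameter defaults and
known limitations.
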