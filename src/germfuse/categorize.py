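"""The alignment-pattern decision tree assigning one category per candidate.

Categories (evaluated in fixed precedence order, first match wins):

A. EXCLUDED_ABUNDANT — a segment gene matches the abundant-blood list
   (globins, T-cell receptors); overrepresented in blood-derived RNA.
B. KNOWN_TRANSCRIPT — the full-length query produces an unbroken
   alignment against the transcriptome: a likely known transcript.
C. GENOMIC_SEQUENCE — unbroken alignment of the full query against the
   genome: likely DNA fragment or unprocessed RNA.
D. LIKELY_ARTIFACT — no alignment at all, or only a part alignment
   (one segment, or a <25%-coverage best full hit): low-quality or
   non-human sequence, adapters.
E. NOVEL_TRANSCRIPT_SINGLE_GENE — both segments fall within one gene's
   boundaries without a full transcript match: potential novel isoform
   or aberrant single-gene event.
F. IMMUNE_DIVERSITY — two hits to separate immunoglobulin loci.
G. INTERCHROMOSOMAL_FUSION — distinct alignments on two chromosomes.
H. INTRACHROMOSOMAL_FUSION — two distinct genes or regions on one
   chromosome; neighboring genes are flagged as potential read-through,
   and paralogous partners are flagged as homologous (also applied to G).

The precedence resolves overlaps conservatively: exclusion and
single-sequence explanations are exhausted before any fusion call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import AlignmentSummary
from .annotate import (
    BreakpointAnnotation,
    FrameCall,
    are_homologs,
    are_neighbors,
    frame_status,
    genomic_separation,
    read_through_strict,
)
from .fusion_io import FusionCandidate, GeneSymbolSet, HomologSet
from .genemodels import GeneModelIndex


class Category(str, Enum):
    EXCLUDED_ABUNDANT = "EXCLUDED_ABUNDANT"
    KNOWN_TRANSCRIPT = "KNOWN_TRANSCRIPT"
    GENOMIC_SEQUENCE = "GENOMIC_SEQUENCE"
    LIKELY_ARTIFACT = "LIKELY_ARTIFACT"
    NOVEL_TRANSCRIPT_SINGLE_GENE = "NOVEL_TRANSCRIPT_SINGLE_GENE"
    IMMUNE_DIVERSITY = "IMMUNE_DIVERSITY"
    INTERCHROMOSOMAL_FUSION = "INTERCHROMOSOMAL_FUSION"
    INTRACHROMOSOMAL_FUSION = "INTRACHROMOSOMAL_FUSION"


#: Categories that proceed to phenotype-based prioritization.
FUSION_CATEGORIES = frozenset(
    {Category.INTERCHROMOSOMAL_FUSION, Category.INTRACHROMOSOMAL_FUSION}
)

#: Fraction of the full query a best raw hit must reach to escape the
#: "only a part alignment was possible" artifact clause.
PART_ALIGNMENT_MAX_COVERAGE = 0.25


@dataclass
class CategorizedCandidate:
    """A candidate with exactly one category plus optional flags."""

    candidate: FusionCandidate
    category: Category
    flags: set[str] = field(default_factory=set)
    ann5: Optional[BreakpointAnnotation] = None
    ann3: Optional[BreakpointAnnotation] = None
    separation: Optional[int] = None
    frame: Optional[FrameCall] = None
    gene5: Optional[str] = None
    gene3: Optional[str] = None
    read_through_strict: bool = False
    rank_score: Optional[float] = None

    def __post_init__(self) -> None:
        if "read_through" in self.flags and (
                self.category != Category.INTRACHROMOSOMAL_FUSION):
            raise ValueError("read_through flag requires an intrachromosomal fusion")
        if "homologous" in self.flags and self.category not in FUSION_CATEGORIES:
            raise ValueError("homologous flag requires a fusion category")


def _primary_gene(genes: tuple[str, ...]) -> Optional[str]:
    return genes[0] if genes else None


def categorize_candidate(
    candidate: FusionCandidate,
    summary: AlignmentSummary,
    ann5: BreakpointAnnotation,
    ann3: BreakpointAnnotation,
    abundant: GeneSymbolSet,
    immunoglobulins: GeneSymbolSet,
    homologs: HomologSet,
    index: GeneModelIndex,
) -> CategorizedCandidate:
    """Assign exactly one category plus flags; deterministic given inputs."""
    if summary is None:
        raise ValueError(
            f"{candidate.candidate_id}: no alignment summary — candidate "
            "must pass the alignment stage or be declared unalignable")

    genes5, genes3 = summary.seg5_genes, summary.seg3_genes
    g5, g3 = _primary_gene(genes5), _primary_gene(genes3)
    flags: set[str] = set()
    if summary.ambiguous:
        flags.add("ambiguous_alignment")
    sep = genomic_separation(candidate.bp5, candidate.bp3)

    def build(cat: Category, **kw) -> CategorizedCandidate:
        return CategorizedCandidate(
            candidate=candidate, category=cat, flags=flags,
            ann5=ann5, ann3=ann3, separation=sep,
            gene5=g5, gene3=g3, **kw)

    # A — abundant hematological genes
    if abundant.any_match(summary.seg_genes):
        return build(Category.EXCLUDED_ABUNDANT)
    # B — unbroken full-length transcriptome alignment
    if summary.full_unbroken_tx_hit:
        return build(Category.KNOWN_TRANSCRIPT)
    # C — unbroken full-length genome alignment
    if summary.full_unbroken_genome_hit:
        return build(Category.GENOMIC_SEQUENCE)
    # D — no alignment, or only a part alignment
    part_only = (
        summary.full_best_raw_coverage is not None
        and summary.full_best_raw_coverage < PART_ALIGNMENT_MAX_COVERAGE)
    if (not summary.any_alignment
            or not (summary.seg5_has_hit and summary.seg3_has_hit)
            or part_only):
        return build(Category.LIKELY_ARTIFACT)

    frame = frame_status(ann5, ann3)

    # E — both segments within one gene's boundaries
    shared = set(genes5) & set(genes3)
    if shared:
        g5 = g3 = sorted(shared)[0]
        return build(Category.NOVEL_TRANSCRIPT_SINGLE_GENE, frame=frame)
    # F — two hits to separate immunoglobulins
    if (any(immunoglobulins.matches(g) for g in genes5)
            and any(immunoglobulins.matches(g) for g in genes3)):
        return build(Category.IMMUNE_DIVERSITY, frame=frame)

    homologous = any(
        are_homologs(a, b, homologs)
        for a in (genes5 or (None,)) for b in (genes3 or (None,)))

    # G — different chromosomes
    chroms5 = set(summary.seg5_chroms) or {candidate.bp5.chrom}
    chroms3 = set(summary.seg3_chroms) or {candidate.bp3.chrom}
    if not (chroms5 & chroms3):
        if homologous:
            flags.add("homologous")
        return build(Category.INTERCHROMOSOMAL_FUSION, frame=frame)

    # H — two distinct genes or regions on a single chromosome
    if homologous:
        flags.add("homologous")
    neighbor = bool(g5 and g3 and g5 != g3 and are_neighbors(g5, g3, index))
    if neighbor:
        flags.add("read_through")
    strict = bool(g5 and g3 and g5 != g3
                  and read_through_strict(g5, g3, index))
    return build(Category.INTRACHROMOSOMAL_FUSION, frame=frame,
                 read_through_strict=strict)


def category_counts(per_sample_categories: dict[str, list[Category]]) -> pd.DataFrame:
    """Median (lower-median convention) and quartiles of per-sample counts.

    For an even number of samples the lower median — the n//2-th order
    statistic (0-based (n-1)//2) — is reported.
    """
    if not per_sample_categories:
        raise ValueError("at least one sample report required")
    samples = sorted(per_sample_categories)
    rows = []
    for cat in Category:
        counts = sorted(
            sum(1 for c in per_sample_categories[s] if c == cat)
            for s in samples)
        n = len(counts)
        rows.append({
            "category": cat.value,
            "median": counts[(n - 1) // 2],
            "q1": float(np.percentile(counts, 25)),
            "q3": float(np.percentile(counts, 75)),
            "total": int(sum(counts)),
        })
    return pd.DataFrame(rows)


def __getattr__(name):
    # Re-exported pipeline entry points (the orchestration lives in
    # germfuse.pipeline; this keeps the categorization module the single
    # import surface for running the full workflow).
    if name in {"PipelineConfig", "PipelineResult", "run_pipeline"}:
        from . import pipeline

        return getattr(pipeline, name)
    raise AttributeError(name)
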