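"""Breakpoint-level biology: gene/exon localization, frame, separation.

A fusion junction formed by splicing should coincide with annotated exon
edges: the transcriptional 3' edge of an exon on the 5' partner and the
5' edge of an exon on the 3' partner.  When both sides sit at coding exon
boundaries, the junction preserves the downstream gene's reading frame
iff the number of coding bases contributed by the 5' partner is congruent
modulo 3 with the downstream partner's native coding offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .fusion_io import Breakpoint, HomologSet, Side
from .genemodels import GeneModelIndex, Transcript


@dataclass
class BreakpointAnnotation:
    """Gene-model context of one breakpoint.

    cds_offset is the count of coding nucleotides transcriptionally
    upstream of the junction within the chosen transcript (None for
    non-coding or UTR-only context).
    """

    gene: Optional[str] = None
    transcript: Optional[str] = None
    exon_index: Optional[int] = None
    at_exon_boundary: bool = False
    cds_offset: Optional[int] = None


class FrameStatus(str, Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class FrameCall:
    status: FrameStatus


def _is_junction_edge(tx: Transcript, pos: int, side: Side) -> bool:
    """Is pos the junction-facing exon edge for this side, in tx orientation?

    5' partner: junction follows the exon, so the edge is the exon's
    transcriptional 3' end (genomic end on '+', genomic start on '-').
    3' partner: the exon's transcriptional 5' start.
    """
    for ex in tx.exons:
        if not ex.contains(pos):
            continue
        if side == Side.FIVE_PRIME:
            edge = ex.end if tx.strand == "+" else ex.start
        else:
            edge = ex.start if tx.strand == "+" else ex.end
        if pos == edge:
            return True
    return False


def _cds_offset(tx: Transcript, pos: int, side: Side) -> Optional[int]:
    """Coding bases transcriptionally upstream of the junction, or None.

    For the 5' side the junction lies just past the breakpoint base, so a
    coding base at pos is counted; for the 3' side the junction precedes
    it.  None when the transcript is non-coding, when a 5' junction
    includes no coding base (UTR-only), or when a 3' junction leaves no
    coding base downstream.
    """
    if not tx.cds:
        return None
    if side == Side.FIVE_PRIME:
        n = tx.coding_bases_before(pos, inclusive=True)
        return n if n > 0 else None
    n = tx.coding_bases_before(pos, inclusive=False)
    return n if n < tx.cds_length else None


def locate_breakpoint(bp: Breakpoint, index: GeneModelIndex) -> BreakpointAnnotation:
    """Annotate a breakpoint against the gene models.

    Transcript choice when several overlap: prefer one where the position
    is the junction-facing exon edge; among those, longest CDS; tie broken
    by lexicographically smallest transcript id.
    """
    if bp.chrom not in index.chromosomes():
        warnings.warn(f"chromosome {bp.chrom!r} absent from gene-model index")
        return BreakpointAnnotation()
    candidates = index.transcripts_at(bp.chrom, bp.pos)
    if not candidates:
        genes = index.genes_at(bp.chrom, bp.pos)
        return BreakpointAnnotation(gene=genes[0].symbol if genes else None)
    ranked = sorted(
        candidates,
        key=lambda tx: (
            not _is_junction_edge(tx, bp.pos, bp.side),  # boundary first
            -tx.cds_length,
            tx.tx_id,
        ),
    )
    tx = ranked[0]
    boundary = _is_junction_edge(tx, bp.pos, bp.side)
    return BreakpointAnnotation(
        gene=tx.gene,
        transcript=tx.tx_id,
        exon_index=tx.exon_index_at(bp.pos),
        at_exon_boundary=boundary,
        cds_offset=_cds_offset(tx, bp.pos, bp.side),
    )


def frame_status(ann5: BreakpointAnnotation,
                 ann3: BreakpointAnnotation) -> FrameCall:
    """Reading-frame call for a junction from its two annotations.

    in_frame iff both sides sit at exon boundaries with defined coding
    offsets and (offset5 - offset3) mod 3 == 0, i.e. the downstream
    gene's native codon phase is preserved in the chimeric transcript.
    """
    if (not ann5.at_exon_boundary or not ann3.at_exon_boundary
            or ann5.cds_offset is None or ann3.cds_offset is None):
        return FrameCall(FrameStatus.NOT_APPLICABLE)
    if (ann5.cds_offset - ann3.cds_offset) % 3 == 0:
        return FrameCall(FrameStatus.IN_FRAME)
    return FrameCall(FrameStatus.OUT_OF_FRAME)


def genomic_separation(bp5: Breakpoint, bp3: Breakpoint) -> Optional[int]:
    """Absolute base-pair separation when intrachromosomal, else None (NA)."""
    if bp5.chrom != bp3.chrom:
        return None
    return abs(bp5.pos - bp3.pos)


def are_neighbors(geneA: str, geneB: str, index: GeneModelIndex) -> bool:
    """True when no third gene lies entirely between the two gene spans.

    Strand-agnostic adjacency on one chromosome: the substrate of a
    potential read-through (co-transcription of adjacent loci).  Genes on
    different chromosomes, or unknown genes, are not neighbors.
    """
    if geneA not in index.genes or geneB not in index.genes:
        warnings.warn(f"gene absent from index: {geneA!r} or {geneB!r}")
        return False
    if index.genes[geneA].chrom != index.genes[geneB].chrom:
        return False
    if geneA == geneB:
        return False
    return len(index.genes_between(geneA, geneB)) == 0


def read_through_strict(gene5: str, gene3: str, index: GeneModelIndex) -> bool:
    """Stricter read-through test: same strand, adjacent, collinear.

    Requires the 5' partner to lie transcriptionally upstream of the 3'
    partner on the shared strand, with no intervening gene — the geometry
    a polymerase reading through an intergenic region would produce.
    """
    if not are_neighbors(gene5, gene3, index):
        return False
    a, b = index.genes[gene5], index.genes[gene3]
    if a.strand != b.strand:
        return False
    if a.strand == "+":
        return a.end < b.start
    return a.start > b.end


def are_homologs(geneA: Optional[str], geneB: Optional[str],
                 homologs: HomologSet) -> bool:
    """Symmetric homology test; a gene is its own homolog by convention,
    so duplicate-gene artifacts of a single locus are flagged rather than
    silently passed."""
    if not geneA or not geneB:
        return False
    if geneA.upper() == geneB.upper():
        return True
    return homologs.contains(geneA, geneB)
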