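"""Interval-queryable gene models parsed from GTF.

The :class:`GeneModelIndex` backs every annotation step of the workflow:
breakpoint-to-gene assignment, exon-boundary tests, coding-offset
computation for reading-frame calls, neighbor detection for read-through
flagging, and transcript-to-gene resolution of transcriptome alignments.

Coordinates are 1-based and both-inclusive throughout, matching the GTF
convention and the way breakpoints are printed in fusion reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from intervaltree import IntervalTree


class GtfFormatError(ValueError):
    """Raised when a GTF feature line lacks mandatory attributes."""


@dataclass(frozen=True)
class Exon:
    """A genomic interval, 1-based both-inclusive."""

    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class Transcript:
    """One transcript: ordered exons plus optional CDS sub-intervals.

    ``exons`` and ``cds`` are stored in ascending genomic order; use
    :meth:`exons_tx_order` for 5'→3' transcription order.
    """

    tx_id: str
    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[Exon, ...]
    cds: tuple[Exon, ...] = ()

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    def exons_tx_order(self) -> tuple[Exon, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def exon_index_at(self, pos: int) -> Optional[int]:
        """1-based exon number in transcription order containing ``pos``."""
        for i, ex in enumerate(self.exons_tx_order(), start=1):
            if ex.contains(pos):
                return i
        return None

    def spliced_sequence(self, genome_seq: str) -> str:
        """Transcript sequence from a chromosome string (1-based slicing)."""
        from Bio.Seq import Seq

        s = "".join(genome_seq[e.start - 1 : e.end] for e in self.exons)
        return str(Seq(s).reverse_complement()) if self.strand == "-" else s

    def cds_sequence(self, genome_seq: str) -> str:
        from Bio.Seq import Seq

        s = "".join(genome_seq[c.start - 1 : c.end] for c in self.cds)
        return str(Seq(s).reverse_complement()) if self.strand == "-" else s

    def coding_bases_before(self, pos: int, inclusive: bool) -> int:
        """Number of coding bases transcriptionally upstream of ``pos``.

        With ``inclusive=True`` a coding base at ``pos`` itself is counted
        (the convention for a 5' breakpoint, whose junction lies just past
        the breakpoint base); with ``inclusive=False`` it is not (3' side).
        """
        n = 0
        if self.strand == "+":
            limit = pos if inclusive else pos - 1
            for c in self.cds:
                lo, hi = c.start, min(c.end, limit)
                if hi >= lo:
                    n += hi - lo + 1
        else:
            limit = pos if inclusive else pos + 1
            for c in self.cds:
                lo, hi = max(c.start, limit), c.end
                if hi >= lo:
                    n += hi - lo + 1
        return n


@dataclass
class Gene:
    symbol: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class GeneModelIndex:
    """Genes, transcripts and exons with point/interval queries per chromosome."""

    def __init__(self) -> None:
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, Transcript] = {}
        self._trees: dict[str, IntervalTree] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GeneModelIndex":
        """Build an index from an Ensembl-style GTF.

        Requires gene, transcript and exon features; CDS features (when
        present) enable coding-frame annotation.  Every feature line must
        carry a ``gene_id`` attribute.
        """
        path = Path(path)
        cls._validate_gtf(path)
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        idx = cls()
        for g in db.features_of_type("gene"):
            symbol = (g.attributes.get("gene_name") or g.attributes["gene_id"])[0]
            idx.genes[symbol] = Gene(
                symbol=symbol,
                gene_id=g.attributes["gene_id"][0],
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
            )
        sym_by_id = {g.gene_id: g.symbol for g in idx.genes.values()}
        for t in db.features_of_type("transcript"):
            tx_id = t.attributes["transcript_id"][0]
            gene_sym = sym_by_id.get(t.attributes["gene_id"][0])
            exons = tuple(
                sorted(
                    (Exon(e.start, e.end) for e in db.children(t, featuretype="exon")),
                    key=lambda e: e.start,
                )
            )
            cds = tuple(
                sorted(
                    (Exon(c.start, c.end) for c in db.children(t, featuretype="CDS")),
                    key=lambda c: c.start,
                )
            )
            if not exons:
                continue
            tx = Transcript(
                tx_id=tx_id, gene=gene_sym, chrom=t.seqid, strand=t.strand,
                exons=exons, cds=cds,
            )
            idx.transcripts[tx_id] = tx
            if gene_sym is not None:
                idx.genes[gene_sym].transcripts.append(tx_id)
        idx._build_trees()
        return idx

    @staticmethod
    def _validate_gtf(path: Path) -> None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9 or "gene_id" not in fields[8]:
                    raise GtfFormatError(
                        f"{path}:{lineno}: feature line missing gene_id attribute"
                    )

    def _build_trees(self) -> None:
        self._trees = {}
        for gene in self.genes.values():
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            tree[gene.start : gene.end + 1] = gene.symbol

    # -- queries ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree[pos]), key=lambda g: g.symbol
        )

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree[start : end + 1]),
            key=lambda g: g.symbol,
        )

    def transcripts_at(self, chrom: str, pos: int) -> list[Transcript]:
        out = []
        for gene in self.genes_at(chrom, pos):
            for tx_id in gene.transcripts:
                tx = self.transcripts[tx_id]
                if tx.start <= pos <= tx.end:
                    out.append(tx)
        return out

    def gene_of_transcript(self, tx_id: str) -> Optional[Gene]:
        tx = self.transcripts.get(tx_id)
        if tx is None or tx.gene is None:
            return None
        return self.genes.get(tx.gene)

    def genes_between(self, sym_a: str, sym_b: str) -> list[Gene]:
        """Genes whose span lies entirely within the gap separating two genes.

        Empty when the two spans touch or overlap.  Both genes must be on
        the same chromosome; otherwise a ValueError is raised.
        """
        a, b = self.genes[sym_a], self.genes[sym_b]
        if a.chrom != b.chrom:
            raise ValueError(f"{sym_a} and {sym_b} are on different chromosomes")
        first, second = (a, b) if a.start <= b.start else (b, a)
        gap_lo, gap_hi = first.end + 1, second.start - 1
        if gap_lo > gap_hi:
            return []
        return [
            g
            for g in self.genes_overlapping(a.chrom, gap_lo, gap_hi)
            if g.symbol not in (sym_a, sym_b) and g.start >= gap_lo and g.end <= gap_hi
        ]


def write_gtf(genes: Iterable[Gene], transcripts: dict[str, Transcript],
              path: str | Path, source: str = "germfuse") -> None:
    """Serialize gene models to GTF (used by the fixture generator)."""
    lines = []
    for gene in genes:
        attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}";'
        lines.append(
            "\t".join(
                [gene.chrom, source, "gene", str(gene.start), str(gene.end),
                 ".", gene.strand, ".", attrs]
            )
        )
        for tx_id in gene.transcripts:
            tx = transcripts[tx_id]
            tattrs = attrs + f' transcript_id "{tx.tx_id}";'
            lines.append(
                "\t".join(
                    [gene.chrom, source, "transcript", str(tx.start), str(tx.end),
                     ".", tx.strand, ".", tattrs]
                )
            )
            for i, ex in enumerate(tx.exons, start=1):
                eattrs = tattrs + f' exon_number "{i}";'
                lines.append(
                    "\t".join(
                        [gene.chrom, source, "exon", str(ex.start), str(ex.end),
                         ".", tx.strand, ".", eattrs]
                    )
                )
            for c in tx.cds:
                lines.append(
                    "\t".join(
                        [gene.chrom, source, "CDS", str(c.start), str(c.end),
                         ".", tx.strand, "0", tattrs]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")
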