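"""Alignment queries, tabular hit ingestion, and alignment-pattern summaries.

Each candidate contributes three nucleotide queries: the full fusion
contig (conjoined 5' and 3' segments) and the two decoupled segments.
Queries are aligned — by an external nucleotide aligner run with word
size 7 and e-value 1, suitable for short sequences, or supplied as
precomputed files — against both a genome and a transcriptome, producing
conventional 12-column tabular records.  Hits below 90% identity or 75%
query coverage are discarded; the top-scoring hit per (query, database)
is selected (ties retained and marked ambiguous) and reduced to the
boolean/gene-level summary the categorization decision tree consumes.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .fusion_io import FusionCandidate
from .genemodels import GeneModelIndex

GENOME = "genome"
TRANSCRIPTOME = "transcriptome"

OUTFMT6_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


class AlignerNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class AlignConfig:
    """Alignment and hit-filtering parameters.

    word_size/evalue_max parameterize the external aligner (small word
    size so short queries still seed); min_identity and min_query_coverage
    gate which hits survive; unbroken_coverage defines how much of the
    full-length query a single alignment block must cover to count as an
    "unbroken" alignment (defaults to the same 75%).
    """

    word_size: int = 7
    evalue_max: float = 1.0
    min_identity: float = 0.90
    min_query_coverage: float = 0.75
    unbroken_coverage: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 < self.min_query_coverage <= 1):
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular alignment record against genome or transcriptome.

    query_id encodes candidate and query kind as ``<candidate_id>|<kind>``
    with kind in {full, seg5, seg3}.  s_start > s_end signals reverse
    orientation on the subject.
    """

    query_id: str
    subject_id: str
    subject_db: str  # genome | transcriptome
    pct_identity: float
    length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError(f"{self.query_id}: bad query coordinates")
        if not (0 < self.pct_identity <= 100):
            raise ValueError(f"{self.query_id}: pct_identity out of range")

    @property
    def candidate_id(self) -> str:
        return self.query_id.rsplit("|", 1)[0]

    @property
    def query_kind(self) -> str:
        return self.query_id.rsplit("|", 1)[1]

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))

    def coverage(self, query_length: int) -> float:
        return (self.q_end - self.q_start + 1) / query_length


def query_id_for(candidate_id: str, kind: str) -> str:
    if kind not in {"full", "seg5", "seg3"}:
        raise ValueError(f"unknown query kind {kind!r}")
    return f"{candidate_id}|{kind}"


# ---------------------------------------------------------------------------
# query construction

def build_queries(candidate: FusionCandidate,
                  junction: Optional[int] = None):
    """FASTA records (full, seg5, seg3) for one candidate.

    Returns ``(records, unalignable)``.  When only the full contig is
    present and a junction offset (length of the 5' segment) is known,
    segments are sliced from it.  A candidate with no sequence at all is
    flagged unalignable (it will classify as an artifact-pattern "no
    alignment" unless hits are supplied externally).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    full, seg5, seg3 = candidate.seq_full, candidate.seq5, candidate.seq3
    if full is None and seg5 is not None and seg3 is not None:
        full = seg5 + seg3
    if full is not None and (seg5 is None or seg3 is None) and junction:
        seg5, seg3 = full[:junction], full[junction:]
    records = []
    for kind, seq in (("full", full), ("seg5", seg5), ("seg3", seg3)):
        if seq:
            records.append(
                SeqRecord(Seq(seq), id=query_id_for(candidate.candidate_id, kind),
                          description=""))
    return records, len(records) == 0


# ---------------------------------------------------------------------------
# tabular hit I/O

def read_hits(path: str | Path, subject_db: str) -> list[AlignmentHit]:
    """Read 12-column tabular alignment records (outfmt-6 layout)."""
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return [
        AlignmentHit(
            query_id=str(r.query_id), subject_id=str(r.subject_id),
            subject_db=subject_db, pct_identity=float(r.pct_identity),
            length=int(r.length), mismatches=int(r.mismatches),
            gap_opens=int(r.gap_opens), q_start=int(r.q_start),
            q_end=int(r.q_end), s_start=int(r.s_start), s_end=int(r.s_end),
            evalue=float(r.evalue), bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def write_hits(hits: list[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_id, h.pct_identity, h.length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end,
                h.s_start, h.s_end, h.evalue, h.bitscore))) + "\n")


# ---------------------------------------------------------------------------
# hit filtering and selection

def filter_hits(hits: list[AlignmentHit], cfg: AlignConfig,
                query_lengths: dict[str, int]) -> list[AlignmentHit]:
    """Keep hits with identity >= min_identity and coverage >= min coverage.

    Coverage is (q_end - q_start + 1) / query_length.  Order preserved;
    pure filter (idempotent).  A hit referencing an unknown query raises.
    """
    out = []
    for h in hits:
        if h.query_id not in query_lengths:
            raise KeyError(f"hit references unknown query {h.query_id!r}")
        if (h.pct_identity >= 100.0 * cfg.min_identity
                and h.coverage(query_lengths[h.query_id])
                >= cfg.min_query_coverage):
            out.append(h)
    return out


def select_top_hits(
    hits: list[AlignmentHit],
) -> dict[tuple[str, str], list[AlignmentHit]]:
    """Top-scoring hit per (query_id, subject_db); score ties all retained.

    A multi-element value marks the selection ambiguous for that query
    and database.
    """
    best: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        key = (h.query_id, h.subject_db)
        cur = best.get(key)
        if cur is None or h.bitscore > cur[0].bitscore:
            best[key] = [h]
        elif h.bitscore == cur[0].bitscore:
            cur.append(h)
    return best


# ---------------------------------------------------------------------------
# per-candidate summary

@dataclass
class AlignmentSummary:
    """Reduction of a candidate's top hits to what the decision tree needs."""

    candidate_id: str
    full_unbroken_tx_hit: bool = False
    full_unbroken_genome_hit: bool = False
    full_tx_subject: Optional[str] = None
    seg5_genes: tuple[str, ...] = ()
    seg3_genes: tuple[str, ...] = ()
    seg5_chroms: tuple[str, ...] = ()
    seg3_chroms: tuple[str, ...] = ()
    seg5_has_hit: bool = False
    seg3_has_hit: bool = False
    any_alignment: bool = False
    ambiguous: bool = False
    full_best_raw_coverage: Optional[float] = None
    unalignable: bool = False

    @property
    def seg_genes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.seg5_genes) | set(self.seg3_genes)))


def _genes_for_hit(hit: AlignmentHit, index: GeneModelIndex) -> list[str]:
    if hit.subject_db == TRANSCRIPTOME:
        gene = index.gene_of_transcript(hit.subject_id)
        return [gene.symbol] if gene else []
    lo, hi = hit.subject_interval
    return [g.symbol for g in index.genes_overlapping(hit.subject_id, lo, hi)]


def _chrom_for_hit(hit: AlignmentHit, index: GeneModelIndex) -> Optional[str]:
    if hit.subject_db == GENOME:
        return hit.subject_id
    tx = index.transcripts.get(hit.subject_id)
    return tx.chrom if tx else None


def summarize_alignments(
    candidate: FusionCandidate,
    top_hits: dict[tuple[str, str], list[AlignmentHit]],
    gene_index: GeneModelIndex,
    cfg: Optional[AlignConfig] = None,
    query_lengths: Optional[dict[str, int]] = None,
    raw_hits: Optional[list[AlignmentHit]] = None,
) -> AlignmentSummary:
    """Summarize a candidate's (already filtered, top-selected) hits.

    ``raw_hits`` — the pre-gate records — feed the best raw coverage of
    the full query, used downstream to distinguish "only a part alignment
    was possible" from genuine two-gene patterns.  full_unbroken flags are
    true only when a single top alignment block covers at least
    ``cfg.unbroken_coverage`` of the full query.
    """
    cfg = cfg or AlignConfig()
    cid = candidate.candidate_id
    qlen = dict(query_lengths or {})
    for kind, seq in (("full", candidate.seq_full), ("seg5", candidate.seq5),
                      ("seg3", candidate.seq3)):
        q = query_id_for(cid, kind)
        if q not in qlen and seq:
            qlen[q] = len(seq)
    if (query_id_for(cid, "full") not in qlen
            and query_id_for(cid, "seg5") in qlen
            and query_id_for(cid, "seg3") in qlen):
        qlen[query_id_for(cid, "full")] = (
            qlen[query_id_for(cid, "seg5")] + qlen[query_id_for(cid, "seg3")])

    summary = AlignmentSummary(candidate_id=cid)
    full_q = query_id_for(cid, "full")

    def tops(kind: str, db: str) -> list[AlignmentHit]:
        return top_hits.get((query_id_for(cid, kind), db), [])

    # full-query unbroken flags
    for db, attr in ((TRANSCRIPTOME, "full_unbroken_tx_hit"),
                     (GENOME, "full_unbroken_genome_hit")):
        for h in tops("full", db):
            if full_q in qlen and h.coverage(qlen[full_q]) >= cfg.unbroken_coverage:
                setattr(summary, attr, True)
                if db == TRANSCRIPTOME:
                    summary.full_tx_subject = h.subject_id
                break

    # per-segment gene/chromosome resolution across both databases
    for seg, gattr, cattr, hattr in (
        ("seg5", "seg5_genes", "seg5_chroms", "seg5_has_hit"),
        ("seg3", "seg3_genes", "seg3_chroms", "seg3_has_hit"),
    ):
        genes: list[str] = []
        chroms: list[str] = []
        has = False
        for db in (TRANSCRIPTOME, GENOME):
            for h in tops(seg, db):
                has = True
                genes.extend(_genes_for_hit(h, gene_index))
                c = _chrom_for_hit(h, gene_index)
                if c:
                    chroms.append(c)
        setattr(summary, gattr, tuple(sorted(set(genes))))
        setattr(summary, cattr, tuple(sorted(set(chroms))))
        setattr(summary, hattr, has)

    summary.any_alignment = any(
        top_hits.get((query_id_for(cid, k), db))
        for k in ("full", "seg5", "seg3") for db in (GENOME, TRANSCRIPTOME))
    summary.ambiguous = any(
        len(v) > 1 for k, v in top_hits.items() if k[0].startswith(cid + "|"))

    if raw_hits is not None and full_q in qlen:
        covs = [h.coverage(qlen[full_q]) for h in raw_hits
                if h.query_id == full_q]
        summary.full_best_raw_coverage = max(covs) if covs else 0.0

    summary.unalignable = (
        candidate.seq_full is None and candidate.seq5 is None
        and candidate.seq3 is None and not summary.any_alignment)
    return summary


# ---------------------------------------------------------------------------
# optional external aligner

def run_external_aligner(queries_fasta: str | Path, subject_fasta: str | Path,
                         cfg: AlignConfig, out_path: str | Path) -> Path:
    """Run blastn (if on PATH) and write 12-column tabular records.

    Deterministic given identical inputs and config.  Raises
    AlignerNotFoundError with guidance when the executable is missing —
    precomputed hit files are a first-class alternative input.
    """
    exe = shutil.which("blastn")
    if exe is None:
        raise AlignerNotFoundError(
            "blastn not found on PATH; supply precomputed tabular hits "
            "via --genome-aln/--tx-aln instead")
    out_path = Path(out_path)
    cmd = [exe, "-query", str(queries_fasta), "-subject", str(subject_fasta),
           "-task", "blastn", "-word_size", str(cfg.word_size),
           "-evalue", str(cfg.evalue_max), "-outfmt", "6",
           "-out", str(out_path)]
    subprocess.run(cmd, check=True, capture_output=True)
    return out_path
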