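"""Deterministic synthetic fixtures: toy reference, planted candidates, controls.

Everything the pipeline consumes is generated here at toy scale so the
whole workflow is testable without downloads or external binaries:

* a two-chromosome reference (~100 kb total, ~20 genes) whose gene
  inventory covers every decision-tree branch — a globin-like abundant
  gene, two immunoglobulin loci, a near-identical duplicated gene pair,
  two adjacent same-strand genes (read-through substrate), and multi-exon
  coding genes on both strands and both chromosomes;
* per-patient candidate sets planting at least one positive for every
  category and every filter stage, with known reading-frame status for
  every coding fusion;
* alignment records synthesized directly at the table level (respecting
  or violating the 90%/75% identity/coverage gates per truth), so tests
  have no aligner dependency;
* a control cohort whose supporting-read distribution is mostly
  single-read events, as observed in large normal-tissue RNA databases,
  with designated events shared with patients at >=2 reads (must be
  filtered) and at exactly 1 read (must survive).

All generation is driven by a single integer seed; identical seeds give
byte-identical outputs, and changing the seed varies coordinates and
sequences while preserving the planted category structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alignment import GENOME, TRANSCRIPTOME, AlignmentHit, query_id_for, write_hits
from .categorize import Category
from .filters import FusionKey
from .fusion_io import (
    Breakpoint,
    CandidateSet,
    FusionCandidate,
    HomologSet,
    Side,
    Strand,
    write_candidates,
)
from .genemodels import Exon, Gene, GeneModelIndex, Transcript, write_gtf

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 4 patients; per patient 10 low-support events, 5 events
    shared with a control at >=2 reads, 1 cohort-recurrent event, and one
    candidate per decision-tree branch (13 categorized events).  Controls
    carry mostly single-read background events (frac_one_read), matching
    the support distribution seen in normal-tissue fusion databases.
    """

    seed: int
    n_patients: int = 4
    n_low_support: int = 10
    n_normal_shared: int = 5
    n_controls: int = 6
    n_control_background: int = 8
    frac_one_read: float = 0.8
    read_support_low: int = 2
    read_support_high: int = 30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in ("n_patients", "n_low_support", "n_normal_shared",
                  "n_controls", "n_control_background"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class TruthLabel:
    candidate_id: str
    sample_id: str
    true_category: Optional[Category]  # None for pre-categorization removals
    true_flags: frozenset = frozenset()
    expected_disposition: str = "retained"  # or depth|normal_db|cohort
    frame: Optional[str] = None  # in_frame | out_of_frame | None
    gene5: Optional[str] = None
    gene3: Optional[str] = None
    transcript5: Optional[str] = None
    transcript3: Optional[str] = None
    cds_offset5: Optional[int] = None
    cds_offset3: Optional[int] = None


@dataclass
class ToyReference:
    genome: dict[str, str]
    index: GeneModelIndex
    homologs: HomologSet

    def transcript_seq(self, tx_id: str) -> str:
        tx = self.index.transcripts[tx_id]
        return tx.spliced_sequence(self.genome[tx.chrom])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n{self.genome[chrom]}\n")
        with open(outdir / "transcriptome.fa", "w") as fh:
            for tx_id in sorted(self.index.transcripts):
                fh.write(f">{tx_id}\n{self.transcript_seq(tx_id)}\n")
        write_gtf(
            sorted(self.index.genes.values(), key=lambda g: (g.chrom, g.start)),
            self.index.transcripts, outdir / "models.gtf")
        with open(outdir / "homologs.tsv", "w") as fh:
            fh.write("# duplicated-gene pairs\n")
            for pair in sorted(tuple(sorted(p)) for p in self.homologs.pairs):
                fh.write("\t".join(pair) + "\n")


# ---------------------------------------------------------------------------
# gene construction

# (symbol, strand, exon lengths in transcription order, utr5, utr3)
_CHRA_TEMPLATES = [
    ("HBB", "+", (142, 223, 129), 50, 40),
    ("TRAC", "+", (200, 180), 40, 40),
    ("GC1", "+", (120, 121, 122, 123, 124), 30, 30),
    ("DUPA", "-", (140, 150, 160), 30, 30),
    ("MIDX", "+", (160, 150), 30, 30),
    ("DUPB", "-", (140, 150, 160), 30, 30),
    ("RTA", "+", (130, 140, 150), 30, 30),
    ("RTB", "+", (130, 140, 150), 30, 30),
    ("GC2", "-", (120, 121, 122, 123, 124), 30, 30),
    ("GC5", "+", (120, 121, 122, 123), 30, 30),
    ("NOV1", "+", (150, 140, 130, 160), 30, 30),
    ("KT1", "+", (150, 160, 170, 140), 30, 30),
]
_CHRB_TEMPLATES = [
    ("IGHV1", "+", (180, 210), 30, 30),
    ("GC3", "+", (120, 121, 122, 123, 124), 30, 30),
    ("IGKV1", "-", (190, 170), 30, 30),
    ("GC4", "-", (120, 121, 122, 123, 124), 30, 30),
    ("GC6", "+", (120, 122, 121, 124), 30, 30),
]
# fixed intron lengths for the duplicated pair so both spans are identical
_DUP_INTRONS = (300, 400)


def _build_gene(symbol: str, chrom: str, strand: str, gstart: int,
                exon_lens: tuple[int, ...], intron_lens: list[int],
                utr5: int, utr3: int) -> tuple[Gene, Transcript]:
    glens = list(exon_lens) if strand == "+" else list(reversed(exon_lens))
    exons, pos = [], gstart
    for i, L in enumerate(glens):
        exons.append(Exon(pos, pos + L - 1))
        pos += L + (intron_lens[i] if i < len(glens) - 1 else 0)
    total = sum(exon_lens)
    cds_lo_t, cds_hi_t = utr5 + 1, total - utr3
    tx_exons = exons if strand == "+" else list(reversed(exons))
    cds: list[Exon] = []
    t0 = 1
    for k, ex in enumerate(tx_exons):
        L = len(ex)
        a, b = max(t0, cds_lo_t), min(t0 + L - 1, cds_hi_t)
        if a <= b:
            if strand == "+":
                cds.append(Exon(ex.start + (a - t0), ex.start + (b - t0)))
            else:
                cds.append(Exon(ex.end - (b - t0), ex.end - (a - t0)))
        t0 += L
    tx = Transcript(
        tx_id=f"{symbol}.t1", gene=symbol, chrom=chrom, strand=strand,
        exons=tuple(exons), cds=tuple(sorted(cds, key=lambda c: c.start)))
    gene = Gene(symbol=symbol, gene_id=symbol, chrom=chrom, strand=strand,
                start=exons[0].start, end=exons[-1].end,
                transcripts=[tx.tx_id])
    return gene, tx


def make_toy_reference(cfg: SimConfig) -> ToyReference:
    """Build the toy genome, gene models and transcriptome."""
    rng = np.random.default_rng(int(cfg.seed))
    index = GeneModelIndex()
    for chrom, templates in (("chrA", _CHRA_TEMPLATES),
                             ("chrB", _CHRB_TEMPLATES)):
        pos = int(rng.integers(1500, 2500))
        for symbol, strand, exon_lens, u5, u3 in templates:
            if symbol in ("DUPA", "DUPB"):
                introns = list(_DUP_INTRONS)
            else:
                introns = [int(rng.integers(200, 800))
                           for _ in range(len(exon_lens) - 1)]
            gene, tx = _build_gene(symbol, chrom, strand, pos, exon_lens,
                                   introns, u5, u3)
            index.genes[symbol] = gene
            index.transcripts[tx.tx_id] = tx
            pos = gene.end + int(rng.integers(800, 2000))
    index._build_trees()

    genome: dict[str, str] = {}
    for chrom in ("chrA", "chrB"):
        genes = [g for g in index.genes.values() if g.chrom == chrom]
        length = max(g.end for g in genes) + 4000
        genome[chrom] = "".join(rng.choice(_BASES, size=length))
    # make DUPB a near-identical copy of DUPA (one mismatch per ~200 bp)
    a, b = index.genes["DUPA"], index.genes["DUPB"]
    seq = list(genome[a.chrom])
    copy = seq[a.start - 1 : a.end]
    n_mut = max(1, len(copy) // 200)
    for i in rng.choice(len(copy), size=n_mut, replace=False):
        copy[i] = str(rng.choice(_BASES))
    seq[b.start - 1 : b.start - 1 + len(copy)] = copy
    genome[a.chrom] = "".join(seq)

    homologs = HomologSet()
    homologs.add("DUPA", "DUPB")
    return ToyReference(genome=genome, index=index, homologs=homologs)


# ---------------------------------------------------------------------------
# phenotype fixture

@dataclass
class PhenotypeFixture:
    """Toy ontology, gene–term associations and per-patient term lists."""

    obo_text: str
    gene_terms: dict[str, set[str]]
    patient_terms: dict[str, list[str]]

    def ontology(self):
        import io

        from .prioritize import PhenotypeOntology

        import obonet

        return PhenotypeOntology(obonet.read_obo(io.StringIO(self.obo_text)))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "phenotype.obo").write_text(self.obo_text)
        with open(outdir / "gene_terms.tsv", "w") as fh:
            for gene in sorted(self.gene_terms):
                for term in sorted(self.gene_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")
        with open(outdir / "patient_terms.tsv", "w") as fh:
            for pid in sorted(self.patient_terms):
                fh.write(f"{pid}\t{','.join(self.patient_terms[pid])}\n")


def make_toy_phenotype(cfg: SimConfig, ref: ToyReference,
                       n_panel_genes: int = 100) -> PhenotypeFixture:
    """Small is_a tree plus a gene panel annotated with its leaf terms.

    Each patient's term list equals the annotation of one designated
    fusion partner gene (GC1), so phenotype ranking has a planted signal.
    """
    rng = np.random.default_rng(int(cfg.seed) + 3)
    n_branches, leaves_per_branch = 4, 6
    stanzas = ["format-version: 1.2", "ontology: toy-phenotype", "",
               "[Term]", "id: T:0001", "name: root"]
    branches = []
    leaf_ids: dict[str, list[str]] = {}
    tid = 2
    for b in range(n_branches):
        bid = f"T:{tid:04d}"
        tid += 1
        branches.append(bid)
        stanzas += ["", "[Term]", f"id: {bid}", f"name: branch{b}",
                    "is_a: T:0001 ! root"]
        leaf_ids[bid] = []
        for _ in range(leaves_per_branch):
            lid = f"T:{tid:04d}"
            tid += 1
            leaf_ids[bid].append(lid)
            stanzas += ["", "[Term]", f"id: {lid}", f"name: leaf{lid}",
                        f"is_a: {bid} ! branch{b}"]
    obo_text = "\n".join(stanzas) + "\n"

    panel = sorted(ref.index.genes)
    panel += [f"GENE{k:03d}" for k in range(n_panel_genes - len(panel))]
    gene_terms: dict[str, set[str]] = {}
    for gene in panel:
        bid = branches[int(rng.integers(0, n_branches))]
        picks = rng.choice(leaves_per_branch, size=2, replace=False)
        gene_terms[gene] = {leaf_ids[bid][int(i)] for i in picks}
    patient_terms = {f"P{p + 1:02d}": sorted(gene_terms["GC1"])
                     for p in range(cfg.n_patients)}
    return PhenotypeFixture(obo_text=obo_text, gene_terms=gene_terms,
                            patient_terms=patient_terms)


# ---------------------------------------------------------------------------
# candidate planting

@dataclass
class SimulatedCohort:
    reference: ToyReference
    config: SimConfig
    patients: dict[str, CandidateSet]
    control_sets: list[CandidateSet]
    hits: list[AlignmentHit]
    truths: dict[str, TruthLabel]
    phenotype: Optional["PhenotypeFixture"] = None

    def expected_attrition(self) -> dict[str, dict[str, int]]:
        """Per-patient stage counts implied by the truth labels."""
        out: dict[str, dict[str, int]] = {}
        for pid, cset in self.patients.items():
            row = {"n_input": len(cset), "removed_depth": 0,
                   "removed_normal_db": 0, "removed_cohort": 0,
                   "n_categorized": 0}
            for cat in Category:
                row[cat.value] = 0
            for cand in cset:
                t = self.truths[cand.candidate_id]
                if t.expected_disposition == "retained":
                    row["n_categorized"] += 1
                    row[t.true_category.value] += 1
                else:
                    row[f"removed_{t.expected_disposition}"] += 1
            out[pid] = row
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reference.write(outdir)
        for pid in sorted(self.patients):
            write_candidates(self.patients[pid], outdir / f"{pid}.tsv")
        for cset in self.control_sets:
            write_candidates(cset, outdir / f"{cset.sample_id}.tsv")
        write_hits([h for h in self.hits if h.subject_db == GENOME],
                   outdir / "genome_aln.tsv")
        write_hits([h for h in self.hits if h.subject_db == TRANSCRIPTOME],
                   outdir / "tx_aln.tsv")
        if self.phenotype is not None:
            self.phenotype.write(outdir)
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("candidate_id\tsample_id\tcategory\tflags\tdisposition"
                     "\tframe\tgene5\tgene3\n")
            for cid in sorted(self.truths):
                t = self.truths[cid]
                fh.write("\t".join([
                    cid, t.sample_id,
                    t.true_category.value if t.true_category else "",
                    ",".join(sorted(t.true_flags)),
                    t.expected_disposition, t.frame or "",
                    t.gene5 or "", t.gene3 or ""]) + "\n")


class _Planter:
    """Stateful helper: unique keys, combo tracking, hit emission."""

    def __init__(self, cfg: SimConfig, ref: ToyReference,
                 rng: np.random.Generator):
        self.cfg, self.ref, self.rng = cfg, ref, rng
        self.used_keys: set[tuple] = set()
        self.used_combos: dict[tuple, set] = {}
        self.hits: list[AlignmentHit] = []
        self.truths: dict[str, TruthLabel] = {}

    # -- low-level utilities ------------------------------------------

    def _reserve(self, bp5: Breakpoint, bp3: Breakpoint) -> bool:
        key = FusionKey.from_candidate(
            FusionCandidate("tmp", "tmp", bp5, bp3, 1, 1)).coords
        if key in self.used_keys:
            return False
        self.used_keys.add(key)
        return True

    def random_breakpoints(self) -> tuple[Breakpoint, Breakpoint]:
        for _ in range(1000):
            c5, c3 = self.rng.choice(["chrA", "chrB"], size=2)
            p5 = int(self.rng.integers(1, len(self.ref.genome[c5])))
            p3 = int(self.rng.integers(1, len(self.ref.genome[c3])))
            s5, s3 = (Strand.FORWARD if self.rng.random() < 0.5
                      else Strand.REVERSE for _ in range(2))
            bp5 = Breakpoint(str(c5), p5, s5, Side.FIVE_PRIME)
            bp3 = Breakpoint(str(c3), p3, s3, Side.THREE_PRIME)
            if self._reserve(bp5, bp3):
                return bp5, bp3
        raise RuntimeError("could not draw a unique random breakpoint pair")

    def support(self) -> tuple[int, int]:
        lo, hi = self.cfg.read_support_low, self.cfg.read_support_high
        return (int(self.rng.integers(lo, hi)), int(self.rng.integers(lo, hi)))

    # -- sequence/hit helpers -----------------------------------------

    def _exon_seq(self, tx: Transcript, i: int) -> str:
        from Bio.Seq import Seq

        ex = tx.exons_tx_order()[i - 1]
        s = self.ref.genome[tx.chrom][ex.start - 1 : ex.end]
        return str(Seq(s).reverse_complement()) if tx.strand == "-" else s

    def _edge(self, tx: Transcript, i: int, side: Side) -> int:
        ex = tx.exons_tx_order()[i - 1]
        if side == Side.FIVE_PRIME:  # junction-facing 3' edge
            return ex.end if tx.strand == "+" else ex.start
        return ex.start if tx.strand == "+" else ex.end

    def _seg_hits(self, cid: str, kind: str, tx: Transcript,
                  i: int) -> list[AlignmentHit]:
        ex = tx.exons_tx_order()[i - 1]
        L = len(ex)
        t0 = 1 + sum(len(e) for e in tx.exons_tx_order()[: i - 1])
        q = query_id_for(cid, kind)
        ss, se = (ex.start, ex.end) if tx.strand == "+" else (ex.end, ex.start)
        return [
            AlignmentHit(q, tx.tx_id, TRANSCRIPTOME, 100.0, L, 0, 0,
                         1, L, t0, t0 + L - 1, 1e-30, 2.0 * L),
            AlignmentHit(q, tx.chrom, GENOME, 100.0, L, 0, 0,
                         1, L, ss, se, 1e-30, 2.0 * L),
        ]

    def _full_half_hits(self, cid: str, len5: int, len3: int,
                        chrom5: str, chrom3: str) -> list[AlignmentHit]:
        # two partial blocks on the genome; below the 75% coverage gate but
        # well above the 25% part-alignment clause
        full_q = query_id_for(cid, "full")
        return [
            AlignmentHit(full_q, chrom5, GENOME, 100.0, len5, 0, 0,
                         1, len5, 1, len5, 1e-10, 1.8 * len5),
            AlignmentHit(full_q, chrom3, GENOME, 100.0, len3, 0, 0,
                         len5 + 1, len5 + len3, 1, len3, 1e-10, 1.8 * len3),
        ]

    def _cds_offset(self, tx: Transcript, pos: int, side: Side) -> Optional[int]:
        if not tx.cds:
            return None
        if side == Side.FIVE_PRIME:
            n = tx.coding_bases_before(pos, inclusive=True)
            return n if n > 0 else None
        n = tx.coding_bases_before(pos, inclusive=False)
        return n if n < tx.cds_length else None

    def pick_combo(self, tx5: Transcript, tx3: Transcript,
                   want: str) -> tuple[int, int, int, int]:
        """Donor/acceptor exon pair with the requested frame relation.

        want: 'in', 'out' or 'any'.  Raises when every suitable pair is
        exhausted (generation error naming the requirement).
        """
        pair = (tx5.tx_id, tx3.tx_id)
        used = self.used_combos.setdefault(pair, set())
        n5, n3 = len(tx5.exons), len(tx3.exons)
        for i in range(1, n5):
            for j in range(2, n3 + 1):
                if (i, j) in used:
                    continue
                off5 = self._cds_offset(tx5, self._edge(tx5, i, Side.FIVE_PRIME),
                                        Side.FIVE_PRIME)
                off3 = self._cds_offset(tx3, self._edge(tx3, j, Side.THREE_PRIME),
                                        Side.THREE_PRIME)
                if off5 is None or off3 is None:
                    continue
                in_frame = (off5 - off3) % 3 == 0
                if want == "in" and not in_frame:
                    continue
                if want == "out" and in_frame:
                    continue
                used.add((i, j))
                return i, j, off5, off3
        raise RuntimeError(
            f"no unused {want}-frame exon combination for {pair}")

    # -- candidate builders -------------------------------------------

    def fusion_candidate(self, cid: str, pid: str, gene5: str, gene3: str,
                         want: str = "any",
                         emit_hits: bool = True) -> tuple[FusionCandidate, dict]:
        """Exon-boundary fusion between two genes, with frame bookkeeping."""
        tx5 = self.ref.index.transcripts[f"{gene5}.t1"]
        tx3 = self.ref.index.transcripts[f"{gene3}.t1"]
        for _ in range(50):
            i, j, off5, off3 = self.pick_combo(tx5, tx3, want)
            bp5 = Breakpoint(tx5.chrom, self._edge(tx5, i, Side.FIVE_PRIME),
                             Strand.FORWARD if tx5.strand == "+"
                             else Strand.REVERSE, Side.FIVE_PRIME)
            bp3 = Breakpoint(tx3.chrom, self._edge(tx3, j, Side.THREE_PRIME),
                             Strand.FORWARD if tx3.strand == "+"
                             else Strand.REVERSE, Side.THREE_PRIME)
            if self._reserve(bp5, bp3):
                break
        else:
            raise RuntimeError(f"no unique key for {gene5}-{gene3}")
        seg5, seg3 = self._exon_seq(tx5, i), self._exon_seq(tx3, j)
        split, spanning = self.support()
        cand = FusionCandidate(cid, pid, bp5, bp3, split, spanning,
                               seq_full=seg5 + seg3, seq5=seg5, seq3=seg3)
        if emit_hits:
            self.hits += self._seg_hits(cid, "seg5", tx5, i)
            self.hits += self._seg_hits(cid, "seg3", tx3, j)
            self.hits += self._full_half_hits(
                cid, len(seg5), len(seg3), tx5.chrom, tx3.chrom)
        info = {"frame": "in_frame" if (off5 - off3) % 3 == 0 else "out_of_frame",
                "off5": off5, "off3": off3,
                "tx5": tx5.tx_id, "tx3": tx3.tx_id}
        return cand, info

    def loose_fusion_candidate(self, cid: str, pid: str, gene5: str,
                               gene3: str) -> FusionCandidate:
        """Two-gene candidate with random in-exon breakpoints (no frame truth)."""
        tx5 = self.ref.index.transcripts[f"{gene5}.t1"]
        tx3 = self.ref.index.transcripts[f"{gene3}.t1"]
        for _ in range(100):
            i = int(self.rng.integers(1, len(tx5.exons) + 1))
            j = int(self.rng.integers(1, len(tx3.exons) + 1))
            e5 = tx5.exons_tx_order()[i - 1]
            e3 = tx3.exons_tx_order()[j - 1]
            bp5 = Breakpoint(tx5.chrom, int(self.rng.integers(e5.start, e5.end + 1)),
                             Strand.FORWARD if tx5.strand == "+"
                             else Strand.REVERSE, Side.FIVE_PRIME)
            bp3 = Breakpoint(tx3.chrom, int(self.rng.integers(e3.start, e3.end + 1)),
                             Strand.FORWARD if tx3.strand == "+"
                             else Strand.REVERSE, Side.THREE_PRIME)
            if self._reserve(bp5, bp3):
                break
        else:
            raise RuntimeError(f"no unique key for {gene5}-{gene3}")
        seg5, seg3 = self._exon_seq(tx5, i), self._exon_seq(tx3, j)
        cand = FusionCandidate(cid, pid, bp5, bp3, *self.support(),
                               seq_full=seg5 + seg3, seq5=seg5, seq3=seg3)
        self.hits += self._seg_hits(cid, "seg5", tx5, i)
        self.hits += self._seg_hits(cid, "seg3", tx3, j)
        self.hits += self._full_half_hits(cid, len(seg5), len(seg3),
                                          tx5.chrom, tx3.chrom)
        return cand

    def random_seq(self, n: int) -> str:
        return "".join(self.rng.choice(_BASES, size=n))


def plant_candidates(cfg: SimConfig, ref: ToyReference):
    """Per-patient candidate sets, alignment records, truth labels.

    Returns ``(patients, hits, truths, shared_for_controls)`` where the
    last element lists (control_ordinal, candidate, total_reads) control
    observations the control cohort must carry.
    """
    rng = np.random.default_rng(int(cfg.seed) + 1)
    pl = _Planter(cfg, ref, rng)
    patients: dict[str, CandidateSet] = {}
    shared_for_controls: list[tuple[int, FusionCandidate, int]] = []
    recurrent_bp: Optional[tuple[Breakpoint, Breakpoint]] = None

    for p in range(cfg.n_patients):
        pid = f"P{p + 1:02d}"
        cset = CandidateSet(sample_id=pid, provenance="synthetic")
        counter = 0

        def cid() -> str:
            nonlocal counter
            counter += 1
            return f"{pid}:c{counter:02d}"

        def add(cand: FusionCandidate, label: TruthLabel) -> None:
            cset.candidates.append(cand)
            pl.truths[cand.candidate_id] = label

        # -- removed at depth: missing one (or both) read classes
        for k in range(cfg.n_low_support):
            bp5, bp3 = pl.random_breakpoints()
            pattern = k % 3
            split = 0 if pattern != 1 else int(rng.integers(1, 8))
            spanning = 0 if pattern != 0 else int(rng.integers(1, 8))
            c = FusionCandidate(cid(), pid, bp5, bp3, split, spanning)
            add(c, TruthLabel(c.candidate_id, pid, None,
                              expected_disposition="depth"))

        # -- removed by the normal-control database (control has >=2 reads)
        for k in range(cfg.n_normal_shared):
            bp5, bp3 = pl.random_breakpoints()
            c = FusionCandidate(cid(), pid, bp5, bp3, *pl.support())
            add(c, TruthLabel(c.candidate_id, pid, None,
                              expected_disposition="normal_db"))
            shared_for_controls.append(
                ((p * cfg.n_normal_shared + k) % cfg.n_controls, c, 3))

        # -- removed by cohort recurrence (same key in every patient)
        if cfg.n_patients >= 2:
            if recurrent_bp is None:
                recurrent_bp = pl.random_breakpoints()
            c = FusionCandidate(cid(), pid, *recurrent_bp, *pl.support())
            add(c, TruthLabel(c.candidate_id, pid, None,
                              expected_disposition="cohort"))

        # -- A: abundant hematological gene involved
        c, _ = pl.fusion_candidate(cid(), pid, "HBB", "GC3")
        add(c, TruthLabel(c.candidate_id, pid, Category.EXCLUDED_ABUNDANT))

        # -- B: unbroken full-length transcriptome alignment
        tx = ref.index.transcripts["KT1.t1"]
        i = 1 + p % (len(tx.exons) - 1)
        seg5, seg3 = pl._exon_seq(tx, i), pl._exon_seq(tx, i + 1)
        full = seg5 + seg3
        t0 = 1 + sum(len(e) for e in tx.exons_tx_order()[: i - 1])
        b_id = cid()
        for _ in range(100):
            e5 = tx.exons_tx_order()[i - 1]
            e3 = tx.exons_tx_order()[i]
            bp5 = Breakpoint(tx.chrom, int(rng.integers(e5.start, e5.end + 1)),
                             Strand.FORWARD, Side.FIVE_PRIME)
            bp3 = Breakpoint(tx.chrom, int(rng.integers(e3.start, e3.end + 1)),
                             Strand.FORWARD, Side.THREE_PRIME)
            if pl._reserve(bp5, bp3):
                break
        c = FusionCandidate(b_id, pid, bp5, bp3, *pl.support(),
                            seq_full=full, seq5=seg5, seq3=seg3)
        pl.hits.append(AlignmentHit(
            query_id_for(b_id, "full"), tx.tx_id, TRANSCRIPTOME, 100.0,
            len(full), 0, 0, 1, len(full), t0, t0 + len(full) - 1,
            1e-40, 2.0 * len(full)))
        pl.hits += pl._seg_hits(b_id, "seg5", tx, i)
        pl.hits += pl._seg_hits(b_id, "seg3", tx, i + 1)
        add(c, TruthLabel(b_id, pid, Category.KNOWN_TRANSCRIPT))

        # -- C: unbroken genomic alignment (intergenic slice)
        g_id = cid()
        chrom = "chrA"
        tail_start = max(g.end for g in ref.index.genes.values()
                         if g.chrom == chrom) + 500
        L = 240
        start = int(rng.integers(tail_start,
                                 len(ref.genome[chrom]) - L - 100))
        full = ref.genome[chrom][start - 1 : start - 1 + L]
        half = L // 2
        bp5 = Breakpoint(chrom, start + half - 1, Strand.FORWARD,
                         Side.FIVE_PRIME)
        bp3 = Breakpoint(chrom, start + half, Strand.FORWARD,
                         Side.THREE_PRIME)
        pl._reserve(bp5, bp3)
        c = FusionCandidate(g_id, pid, bp5, bp3, *pl.support(),
                            seq_full=full, seq5=full[:half], seq3=full[half:])
        pl.hits.append(AlignmentHit(
            query_id_for(g_id, "full"), chrom, GENOME, 100.0, L, 0, 0,
            1, L, start, start + L - 1, 1e-40, 2.0 * L))
        pl.hits.append(AlignmentHit(
            query_id_for(g_id, "seg5"), chrom, GENOME, 100.0, half, 0, 0,
            1, half, start, start + half - 1, 1e-30, 2.0 * half))
        pl.hits.append(AlignmentHit(
            query_id_for(g_id, "seg3"), chrom, GENOME, 100.0, L - half, 0, 0,
            1, L - half, start + half, start + L - 1, 1e-30, 2.0 * (L - half)))
        add(c, TruthLabel(g_id, pid, Category.GENOMIC_SEQUENCE))

        # -- D: no alignment at all (non-reference sequence)
        bp5, bp3 = pl.random_breakpoints()
        c = FusionCandidate(cid(), pid, bp5, bp3, *pl.support(),
                            seq_full=None, seq5=pl.random_seq(120),
                            seq3=pl.random_seq(110))
        add(c, TruthLabel(c.candidate_id, pid, Category.LIKELY_ARTIFACT))

        # -- D: only a part alignment (one segment aligns)
        d2_id = cid()
        txd = ref.index.transcripts["GC2.t1"]
        di = 1 + p % (len(txd.exons) - 1)
        seg5 = pl._exon_seq(txd, di)
        seg3 = pl.random_seq(130)
        bp5 = Breakpoint(txd.chrom, pl._edge(txd, di, Side.FIVE_PRIME),
                         Strand.REVERSE, Side.FIVE_PRIME)
        bp3c, _unused = pl.random_breakpoints()
        bp3 = Breakpoint(bp3c.chrom, bp3c.pos, bp3c.strand, Side.THREE_PRIME)
        c = FusionCandidate(d2_id, pid, bp5, bp3, *pl.support(),
                            seq_full=seg5 + seg3, seq5=seg5, seq3=seg3)
        pl.hits += pl._seg_hits(d2_id, "seg5", txd, di)
        add(c, TruthLabel(d2_id, pid, Category.LIKELY_ARTIFACT))

        # -- E: both segments within one gene, no full transcript match
        e_id = cid()
        txn = ref.index.transcripts["NOV1.t1"]
        n_ex = len(txn.exons)
        for ei in range(1, n_ex):
            for ej in range(ei + 1, n_ex + 1):
                bp5 = Breakpoint(txn.chrom, pl._edge(txn, ei, Side.FIVE_PRIME),
                                 Strand.FORWARD, Side.FIVE_PRIME)
                bp3 = Breakpoint(txn.chrom, pl._edge(txn, ej, Side.THREE_PRIME),
                                 Strand.FORWARD, Side.THREE_PRIME)
                if pl._reserve(bp5, bp3):
                    break
            else:
                continue
            break
        else:
            raise RuntimeError("no unused exon pair for the NOV1 candidate")
        seg5, seg3 = pl._exon_seq(txn, ei), pl._exon_seq(txn, ej)
        c = FusionCandidate(e_id, pid, bp5, bp3, *pl.support(),
                            seq_full=seg5 + seg3, seq5=seg5, seq3=seg3)
        pl.hits += pl._seg_hits(e_id, "seg5", txn, ei)
        pl.hits += pl._seg_hits(e_id, "seg3", txn, ej)
        pl.hits += pl._full_half_hits(e_id, len(seg5), len(seg3),
                                      txn.chrom, txn.chrom)
        add(c, TruthLabel(e_id, pid, Category.NOVEL_TRANSCRIPT_SINGLE_GENE,
                          gene5="NOV1", gene3="NOV1"))

        # -- F: two separate immunoglobulin loci
        c = pl.loose_fusion_candidate(cid(), pid, "IGHV1", "IGKV1")
        add(c, TruthLabel(c.candidate_id, pid, Category.IMMUNE_DIVERSITY))

        # -- G: interchromosomal, in-frame and out-of-frame
        c, info = pl.fusion_candidate(cid(), pid, "GC1", "GC3", want="in")
        add(c, TruthLabel(c.candidate_id, pid,
                          Category.INTERCHROMOSOMAL_FUSION,
                          frame="in_frame", gene5="GC1", gene3="GC3",
                          transcript5=info["tx5"], transcript3=info["tx3"],
                          cds_offset5=info["off5"], cds_offset3=info["off3"]))
        c, info = pl.fusion_candidate(cid(), pid, "GC2", "GC4", want="out")
        add(c, TruthLabel(c.candidate_id, pid,
                          Category.INTERCHROMOSOMAL_FUSION,
                          frame="out_of_frame", gene5="GC2", gene3="GC4",
                          transcript5=info["tx5"], transcript3=info["tx3"],
                          cds_offset5=info["off5"], cds_offset3=info["off3"]))

        # -- H: plain intrachromosomal (distant genes, intervening loci)
        c, info = pl.fusion_candidate(cid(), pid, "GC1", "GC2")
        add(c, TruthLabel(c.candidate_id, pid,
                          Category.INTRACHROMOSOMAL_FUSION,
                          frame=info["frame"], gene5="GC1", gene3="GC2",
                          transcript5=info["tx5"], transcript3=info["tx3"],
                          cds_offset5=info["off5"], cds_offset3=info["off3"]))

        # -- H + read_through: adjacent same-strand genes
        c, info = pl.fusion_candidate(cid(), pid, "RTA", "RTB")
        add(c, TruthLabel(c.candidate_id, pid,
                          Category.INTRACHROMOSOMAL_FUSION,
                          true_flags=frozenset({"read_through"}),
                          frame=info["frame"], gene5="RTA", gene3="RTB",
                          transcript5=info["tx5"], transcript3=info["tx3"],
                          cds_offset5=info["off5"], cds_offset3=info["off3"]))

        # -- H + homologous: duplicated gene pair with an intervening gene
        c, info = pl.fusion_candidate(cid(), pid, "DUPA", "DUPB")
        add(c, TruthLabel(c.candidate_id, pid,
                          Category.INTRACHROMOSOMAL_FUSION,
                          true_flags=frozenset({"homologous"}),
                          frame=info["frame"], gene5="DUPA", gene3="DUPB",
                          transcript5=info["tx5"], transcript3=info["tx3"],
                          cds_offset5=info["off5"], cds_offset3=info["off3"]))

        # -- retained despite a 1-read control observation
        c, info = pl.fusion_candidate(cid(), pid, "GC3", "GC6")
        add(c, TruthLabel(c.candidate_id, pid,
                          Category.INTRACHROMOSOMAL_FUSION,
                          frame=info["frame"], gene5="GC3", gene3="GC6",
                          transcript5=info["tx5"], transcript3=info["tx3"],
                          cds_offset5=info["off5"], cds_offset3=info["off3"]))
        shared_for_controls.append((p % cfg.n_controls, c, 1))

        patients[pid] = cset

    return patients, pl.hits, pl.truths, shared_for_controls


def make_control_cohort(
    cfg: SimConfig, ref: ToyReference,
    shared_events: Optional[list[tuple[int, FusionCandidate, int]]] = None,
) -> list[CandidateSet]:
    """Control candidate sets with a mostly single-read support profile."""
    rng = np.random.default_rng(int(cfg.seed) + 2)
    controls = [CandidateSet(sample_id=f"C{k + 1:02d}", provenance="synthetic")
                for k in range(cfg.n_controls)]
    for cset in controls:
        for _ in range(cfg.n_control_background):
            c5, c3 = rng.choice(["chrA", "chrB"], size=2)
            bp5 = Breakpoint(str(c5),
                             int(rng.integers(1, len(ref.genome[str(c5)]))),
                             Strand.FORWARD, Side.FIVE_PRIME)
            bp3 = Breakpoint(str(c3),
                             int(rng.integers(1, len(ref.genome[str(c3)]))),
                             Strand.FORWARD, Side.THREE_PRIME)
            if rng.random() < cfg.frac_one_read:
                split, spanning = 1, 0
            else:
                total = int(rng.integers(2, 6))
                split = int(rng.integers(1, total + 1))
                spanning = total - split
            cset.candidates.append(FusionCandidate(
                f"{cset.sample_id}:b{len(cset.candidates):03d}",
                cset.sample_id, bp5, bp3, split, spanning))
    for ordinal, cand, total_reads in shared_events or []:
        cset = controls[ordinal % cfg.n_controls]
        split = max(1, total_reads - 1)
        spanning = total_reads - split
        cset.candidates.append(FusionCandidate(
            f"{cset.sample_id}:s{len(cset.candidates):03d}",
            cset.sample_id, cand.bp5, cand.bp3, split, spanning))
    return controls


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Build the complete input bundle: reference, patients, controls, hits."""
    ref = make_toy_reference(cfg)
    patients, hits, truths, shared = plant_candidates(cfg, ref)
    controls = make_control_cohort(cfg, ref, shared_events=shared)
    phenotype = make_toy_phenotype(cfg, ref)
    return SimulatedCohort(reference=ref, config=cfg, patients=patients,
                           control_sets=controls, hits=hits, truths=truths,
                           phenotype=phenotype)
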