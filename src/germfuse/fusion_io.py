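"""Candidate data model and readers/writers for the workflow's tabular formats.

The fusion caller upstream of this package reports putative chimeric
junctions with split-read and spanning-read support.  This module defines
the in-memory candidate model and parses/emits every external table the
workflow touches: candidate TSVs (a raw caller dialect and a documented
generic dialect), homologous-gene pair lists, gene-symbol lists with
glob-style patterns, and the final categorized report.

All genomic coordinates are 1-based and both-inclusive.
"""

from __future__ import annotations

import csv
import fnmatch
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

try:  # py>=3.9
    from importlib import resources
except ImportError:  # pragma: no cover
    import importlib_resources as resources  # type: ignore


class FusionIOError(ValueError):
    """Configuration or format error in a workflow input file."""


class Strand(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"

    @classmethod
    def parse(cls, token: str) -> "Strand":
        t = token.strip().lower()
        if t in {"+", "f", "forward", "1"}:
            return cls.FORWARD
        if t in {"-", "r", "reverse"}:
            return cls.REVERSE
        raise ValueError(f"unrecognized strand token {token!r}")


class Side(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


def parse_orientation(token: str) -> tuple[Strand, Strand]:
    """Split a two-character orientation token ('ff', 'fr', ...) into strands."""
    t = token.strip().lower()
    if len(t) == 2 and set(t) <= {"f", "r"}:
        return Strand.parse(t[0]), Strand.parse(t[1])
    raise ValueError(f"unrecognized orientation token {token!r}")


@dataclass(frozen=True)
class Breakpoint:
    """One side of a fusion junction: chromosome, 1-based position, strand."""

    chrom: str
    pos: int
    strand: Strand
    side: Side

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass
class FusionCandidate:
    """One caller-reported putative fusion transcript.

    split_reads counts read pairs with one member mapping across the
    junction; spanning_reads counts pairs with one member on each side.
    Sequences (full contig plus decoupled 5'/3' segments) are optional.
    """

    candidate_id: str
    sample_id: str
    bp5: Breakpoint
    bp3: Breakpoint
    split_reads: int
    spanning_reads: int
    seq_full: Optional[str] = None
    seq5: Optional[str] = None
    seq3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.split_reads < 0 or self.spanning_reads < 0:
            raise ValueError("read counts must be >= 0")
        if (
            self.seq_full is not None
            and self.seq5 is not None
            and self.seq3 is not None
            and len(self.seq_full) != len(self.seq5) + len(self.seq3)
        ):
            raise ValueError(
                f"{self.candidate_id}: len(seq_full) != len(seq5)+len(seq3)"
            )

    @property
    def total_reads(self) -> int:
        return self.split_reads + self.spanning_reads


@dataclass
class RowError:
    line_no: int
    message: str


@dataclass
class CandidateSet:
    """Ordered candidates from one sample, with per-row parse errors retained."""

    sample_id: str
    candidates: list[FusionCandidate] = field(default_factory=list)
    provenance: str = ""
    row_errors: list[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def replace(self, candidates: list[FusionCandidate]) -> "CandidateSet":
        return CandidateSet(
            sample_id=self.sample_id,
            candidates=list(candidates),
            provenance=self.provenance,
            row_errors=list(self.row_errors),
        )


@dataclass
class GeneSymbolSet:
    """A named list of gene symbols and/or glob-style symbol patterns.

    Matching is case-insensitive; ``HB*`` matches ``HBB`` but not ``AHBB``.
    """

    name: str
    patterns: set[str]

    def __post_init__(self) -> None:
        if any(not p for p in self.patterns):
            raise ValueError("empty pattern in gene list")

    def matches(self, symbol: Optional[str]) -> bool:
        if not symbol:
            return False
        s = symbol.upper()
        return any(fnmatch.fnmatchcase(s, p.upper()) for p in self.patterns)

    def any_match(self, symbols: Iterable[Optional[str]]) -> bool:
        return any(self.matches(s) for s in symbols)


@dataclass
class HomologSet:
    """Symmetric membership over unordered gene-symbol pairs."""

    pairs: set[frozenset] = field(default_factory=set)

    def add(self, a: str, b: str) -> None:
        self.pairs.add(frozenset((a.upper(), b.upper())))

    def contains(self, a: str, b: str) -> bool:
        return frozenset((a.upper(), b.upper())) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# candidate readers

GENERIC_COLUMNS = [
    "chrom5", "pos5", "strand5", "chrom3", "pos3", "strand3",
    "split_reads", "spanning_reads",
]
OPTIONAL_COLUMNS = ["seq_full", "seq5", "seq3", "sample_id", "candidate_id"]

#: Default column layout for raw caller output: a chromosome pair token
#: ("chrA-chrB"), the two positions, a two-character orientation, then the
#: split and spanning read counts.  Override via ``column_map`` if a raw
#: archive uses a different layout.
TOPHAT_RAW_DEFAULT_MAP = {
    "chrom_pair": 0,
    "pos5": 1,
    "pos3": 2,
    "orientation": 3,
    "split_reads": 4,
    "spanning_reads": 5,
}


def read_candidates(
    path: str | Path,
    dialect: str = "generic_tsv",
    column_map: Optional[dict] = None,
    sample_id: Optional[str] = None,
) -> CandidateSet:
    """Read a per-sample fusion-candidate table.

    Dialects: ``generic_tsv`` (header row naming the generic columns) or
    ``tophat_raw`` (positional columns, see :data:`TOPHAT_RAW_DEFAULT_MAP`).
    Malformed rows are recorded in ``CandidateSet.row_errors``; the read
    fails hard only when more than half the data rows are unparseable.
    """
    path = Path(path)
    if not path.exists():
        raise FusionIOError(f"candidate file not found: {path}")
    if dialect not in {"generic_tsv", "tophat_raw"}:
        raise FusionIOError(f"unknown candidate dialect: {dialect!r}")
    sid = sample_id if sample_id is not None else path.stem
    cset = CandidateSet(sample_id=sid, provenance=f"{dialect}:{path.name}")

    with open(path, newline="") as fh:
        rows = [
            (i, r)
            for i, r in enumerate(csv.reader(fh, delimiter="\t"), start=1)
            if r and not r[0].startswith("#")
        ]

    if dialect == "generic_tsv":
        if not rows:
            return cset
        header_line, header = rows[0]
        colmap = column_map or {
            name.strip().lower(): i for i, name in enumerate(header)
        }
        missing = [c for c in GENERIC_COLUMNS if c not in colmap]
        if missing:
            raise FusionIOError(
                f"{path}: header missing required columns {missing}"
            )
        data_rows = rows[1:]
        parse = lambda r: _parse_generic_row(r, colmap, sid)  # noqa: E731
    else:
        colmap = dict(TOPHAT_RAW_DEFAULT_MAP)
        if column_map:
            colmap.update(column_map)
        data_rows = rows
        parse = lambda r: _parse_tophat_row(r, colmap, sid)  # noqa: E731

    n_fail = 0
    for ordinal, (line_no, row) in enumerate(data_rows):
        try:
            cand = parse(row)
        except (ValueError, IndexError) as exc:
            n_fail += 1
            cset.row_errors.append(RowError(line_no, str(exc)))
            continue
        if cand.candidate_id == "":
            cand.candidate_id = f"{sid}:{ordinal:05d}"
        cset.candidates.append(cand)

    if data_rows and n_fail * 2 > len(data_rows):
        raise FusionIOError(
            f"{path}: {n_fail}/{len(data_rows)} rows failed to parse"
        )
    return cset


def _parse_generic_row(row: list[str], colmap: dict, sid: str) -> FusionCandidate:
    def get(col: str, default: str = "") -> str:
        i = colmap.get(col)
        return row[i].strip() if i is not None and i < len(row) else default

    bp5 = Breakpoint(get("chrom5"), int(get("pos5")),
                     Strand.parse(get("strand5")), Side.FIVE_PRIME)
    bp3 = Breakpoint(get("chrom3"), int(get("pos3")),
                     Strand.parse(get("strand3")), Side.THREE_PRIME)
    return FusionCandidate(
        candidate_id=get("candidate_id"),
        sample_id=get("sample_id", sid) or sid,
        bp5=bp5,
        bp3=bp3,
        split_reads=int(get("split_reads")),
        spanning_reads=int(get("spanning_reads")),
        seq_full=get("seq_full") or None,
        seq5=get("seq5") or None,
        seq3=get("seq3") or None,
    )


def _parse_tophat_row(row: list[str], colmap: dict, sid: str) -> FusionCandidate:
    pair = row[colmap["chrom_pair"]].strip()
    if "-" not in pair:
        raise ValueError(f"bad chromosome pair token {pair!r}")
    chrom5, chrom3 = pair.split("-", 1)
    s5, s3 = parse_orientation(row[colmap["orientation"]])
    return FusionCandidate(
        candidate_id="",
        sample_id=sid,
        bp5=Breakpoint(chrom5, int(row[colmap["pos5"]]), s5, Side.FIVE_PRIME),
        bp3=Breakpoint(chrom3, int(row[colmap["pos3"]]), s3, Side.THREE_PRIME),
        split_reads=int(row[colmap["split_reads"]]),
        spanning_reads=int(row[colmap["spanning_reads"]]),
    )


def write_candidates(cset: CandidateSet, path: str | Path) -> None:
    """Write a CandidateSet in the generic_tsv dialect (round-trip stable)."""
    cols = GENERIC_COLUMNS + OPTIONAL_COLUMNS
    with open(path, "w", newline="") as fh:
        fh.write("# germfuse candidates; coordinates 1-based inclusive\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for c in cset:
            w.writerow(
                [
                    c.bp5.chrom, c.bp5.pos, c.bp5.strand.value,
                    c.bp3.chrom, c.bp3.pos, c.bp3.strand.value,
                    c.split_reads, c.spanning_reads,
                    c.seq_full or "", c.seq5 or "", c.seq3 or "",
                    c.sample_id, c.candidate_id,
                ]
            )


# ---------------------------------------------------------------------------
# gene lists / homolog pairs

def read_gene_list(path: str | Path, name: str = "custom") -> GeneSymbolSet:
    """Read a plain-text symbol/pattern list (one per line, '#' comments)."""
    patterns = set()
    with open(path) as fh:
        for line in fh:
            tok = line.split("#", 1)[0].strip()
            if tok:
                patterns.add(tok)
    return GeneSymbolSet(name=name, patterns=patterns)


def default_gene_list(name: str) -> GeneSymbolSet:
    """Bundled default lists: ``abundant_blood`` or ``immunoglobulin``."""
    fname = {"abundant_blood": "abundant_blood.txt",
             "immunoglobulin": "immunoglobulin.txt"}[name]
    ref = resources.files("germfuse.data").joinpath(fname)
    with resources.as_file(ref) as p:
        return read_gene_list(p, name=name)


def read_homolog_pairs(path: str | Path) -> HomologSet:
    """Read a two-column TSV of homologous gene-symbol pairs."""
    hs = HomologSet()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) >= 2:
                hs.add(parts[0], parts[1])
    return hs


# ---------------------------------------------------------------------------
# categorized report

REPORT_COLUMNS = [
    "candidate_id", "sample_id",
    "chrom5", "pos5", "strand5", "chrom3", "pos3", "strand3",
    "split_reads", "spanning_reads",
    "category", "flags",
    "gene5", "gene3", "transcript5", "transcript3",
    "exon5", "exon3",
    "fused_at_exon_boundaries", "preserves_reading_frame",
    "separation_bp", "read_through_strict",
    "rank_score", "stage", "kept", "reason",
]


def write_report(rows: list[dict], path: str | Path,
                 params: Optional[dict] = None) -> None:
    """Write the categorized report TSV.

    One row per candidate; header lines starting '#' record run parameters.
    Coordinates are 1-based both-inclusive.
    """
    with open(path, "w", newline="") as fh:
        fh.write("# germfuse report; coordinates 1-based inclusive\n")
        for k, v in (params or {}).items():
            fh.write(f"# param {k}={v}\n")
        w = csv.DictWriter(
            fh, fieldnames=REPORT_COLUMNS, delimiter="\t",
            lineterminator="\n", extrasaction="ignore",
        )
        w.writeheader()
        for row in rows:
            w.writerow({k: ("" if row.get(k) is None else row.get(k))
                        for k in REPORT_COLUMNS})


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"category": str, "flags": str},
                       keep_default_na=False, na_values=[""])
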