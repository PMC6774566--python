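"""Evidence and frequency filters applied before categorization.

Three filters run in fixed order ahead of the alignment-pattern decision
tree:

1. *depth*: a candidate must be supported by at least one split read pair
   and at least one spanning read pair (both evidence classes required);
   far more inclusive than typical caller defaults of 3 split / 2
   supporting, which is the point for germline data where mosaicism and
   low expression depress support.
2. *normal-control database*: candidates observed in any unaffected
   control specimen with at least ``min_reads`` supporting reads (default
   2) are removed as recurrent artifacts or constitutive events.
3. *cohort recurrence*: candidates sharing a breakpoint key across two or
   more patients are removed from every patient carrying them — the
   patients are unrelated and expected to have rare, distinct disorders.

Every filter partitions its input: kept and removed are disjoint and
their union, in input order, is the input.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .fusion_io import CandidateSet, FusionCandidate


def _chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering: chr2 < chr10 < chrX."""
    m = re.match(r"(?:chr)?(\d+|[XYM]T?)$", chrom, flags=re.IGNORECASE)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (0, int(tok), "")
        return (1, 0, tok)
    return (2, 0, chrom)


@dataclass(frozen=True)
class FusionKey:
    """Canonical breakpoint-pair key used to match fusions across samples.

    Sides are stored in canonical (chromosome, position) order so that
    reciprocal orientations of the same coordinate pair share a key only
    when the coordinates themselves match.
    """

    chromA: str
    posA: int
    chromB: str
    posB: int
    geneA: Optional[str] = None
    geneB: Optional[str] = None

    @classmethod
    def from_candidate(cls, cand: FusionCandidate,
                       gene5: Optional[str] = None,
                       gene3: Optional[str] = None) -> "FusionKey":
        a = (cand.bp5.chrom, cand.bp5.pos, gene5)
        b = (cand.bp3.chrom, cand.bp3.pos, gene3)
        if (_chrom_sort_key(a[0]), a[1]) <= (_chrom_sort_key(b[0]), b[1]):
            lo, hi = a, b
        else:
            lo, hi = b, a
        return cls(chromA=lo[0], posA=lo[1], chromB=hi[0], posB=hi[1],
                   geneA=lo[2], geneB=hi[2])

    @property
    def coords(self) -> tuple[str, int, str, int]:
        return (self.chromA, self.posA, self.chromB, self.posB)

    def __str__(self) -> str:
        return f"{self.chromA}:{self.posA}/{self.chromB}:{self.posB}"


@dataclass
class FilterDisposition:
    """Where a candidate left the pipeline (or that it was retained)."""

    candidate_id: str
    stage: str  # depth | normal_db | cohort | categorization | phenotype
    kept: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# depth filter

def depth_filter(candidates: CandidateSet, min_split: int = 1,
                 min_spanning: int = 1) -> tuple[CandidateSet, CandidateSet]:
    """Keep candidates with both read classes at or above threshold.

    Defaults (1, 1) require a single split read pair and a single spanning
    read pair — supporting evidence from both classes of fusion-defining
    read pairs, at the lowest level that still demands both.
    """
    if min_split < 0 or min_spanning < 0:
        raise ValueError("depth thresholds must be >= 0")
    kept, removed = [], []
    for c in candidates:
        if c.split_reads >= min_split and c.spanning_reads >= min_spanning:
            kept.append(c)
        else:
            removed.append(c)
    return candidates.replace(kept), candidates.replace(removed)


# ---------------------------------------------------------------------------
# normal-control database

@dataclass
class NormalFusionDB:
    """Fusion events observed in unaffected control specimens.

    ``observations`` retains every control observation (for histograms of
    per-event support); ``qualified`` holds the coordinate keys that meet
    the evidence rule and drive removal: some single control specimen saw
    the event with >= min_reads supporting reads (or the pooled total
    across specimens when built with ``pool_samples=True``).
    """

    observations: dict[tuple, list[tuple[str, int]]] = field(default_factory=dict)
    qualified: set[tuple] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.qualified)

    def contains(self, key: FusionKey, fuzz_bp: int = 0) -> bool:
        if key.coords in self.qualified:
            return True
        if fuzz_bp > 0:
            for (cA, pA, cB, pB) in self.qualified:
                if (cA == key.chromA and cB == key.chromB
                        and abs(pA - key.posA) <= fuzz_bp
                        and abs(pB - key.posB) <= fuzz_bp):
                    return True
        return False

    # -- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#params " + " ".join(
                f"{k}={v}" for k, v in sorted(self.metadata.items())) + "\n")
            fh.write("chromA\tposA\tchromB\tposB\tsample\treads\tqualified\n")
            for coords in sorted(
                self.observations,
                key=lambda c: (_chrom_sort_key(c[0]), c[1],
                               _chrom_sort_key(c[2]), c[3]),
            ):
                q = int(coords in self.qualified)
                for sample, reads in sorted(self.observations[coords]):
                    fh.write("\t".join(map(str, (*coords, sample, reads, q))) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalFusionDB":
        db = cls()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#params"):
                    for tok in line.split()[1:]:
                        k, _, v = tok.partition("=")
                        db.metadata[k] = v
                    continue
                if line.startswith("chromA") or not line.strip():
                    continue
                cA, pA, cB, pB, sample, reads, q = line.rstrip("\n").split("\t")
                coords = (cA, int(pA), cB, int(pB))
                db.observations.setdefault(coords, []).append((sample, int(reads)))
                if q == "1":
                    db.qualified.add(coords)
        return db


def build_normal_db(control_sets: list[CandidateSet], min_reads: int = 2,
                    pool_samples: bool = False) -> NormalFusionDB:
    """Build the normal-control fusion database.

    A key qualifies for filtering when a single control specimen reports
    it with split+spanning reads >= ``min_reads`` (default 2: fewer than
    two supporting reads is insufficient evidence of a genuine event in a
    control).  With ``pool_samples=True`` the rule is instead applied to
    the total across all control specimens.
    """
    if not control_sets:
        raise ValueError("control_sets must be non-empty")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    db = NormalFusionDB(metadata={
        "min_reads": min_reads,
        "pool_samples": pool_samples,
        "n_samples": len(control_sets),
    })
    for cset in control_sets:
        per_key: dict[tuple, int] = {}
        for cand in cset:
            coords = FusionKey.from_candidate(cand).coords
            if coords in per_key:
                warnings.warn(
                    f"duplicate key {coords} in control sample "
                    f"{cset.sample_id}; summing read counts")
            per_key[coords] = per_key.get(coords, 0) + cand.total_reads
        for coords, reads in per_key.items():
            db.observations.setdefault(coords, []).append(
                (cset.sample_id, reads))
    for coords, obs in db.observations.items():
        if pool_samples:
            if sum(r for _, r in obs) >= min_reads:
                db.qualified.add(coords)
        else:
            if max(r for _, r in obs) >= min_reads:
                db.qualified.add(coords)
    return db


def normal_db_filter(candidates: CandidateSet, db: NormalFusionDB,
                     fuzz_bp: int = 0) -> tuple[CandidateSet, CandidateSet]:
    """Remove candidates whose key matches the normal-control database.

    With ``fuzz_bp > 0`` a database key within +/- fuzz_bp on both
    positions (chromosomes equal) also matches.
    """
    kept, removed = [], []
    for c in candidates:
        if db.contains(FusionKey.from_candidate(c), fuzz_bp=fuzz_bp):
            removed.append(c)
        else:
            kept.append(c)
    return candidates.replace(kept), candidates.replace(removed)


# ---------------------------------------------------------------------------
# cohort recurrence

def cohort_recurrence_filter(
    per_patient: dict[str, CandidateSet],
) -> dict[str, tuple[CandidateSet, CandidateSet]]:
    """Remove candidates recurring across unrelated patients.

    A key observed in >= 2 distinct patients is removed from every patient
    carrying it; duplicates within one patient do not trigger removal.
    """
    if not per_patient:
        raise ValueError("at least one patient required")
    patients_per_key: dict[tuple, set[str]] = {}
    for pid, cset in per_patient.items():
        for cand in cset:
            coords = FusionKey.from_candidate(cand).coords
            patients_per_key.setdefault(coords, set()).add(pid)
    recurrent = {k for k, pids in patients_per_key.items() if len(pids) >= 2}
    out = {}
    for pid, cset in per_patient.items():
        kept, removed = [], []
        for cand in cset:
            if FusionKey.from_candidate(cand).coords in recurrent:
                removed.append(cand)
            else:
                kept.append(cand)
        out[pid] = (cset.replace(kept), cset.replace(removed))
    return out
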