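"""End-to-end workflow orchestration.

Stage order is fixed: depth filter → normal-control database filter →
cohort-recurrence filter → alignment-pattern categorization → phenotype
prioritization.  Every input candidate appears in the final report with
its disposition (the stage that removed it, or its category and flags);
an attrition table records counts entering and leaving every stage per
sample.  Given identical inputs and configuration the report is
byte-identical across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .alignment import (
    AlignConfig,
    AlignmentHit,
    filter_hits,
    query_id_for,
    select_top_hits,
    summarize_alignments,
)
from .annotate import locate_breakpoint
from .categorize import Category, CategorizedCandidate, categorize_candidate
from .filters import (
    FilterDisposition,
    NormalFusionDB,
    build_normal_db,
    cohort_recurrence_filter,
    depth_filter,
    normal_db_filter,
)
from .fusion_io import (
    CandidateSet,
    FusionCandidate,
    GeneSymbolSet,
    HomologSet,
    default_gene_list,
    write_report,
)
from .genemodels import GeneModelIndex


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PhenotypeConfig:
    ontology: object  # PhenotypeOntology
    gene_terms_table: dict[str, set[str]]
    patient_terms: dict[str, list[str]]  # patient id -> term ids
    cutoff: float = 0.05


@dataclass
class PipelineConfig:
    per_patient: dict[str, CandidateSet]
    index: GeneModelIndex
    hits: list[AlignmentHit] = field(default_factory=list)
    control_sets: list[CandidateSet] = field(default_factory=list)
    normal_db: Optional[NormalFusionDB] = None
    homologs: HomologSet = field(default_factory=HomologSet)
    abundant: Optional[GeneSymbolSet] = None
    immunoglobulins: Optional[GeneSymbolSet] = None
    align_cfg: AlignConfig = field(default_factory=AlignConfig)
    min_split: int = 1
    min_spanning: int = 1
    normdb_min_reads: int = 2
    normdb_pool_samples: bool = False
    normdb_fuzz_bp: int = 0
    phenotype: Optional[PhenotypeConfig] = None
    out_dir: Optional[Path] = None


@dataclass
class PipelineResult:
    report: pd.DataFrame
    attrition: pd.DataFrame
    categorized: dict[str, list[CategorizedCandidate]]
    dispositions: dict[str, list[FilterDisposition]]
    shortlists: dict[str, list[CategorizedCandidate]]
    normal_db: Optional[NormalFusionDB] = None


def _candidate_hits(hits: list[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    by_cand: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_cand.setdefault(h.candidate_id, []).append(h)
    return by_cand


def _query_lengths(cand: FusionCandidate,
                   hits: list[AlignmentHit]) -> dict[str, int]:
    """Lengths of a candidate's queries, from sequences when present.

    When a sequence is absent but precomputed hits reference the query,
    the maximum q_end observed is used as a lower bound on its length
    (coverage is then an upper bound, the permissive direction).
    """
    qlen: dict[str, int] = {}
    for kind, seq in (("full", cand.seq_full), ("seg5", cand.seq5),
                      ("seg3", cand.seq3)):
        if seq:
            qlen[query_id_for(cand.candidate_id, kind)] = len(seq)
    full_q = query_id_for(cand.candidate_id, "full")
    s5, s3 = (query_id_for(cand.candidate_id, k) for k in ("seg5", "seg3"))
    if full_q not in qlen and s5 in qlen and s3 in qlen:
        qlen[full_q] = qlen[s5] + qlen[s3]
    for h in hits:
        if h.query_id not in qlen:
            qlen[h.query_id] = h.q_end
    return qlen


def categorize_set(
    cset: CandidateSet,
    hits_by_cand: dict[str, list[AlignmentHit]],
    index: GeneModelIndex,
    abundant: GeneSymbolSet,
    immunoglobulins: GeneSymbolSet,
    homologs: HomologSet,
    cfg: AlignConfig,
) -> list[CategorizedCandidate]:
    out = []
    for cand in cset:
        raw = hits_by_cand.get(cand.candidate_id, [])
        qlen = _query_lengths(cand, raw)
        kept = filter_hits(raw, cfg, qlen)
        top = select_top_hits(kept)
        summary = summarize_alignments(
            cand, top, index, cfg=cfg, query_lengths=qlen, raw_hits=raw)
        ann5 = locate_breakpoint(cand.bp5, index)
        ann3 = locate_breakpoint(cand.bp3, index)
        out.append(categorize_candidate(
            cand, summary, ann5, ann3, abundant, immunoglobulins,
            homologs, index))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; see module docstring for stage order."""
    abundant = config.abundant or default_gene_list("abundant_blood")
    immunoglobulins = (config.immunoglobulins
                       or default_gene_list("immunoglobulin"))
    dispositions: dict[str, list[FilterDisposition]] = {
        pid: [] for pid in config.per_patient}
    attrition_rows = []

    # stage 1: depth -----------------------------------------------------
    try:
        after_depth: dict[str, CandidateSet] = {}
        removed_depth: dict[str, int] = {}
        for pid, cset in config.per_patient.items():
            kept, removed = depth_filter(
                cset, config.min_split, config.min_spanning)
            after_depth[pid] = kept
            removed_depth[pid] = len(removed)
            for c in removed:
                dispositions[pid].append(FilterDisposition(
                    c.candidate_id, "depth", False,
                    f"split={c.split_reads} spanning={c.spanning_reads} "
                    f"< ({config.min_split},{config.min_spanning})"))
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"stage depth failed: {exc}") from exc

    # stage 2: normal-control database ----------------------------------
    try:
        db = config.normal_db
        if db is None and config.control_sets:
            db = build_normal_db(
                config.control_sets, min_reads=config.normdb_min_reads,
                pool_samples=config.normdb_pool_samples)
        after_normal: dict[str, CandidateSet] = {}
        removed_normal: dict[str, int] = {}
        for pid, cset in after_depth.items():
            if db is not None:
                kept, removed = normal_db_filter(
                    cset, db, fuzz_bp=config.normdb_fuzz_bp)
            else:
                kept, removed = cset, cset.replace([])
            after_normal[pid] = kept
            removed_normal[pid] = len(removed)
            for c in removed:
                dispositions[pid].append(FilterDisposition(
                    c.candidate_id, "normal_db", False,
                    "matched normal-control database"))
    except Exception as exc:
        raise PipelineError(f"stage normal_db failed: {exc}") from exc

    # stage 3: cohort recurrence ----------------------------------------
    try:
        cohort_out = cohort_recurrence_filter(after_normal)
        after_cohort: dict[str, CandidateSet] = {}
        removed_cohort: dict[str, int] = {}
        for pid, (kept, removed) in cohort_out.items():
            after_cohort[pid] = kept
            removed_cohort[pid] = len(removed)
            for c in removed:
                dispositions[pid].append(FilterDisposition(
                    c.candidate_id, "cohort", False,
                    "recurrent across cohort patients"))
    except Exception as exc:
        raise PipelineError(f"stage cohort failed: {exc}") from exc

    # stage 4: categorization -------------------------------------------
    try:
        hits_by_cand = _candidate_hits(config.hits)
        categorized: dict[str, list[CategorizedCandidate]] = {}
        for pid, cset in after_cohort.items():
            ccs = categorize_set(
                cset, hits_by_cand, config.index, abundant,
                immunoglobulins, config.homologs, config.align_cfg)
            categorized[pid] = ccs
            for cc in ccs:
                dispositions[pid].append(FilterDisposition(
                    cc.candidate.candidate_id, "categorization", True,
                    cc.category.value))
    except Exception as exc:
        raise PipelineError(f"stage categorization failed: {exc}") from exc

    # stage 5: phenotype prioritization ---------------------------------
    shortlists: dict[str, list[CategorizedCandidate]] = {
        pid: [] for pid in config.per_patient}
    if config.phenotype is not None:
        try:
            from .prioritize import prioritize_candidates

            ph = config.phenotype
            for pid, ccs in categorized.items():
                terms = ph.patient_terms.get(pid, [])
                if not terms:
                    continue
                shortlist, _ = prioritize_candidates(
                    ccs, terms, ph.gene_terms_table, ph.ontology,
                    threshold=ph.cutoff)
                shortlists[pid] = shortlist
        except Exception as exc:
            raise PipelineError(f"stage phenotype failed: {exc}") from exc

    # report + attrition -------------------------------------------------
    report_rows = []
    for pid in sorted(config.per_patient):
        cat_by_id = {cc.candidate.candidate_id: cc
                     for cc in categorized.get(pid, [])}
        disp_by_id = {d.candidate_id: d for d in dispositions[pid]}
        for cand in config.per_patient[pid]:
            cc = cat_by_id.get(cand.candidate_id)
            disp = disp_by_id.get(cand.candidate_id)
            row = {
                "candidate_id": cand.candidate_id,
                "sample_id": cand.sample_id,
                "chrom5": cand.bp5.chrom, "pos5": cand.bp5.pos,
                "strand5": cand.bp5.strand.value,
                "chrom3": cand.bp3.chrom, "pos3": cand.bp3.pos,
                "strand3": cand.bp3.strand.value,
                "split_reads": cand.split_reads,
                "spanning_reads": cand.spanning_reads,
                "stage": disp.stage if disp else "",
                "kept": disp.kept if disp else "",
                "reason": disp.reason if disp else "",
            }
            if cc is not None:
                boundary = (cc.ann5.at_exon_boundary
                            and cc.ann3.at_exon_boundary)
                row.update({
                    "category": cc.category.value,
                    "flags": ",".join(sorted(cc.flags)),
                    "gene5": cc.gene5, "gene3": cc.gene3,
                    "transcript5": cc.ann5.transcript,
                    "transcript3": cc.ann3.transcript,
                    "exon5": cc.ann5.exon_index,
                    "exon3": cc.ann3.exon_index,
                    "fused_at_exon_boundaries": "Yes" if boundary else "No",
                    "preserves_reading_frame": (
                        cc.frame.status.value if cc.frame else ""),
                    "separation_bp": (
                        cc.separation if cc.separation is not None else "NA"),
                    "read_through_strict": cc.read_through_strict,
                    "rank_score": cc.rank_score,
                })
            report_rows.append(row)
        attrition_rows.append({
            "sample": pid,
            "n_input": len(config.per_patient[pid]),
            "removed_depth": removed_depth[pid],
            "removed_normal_db": removed_normal[pid],
            "removed_cohort": removed_cohort[pid],
            "n_categorized": len(categorized.get(pid, [])),
            **{cat.value: sum(1 for cc in categorized.get(pid, [])
                              if cc.category == cat) for cat in Category},
            "n_shortlisted": len(shortlists[pid]),
        })

    report = pd.DataFrame(report_rows)
    attrition = pd.DataFrame(attrition_rows)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        params = {
            "min_split": config.min_split,
            "min_spanning": config.min_spanning,
            "normdb_min_reads": config.normdb_min_reads,
            "normdb_pool_samples": config.normdb_pool_samples,
            "normdb_fuzz_bp": config.normdb_fuzz_bp,
            "min_identity": config.align_cfg.min_identity,
            "min_query_coverage": config.align_cfg.min_query_coverage,
            "unbroken_coverage": config.align_cfg.unbroken_coverage,
            "median_convention": "lower median (order statistic)",
        }
        write_report(report_rows, out / "report.tsv", params=params)
        attrition.to_csv(out / "attrition.tsv", sep="\t", index=False)
        if db is not None:
            db.to_tsv(out / "normal_db.tsv")
        pd.Series({str(k): str(v) for k, v in params.items()}).to_json(
            out / "run_manifest.json", indent=2)

    return PipelineResult(
        report=report, attrition=attrition, categorized=categorized,
        dispositions=dispositions, shortlists=shortlists, normal_db=db)
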