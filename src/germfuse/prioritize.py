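"""Phenotype-based prioritization of fusion-category candidates.

Genes are scored for semantic similarity between the patient's phenotype
terms and the terms associated with each disease gene, then ranked; a
gene's rank-score is rank / number of scored genes, so 0.01 means the
gene scores in the top 1% of all scored disease genes.  Smaller is more
phenotype-relevant.  The similarity scorer is pluggable: the default is
a Resnik-style scorer (mean over patient terms of the information
content of the most informative common ancestor with any gene term, IC
estimated from term frequency in the supplied gene–term table).  Pathway
and interaction-network neighborhood scores from external tools are out
of scope; the report carries a free-text evidence column instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional

import networkx as nx
import obonet
import pandas as pd

from .categorize import FUSION_CATEGORIES, Category, CategorizedCandidate


@dataclass(frozen=True)
class PhenotypeRank:
    gene: str
    raw_score: float
    rank: int
    rank_score: float  # rank / number of scored genes, in (0, 1]


class PhenotypeOntology:
    """A term hierarchy (is_a DAG) with ancestor queries and IC estimates."""

    def __init__(self, graph: nx.MultiDiGraph):
        # obonet graphs point child -> parent along 'is_a'
        self.graph = graph
        self._anc_cache: dict[str, frozenset] = {}

    @classmethod
    def from_obo(cls, path: str | Path) -> "PhenotypeOntology":
        return cls(obonet.read_obo(str(path)))

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> frozenset:
        """All is_a ancestors of a term, including the term itself."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        seen = {term}
        stack = [term]
        while stack:
            node = stack.pop()
            for _, parent, key in self.graph.out_edges(node, keys=True):
                if key == "is_a" and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        out = frozenset(seen)
        self._anc_cache[term] = out
        return out


def read_gene_terms(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> gene -> set of term ids."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "term"], dtype=str)
    table: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        table.setdefault(gene, set()).add(term)
    return table


def information_content(gene_terms_table: dict[str, set[str]],
                        ontology: PhenotypeOntology) -> dict[str, float]:
    """IC(term) = -log(fraction of genes annotated to term or a descendant).

    Annotations propagate to ancestors, so the root is annotated by every
    gene and has IC 0.
    """
    n_genes = len(gene_terms_table)
    counts: dict[str, int] = {}
    for terms in gene_terms_table.values():
        annotated: set[str] = set()
        for t in terms:
            if t in ontology:
                annotated |= ontology.ancestors(t)
        for t in annotated:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n_genes) for t, c in counts.items()}


def similarity_score(patient_terms: Iterable[str], gene_terms: Iterable[str],
                     ontology: PhenotypeOntology,
                     ic: Optional[dict[str, float]] = None) -> float:
    """Resnik-style similarity between a patient's and a gene's term sets.

    Mean over patient terms of the maximum IC of the most informative
    common ancestor shared with any gene term.  Unknown terms are skipped
    with a warning; empty term sets score 0.  Terms whose only common
    ancestor is the root score 0 (root IC is 0).
    """
    ic = ic or {}
    pt = [t for t in patient_terms if _known(t, ontology)]
    gt = [t for t in gene_terms if _known(t, ontology)]
    if not pt or not gt:
        return 0.0
    gene_anc = [ontology.ancestors(t) for t in gt]
    per_term = []
    for p in pt:
        p_anc = ontology.ancestors(p)
        best = 0.0
        for g_anc in gene_anc:
            common = p_anc & g_anc
            if common:
                best = max(best, max(ic.get(t, 0.0) for t in common))
        per_term.append(best)
    return sum(per_term) / len(per_term)


def _known(term: str, ontology: PhenotypeOntology) -> bool:
    if term in ontology:
        return True
    warnings.warn(f"unknown phenotype term {term!r}; skipped")
    return False


Scorer = Callable[[Iterable[str], Iterable[str], PhenotypeOntology], float]


def rank_scores(scores: dict[str, float]) -> dict[str, PhenotypeRank]:
    """Rank genes by descending raw score; rank_score = rank / N.

    Ties receive the minimum rank of the tied block, so ties never worsen
    a gene's rank-score.  Scale-invariant: any strictly monotone
    transform of the raw scores yields identical rank-scores.
    """
    if not scores:
        raise ValueError("at least one scored gene required")
    n = len(scores)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    out: dict[str, PhenotypeRank] = {}
    rank = 0
    prev_score: Optional[float] = None
    for i, (gene, score) in enumerate(ordered, start=1):
        if prev_score is None or score != prev_score:
            rank = i
            prev_score = score
        out[gene] = PhenotypeRank(gene=gene, raw_score=score, rank=rank,
                                  rank_score=rank / n)
    return out


def score_gene_panel(patient_terms: Iterable[str],
                     gene_terms_table: dict[str, set[str]],
                     ontology: PhenotypeOntology,
                     scorer: Optional[Scorer] = None) -> dict[str, PhenotypeRank]:
    """Score and rank every gene in the association table for one patient."""
    patient_terms = list(patient_terms)
    if scorer is None:
        ic = information_content(gene_terms_table, ontology)
        scorer = lambda p, g, o: similarity_score(p, g, o, ic=ic)  # noqa: E731
    raw = {gene: scorer(patient_terms, terms, ontology)
           for gene, terms in gene_terms_table.items()}
    return rank_scores(raw)


def prioritize_candidates(
    categorized: list[CategorizedCandidate],
    patient_terms: Iterable[str],
    gene_terms_table: dict[str, set[str]],
    ontology: PhenotypeOntology,
    threshold: float = 0.05,
    scorer: Optional[Scorer] = None,
    categories: frozenset = FUSION_CATEGORIES,
) -> tuple[list[CategorizedCandidate], list[CategorizedCandidate]]:
    """Annotate fusion-category candidates with rank-scores and shortlist.

    Each candidate receives the better (smaller) rank-score of its two
    partner genes.  Returns ``(shortlist, scored)``: the shortlist holds
    candidates at or below the cutoff, ordered ascending by rank-score;
    ``scored`` retains every scored candidate (manual review of the rest
    is a human step, not automated away).  Candidates whose genes are
    absent from the association table are flagged and excluded from the
    shortlist.
    """
    ranks = score_gene_panel(patient_terms, gene_terms_table, ontology,
                             scorer=scorer)
    scored: list[CategorizedCandidate] = []
    for cc in categorized:
        if cc.category not in categories:
            continue
        partner_ranks = [ranks[g].rank_score
                         for g in (cc.gene5, cc.gene3) if g in ranks]
        if partner_ranks:
            cc.rank_score = min(partner_ranks)
        else:
            cc.rank_score = None
            cc.flags.add("genes_unscored")
        scored.append(cc)
    shortlist = sorted(
        (cc for cc in scored
         if cc.rank_score is not None and cc.rank_score <= threshold),
        key=lambda cc: (cc.rank_score, cc.candidate.candidate_id))
    return shortlist, scored
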