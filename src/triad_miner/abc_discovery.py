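"""The ABC discovery core: scale–therapy linking and candidate ranking.

The model joins a disease literature (A) to candidate interventions (C)
through shared intermediate terms (B) — here, clinical assessment scales.
Scales extracted from the disease corpus anchor a second corpus; therapies
mined from that scale-anchored corpus form the All_Therapies set. Therapies
already known for the disease are subtracted, candidates that ever co-occur
with the disease in the literature are excluded, and the survivors are ranked
by how many distinct scales they share documents with (then by document
frequency, then lexicographically).

Co-occurrence scope is the whole record (title + abstract): two phrases are
linked by a document iff both appear in that document's normalized noun-phrase
set, counted binarily per document.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import Corpus
from .phrase_mining import (
    ChunkGrammar,
    DEFAULT_GRAMMAR,
    compute_tfidf,
    document_phrase_set,
    phrase_document_frequency,
)
from .tagging import Tagger
from .term_classification import (
    Blacklist,
    DEFAULT_BLACKLIST,
    DEFAULT_SUFFIX_RULES,
    SCALE,
    SuffixRuleSet,
    TermRow,
    TermTable,
    THERAPY,
    build_term_table,
)

__all__ = [
    "CooccurrenceEdge",
    "CandidateTherapy",
    "DiscoveryResult",
    "cooccurrence_edges",
    "derive_all_therapies",
    "subtract_known",
    "exclude_disease_cooccurrence",
    "rank_candidates",
    "export_interaction_matrix",
    "run_discovery",
]


@dataclass(frozen=True)
class CooccurrenceEdge:
    """(scale, therapy) linked by ``weight`` ≥ 1 distinct documents."""

    scale_phrase: str
    therapy_phrase: str
    weight: int

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("edge weight must be ≥ 1")


@dataclass(frozen=True)
class CandidateTherapy:
    """A therapy not yet known for the disease, with its linked scales."""

    phrase: str
    doc_freq: int
    linked_scales: frozenset[str]
    rank: int

    @property
    def n_links(self) -> int:
        return len(self.linked_scales)


@dataclass
class DiscoveryResult:
    """Ranked candidates plus the edge set and run provenance."""

    candidates: list[CandidateTherapy]
    edges: list[CooccurrenceEdge]
    provenance: dict = field(default_factory=dict)


def cooccurrence_edges(
    corpus: Corpus,
    scales: Iterable[str],
    therapies: Iterable[str],
    grammar: ChunkGrammar = DEFAULT_GRAMMAR,
    tagger: Tagger | None = None,
) -> list[CooccurrenceEdge]:
    """All (scale, therapy) pairs sharing ≥ 1 document, with document counts.

    Binary per document: repeating a phrase inside one record does not raise a
    weight. The scale and therapy phrase sets must be canonical and disjoint.
    """
    scale_set = set(scales)
    therapy_set = set(therapies)
    overlap = scale_set & therapy_set
    if overlap:
        raise ValueError(f"scale and therapy sets must be disjoint; shared: {sorted(overlap)}")
    weights: dict[tuple[str, str], int] = {}
    for doc in corpus:
        present = document_phrase_set(doc.text, grammar, tagger)
        doc_scales = scale_set & present
        doc_therapies = therapy_set & present
        for b in doc_scales:
            for c in doc_therapies:
                weights[(b, c)] = weights.get((b, c), 0) + 1
    return [
        CooccurrenceEdge(b, c, w)
        for (b, c), w in sorted(weights.items())
    ]


def derive_all_therapies(
    scale_corpus: Corpus,
    rules: SuffixRuleSet = DEFAULT_SUFFIX_RULES,
    min_doc_freq: int = 6,
    blacklist: Blacklist = DEFAULT_BLACKLIST,
    grammar: ChunkGrammar = DEFAULT_GRAMMAR,
    tagger: Tagger | None = None,
) -> TermTable:
    """Therapy table mined from the scale-anchored corpus (All_Therapies).

    Same NP → suffix → threshold → blacklist chain as the disease pipeline,
    applied to the corpus retrieved by scale-phrase queries.
    """
    stats = phrase_document_frequency(scale_corpus, grammar, tagger)
    compute_tfidf(scale_corpus, stats)
    tables = build_term_table(stats, rules, min_doc_freq, blacklist)
    return tables.get(THERAPY, TermTable([], THERAPY, threshold_used=min_doc_freq))


def subtract_known(all_therapies: TermTable, known_therapies: Iterable[str]) -> TermTable:
    """Exact canonical set difference; df and TF-IDF carried through."""
    known = set(known_therapies)
    rows = [r for r in all_therapies.rows if r.phrase not in known]
    return TermTable(rows, all_therapies.category, all_therapies.threshold_used,
                     all_therapies.sort_key)


def exclude_disease_cooccurrence(
    candidates: TermTable,
    disease_corpus: Corpus,
    disease_terms: Iterable[str],
    grammar: ChunkGrammar = DEFAULT_GRAMMAR,
    tagger: Tagger | None = None,
) -> TermTable:
    """Drop every candidate that co-occurs with the disease in any document.

    A document "mentions the disease" if any disease term appears as a raw
    lowercase substring of title+abstract (disease keywords are not tracked
    noun phrases); it "contains the candidate" if the candidate's canonical
    phrase is in the document's normalized NP set. Survivors have provably
    zero co-mention documents in the given corpus.
    """
    remaining = candidates.phrases()
    terms = [t.lower() for t in disease_terms]
    for doc in disease_corpus:
        if not remaining:
            break
        text = doc.text.lower()
        if not any(t in text for t in terms):
            continue
        present = document_phrase_set(doc.text, grammar, tagger)
        remaining -= present
    rows = [r for r in candidates.rows if r.phrase in remaining]
    return TermTable(rows, candidates.category, candidates.threshold_used,
                     candidates.sort_key)


def rank_candidates(
    candidates: TermTable,
    edges: Sequence[CooccurrenceEdge],
    provenance: Mapping | None = None,
) -> DiscoveryResult:
    """Rank candidates by (n_links desc, doc_freq desc, phrase asc).

    A candidate with no edges has zero links but stays in the ranking.
    """
    links: dict[str, set[str]] = {r.phrase: set() for r in candidates.rows}
    for e in edges:
        if e.therapy_phrase in links:
            links[e.therapy_phrase].add(e.scale_phrase)
    ordered = sorted(
        candidates.rows,
        key=lambda r: (-len(links[r.phrase]), -r.doc_freq, r.phrase),
    )
    ranked = [
        CandidateTherapy(r.phrase, r.doc_freq, frozenset(links[r.phrase]), i + 1)
        for i, r in enumerate(ordered)
    ]
    return DiscoveryResult(ranked, list(edges), dict(provenance or {}))


def export_interaction_matrix(
    edges: Sequence[CooccurrenceEdge],
    scales: Iterable[str],
    therapies: Iterable[str],
) -> pd.DataFrame:
    """Scales × therapies weight matrix with row/column marginals appended.

    Marginals live in a ``_total`` row and column; the grand total sits at
    their intersection. Serializable as TSV.
    """
    scale_list = sorted(set(scales))
    therapy_list = sorted(set(therapies))
    mat = pd.DataFrame(0, index=scale_list, columns=therapy_list, dtype=int)
    for e in edges:
        if e.scale_phrase in mat.index and e.therapy_phrase in mat.columns:
            mat.loc[e.scale_phrase, e.therapy_phrase] = e.weight
    mat["_total"] = mat.sum(axis=1)
    mat.loc["_total"] = mat.sum(axis=0)
    return mat


def run_discovery(
    disease_corpus: Corpus,
    scale_corpus: Corpus,
    disease_terms: Iterable[str],
    rules: SuffixRuleSet = DEFAULT_SUFFIX_RULES,
    min_doc_freq: int = 6,
    blacklist: Blacklist = DEFAULT_BLACKLIST,
    grammar: ChunkGrammar = DEFAULT_GRAMMAR,
    tagger: Tagger | None = None,
    scale_universe: Iterable[str] | None = None,
    provenance: Mapping | None = None,
) -> tuple[DiscoveryResult, dict[str, TermTable]]:
    """End-to-end pipeline: disease corpus → scales & known therapies →
    All_Therapies → subtraction → disease-co-occurrence exclusion → ranking.

    ``scale_universe`` overrides the B-term set used for linking; it defaults
    to the disease-derived scale table but may be a superset. Returns the
    ranked result plus the intermediate term tables keyed as ``scales``,
    ``known_therapies``, ``all_therapies`` and ``candidates``.
    """
    stats = phrase_document_frequency(disease_corpus, grammar, tagger)
    compute_tfidf(disease_corpus, stats)
    disease_tables = build_term_table(stats, rules, min_doc_freq, blacklist)
    scale_table = disease_tables.get(SCALE, TermTable([], SCALE, min_doc_freq))
    known_table = disease_tables.get(THERAPY, TermTable([], THERAPY, min_doc_freq))

    all_therapies = derive_all_therapies(
        scale_corpus, rules, min_doc_freq, blacklist, grammar, tagger
    )
    candidates = subtract_known(all_therapies, known_table.phrases())
    candidates = exclude_disease_cooccurrence(
        candidates, disease_corpus, disease_terms, grammar, tagger
    )

    b_set = set(scale_universe) if scale_universe is not None else scale_table.phrases()
    edges = cooccurrence_edges(scale_corpus, b_set, candidates.phrases(), grammar, tagger)
    prov = {
        "disease_corpus": disease_corpus.source_label,
        "scale_corpus": scale_corpus.source_label,
        "min_doc_freq": min_doc_freq,
        "disease_terms": sorted({t.lower() for t in disease_terms}),
        "n_scales": len(scale_table),
        "n_known_therapies": len(known_table),
        **dict(provenance or {}),
    }
    result = rank_candidates(candidates, edges, prov)
    tables = {
        "scales": scale_table,
        "known_therapies": known_table,
        "all_therapies": all_therapies,
        "candidates": candidates,
    }
    return result, tables
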